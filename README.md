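# oculoscreen

Screening for posterior circulation stroke (PCS) from **uncalibrated**
binocular eye-tracking.

PCS presents with non-specific symptoms (dizziness, nausea, headache) and is
frequently misdiagnosed, yet it leaves measurable fingerprints in eye
movements: dysconjugacy, pathological nystagmus, saccadic pursuit. A
screen-based eye tracker can capture these during three short computer-adapted
bedside examinations — the **Dot test** (volitional saccades between jumping
targets), the **H test** (smooth pursuit of a target tracing the letter H) and
the **OKN test** (optokinetic nystagmus elicited by drifting bars). The catch
is calibration: acutely ill patients often cannot complete a calibration
procedure, so the recorded coordinates are related to true gaze by an unknown
affine deformation (translation, scaling, rotation, shearing) per eye.

`oculoscreen` implements a classification pipeline built to be robust to
exactly that, plus a synthetic binocular-gaze simulator and an evaluation
protocol, so the whole pipeline can be built, exercised and tested without
patient data.

## Method

A recording reduces to 2-D point sets carrying uniform mass: one per eye and a
left-minus-right **disparity** set that encodes conjugacy. Each set Ω₂ is
embedded by the **Discrete Radon Cumulative Distribution Transform (DRCDT)**:
for each direction w_θ = (cos θ, sin θ) on an angle grid θ ∈ {jπ/L}, the
projections {x·w_θ : x ∈ Ω₂} are sorted (the discrete CDT, i.e. the empirical
quantile function) and resampled at M fixed quantile levels:

    P̂_s(θ) = sorted({x·w_θ}) evaluated at quantile levels (i−0.5)/M .

The embedding is transport-based: translating the points by t adds the
constant t·w_θ to the θ-row, and scaling by α > 0 scales the feature by α, so
tracker deformations become low-dimensional **linear** families in feature
space.

Classification is **nearest-subspace (NS)**: class k is the span of its
training features augmented with the deformation spanning set

    U_T = {μ₁(θ) = cos θ, μ₂(θ) = sin θ}  (constant per angle stripe),

which absorbs every translation-induced feature shift exactly. A test feature
f is assigned to k* = argmin_k ‖f − B_k B_kᵀ f‖₂. One NS model is trained per
test; the three votes are fused (default **ANY-POSITIVE**: positive iff at
least one test is positive, trading specificity for the sensitivity that
stroke triage prioritizes). Recordings failing the acquisition gate (≥ 1 eye
detected, ≥ 90 % capture) abstain from the vote.

## Worked example

Simulate a labeled cohort, train the three per-test models, and screen two
previously unseen participants:

```bash
oculoscreen simulate --abnormal 6 --normal 6 --seed 7 --out cohort/
oculoscreen train --cohort-dir cohort/ --out models/
oculoscreen simulate --abnormal 1 --normal 1 --seed 99 --out newcases/
oculoscreen diagnose --dot newcases/p000_DOT.csv --h newcases/p000_H.csv \
                     --okn newcases/p000_OKN.csv --models models/
```

which prints (abbreviated):

```
wrote 36 recordings and manifest to cohort
trained 3 models -> models
p000 -> positive  DOT: positive (d0=5995.2, d1=4071.8)
                  H:   positive (d0=3611.3, d1=1989.8)
                  OKN: positive (d0=2185.7, d1=1387.2)
p001 -> negative  DOT: negative (d0=1776.2, d1=2285.1)
```

`d0`/`d1` are the distances to the normal and abnormal class subspaces; the
held-out dysconjugate patient (`p000`, simulated with per-eye translations of
~100–175 px, 10–20 % scale error and rotation) is flagged positive by all
three tests, and the healthy control `p001` is negative on all three. The full
evaluation protocol (bootstrap metrics, inter-eye Spearman tables, ablation,
learning curves) runs with `oculoscreen evaluate --out results/`.

### Gaze CSV dialect

One recording per UTF-8 file, header
`participant_id,test,t,lx,ly,rx,ry,lvalid,rvalid`: time in seconds, per-eye
x/y in tracker units, validity flags 0/1; invalid coordinates are empty
fields. Cohort directories carry a `manifest.csv` with
`participant_id,label,condition,seed` and the per-eye deformation parameters.

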