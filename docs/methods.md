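# Methods

This note documents the models, parameters and design choices behind
`oculoscreen`: what is computed, why the defaults are what they are, and what
the synthetic experiments do and do not demonstrate.

## Preprocessing

Recordings are gated by the acquisition protocol before any processing: a
recording is usable when the tracker detected at least one eye at some point
and at least 90 % of samples carry one valid eye (inclusive comparison;
`compliance_threshold`, default 0.90). Compliance is checked on the raw
validity flags, then usable recordings are smoothed.

Smoothing is a Savitzky–Golay filter applied independently to the four
coordinate channels. The window is 31 samples (≈ 0.26 s at 120 Hz) with cubic
polynomial order — the filter requires an odd window, and 31 is the nearest
odd width to the quarter-second blink-artifact scale the protocol targets;
both are configurable. Invalid runs are first linearly interpolated over time
so the filter sees finite input; interior runs up to `max_gap_s` = 0.25 s are
treated as blinks and kept (flagged *imputed*), longer runs and runs touching
the recording edges are excluded from all downstream point sets — long gaps
are not blinks. An eye with no valid sample at all stays missing and the
recording follows the monocular path (the present eye's feature block is
duplicated; the disparity block is zero). Smoothing reproduces polynomials up
to the filter order exactly (asserted to 1e-9 on interior samples), so it is
idempotent on clean traces.

Coordinates are screen-like (origin top-left, y increasing downward), in
whatever units the uncalibrated tracker emits; no resampling to a uniform time
grid is performed because the transform is order-free.

## The DRCDT embedding

Each recording yields three point sets with uniform mass: left eye, right eye,
and the left-minus-right disparity multiset over samples where both eyes are
present. For each angle θ on a uniform grid of L = 8 directions θ_j = jπ/8
(line projections are π-periodic up to reflection, so [0, π) suffices), the
points are projected onto w_θ = (cos θ, sin θ), sorted, and the resulting
empirical quantile function is evaluated at M = 64 midpoint levels
(i − 0.5)/M by linear interpolation between order statistics at plotting
positions (j − 0.5)/n (Hazen convention; midpoints avoid the degenerate 0/1
extremes). Recordings of any length therefore map to a fixed-length vector;
the three blocks are concatenated left | right | disparity, angle-major within
each block, giving 3·L·M = 1536 dimensions at the defaults. The disparity
block makes conjugacy explicit and can be disabled (`include_disparity`) for
ablations.

Key exact properties (all under test): permutation invariance, row
sortedness, translation covariance (row θ shifts by t·w_θ) and positive scale
covariance (feature scales by α).

## Nearest-subspace classification with deformation modeling

Class k is represented by the orthonormalized span (SVD) of its training
features, optionally augmented with the deformation set U_T: per feature
block and per angle, one column constant cos θ over that angle's M-entry
stripe and one constant sin θ, zero elsewhere (2·L columns per block). A
translation (t_x, t_y) of the underlying points changes the feature by
t_x·(cos θ stripe) + t_y·(sin θ stripe) per block, which lies exactly in
span(U_T) — so NS distances, and hence classifications, are invariant to
arbitrary per-eye translations when U_T is included, and provably not
otherwise (both directions are asserted to 1e-8 in the tests). Scaling is not
spanned but is harmless for the decision: subspaces are cones, so a global
scale multiplies all class distances equally. Rotation and shear are not
modeled; they enter as bounded perturbations.

Subspaces are untruncated by default (`energy_tol` = 1.0, directions above
machine-scale singular values kept): training cohorts here are ≤ ~30 per
class, far below the 1536-dimensional ambient space, and data efficiency is
the point of the method. Ties in the argmin go to the lowest class index for
determinism. Label convention: 1 = abnormal eye movement (positive),
0 = normal.

The ensemble trains one NS model per test and fuses hard per-test votes.
ANY-POSITIVE is the default: it is the only simple rule whose sensitivity
dominates, and specificity trails, every individual test — the ordering the
screening setting wants. MAJORITY (ties → positive, favoring sensitivity) and
ALL-POSITIVE are available for sensitivity analyses. Non-compliant tests
abstain rather than vote negative: the compliance gate judges data quality,
not the patient. Soft (distance-level) fusion is a possible extension; hard
voting is implemented.

## Synthetic cohorts

The simulator produces what the screening pipeline consumes: 120 Hz binocular
recordings of the three tests, for normal responders and four abnormal
presentations. Stimuli are deterministic: DOT visits 9 targets spanning the
screen (8 jumps, ~1.1 s dwell); H traces the letter at constant speed through
all four corners of a 1200×600 px box; OKN drifts at 300 px/s right-to-left
then left-to-right for half the duration each. Screen geometry (1920×1080),
dwell times and bar speed are package defaults, not empirical values.

Tracking models: saccades use a main-sequence-style duration (30–120 ms,
growing with amplitude) with a sigmoid position profile and landing point
prev + gain·(target − prev), so gain ≠ 1 yields under/overshoot; pursuit
integrates gain·(target velocity) with catch-up saccades once the error
exceeds a threshold (60 px normal); OKN is a sawtooth — slow phase at the bar
velocity times gain, quick phase resetting past center at ±150 px
eccentricity. Abnormal profiles: DYSCONJUGATE scales one eye's gains by
0.5–0.7 with a constant offset; NYSTAGMUS superimposes a stimulus-independent
sawtooth (slow-phase velocity 60–110 px/s, amplitude 90–150 px, inter-eye
amplitude asymmetry 0.45–0.75); SACCADIC_PURSUIT drops pursuit gain to
0.3–0.45 with hypometric saccades; COMBINED draws two or three signs — 48 %
of abnormal participants, matching the predominance of multi-sign
presentations, with the rest split 20/18/14 % across the single signs.

Noise has three components per axis, all in pixels: conjugate gaze wander
shared by both eyes (Ornstein–Uhlenbeck, sd 55, τ = 2 s — fixational drift of
the binocular gaze point), per-eye independent OU drift (sd 22 normal, 90–130
abnormal — the component that degrades conjugacy), and white per-eye jitter
(sd 8). Blinks arrive at 8–16 per minute, last 100–200 ms, and invalidate
both eyes. The normal-profile noise split was calibrated once so that the
control-group DOT X inter-eye Spearman mean lands in the empirical control
interval 0.976–0.985 for non-calibrated recordings, then frozen; the same
defaults put H X and DOT Y controls in the mid-0.9s and OKN Y controls around
0.7–0.8, the qualitative pattern expected of binocular coordination data.

Uncalibrated-tracker deformation draws **one** affine map per participant
(translation ≤ 200 px, scale 0.8–1.2, rotation ≤ 10°, shear ≤ 0.1) and gives
each eye that map plus a small independent perturbation (10 % of the ranges).
The common map models rig/camera/screen geometry, which both eyes share;
fully independent per-eye draws would rotate the two eyes' coordinate frames
apart by up to ~20°, which structurally caps inter-eye correlation near 0.96
— far below what uncalibrated control recordings actually show — while the
translation component (the part the classifier must absorb) is unaffected by
this choice.

What the simulator does **not** model: oculomotor-plant dynamics, vergence
and torsion, pupil size, head movement, fatigue or attention drift, and
tracker-specific artifacts (e.g. pupil-occlusion transients around blinks
beyond simple dropout). Passing tests on synthetic cohorts therefore
demonstrate the pipeline's mathematical properties and its separation of
clearly expressed oculomotor signs under affine miscalibration — not clinical
performance on real patients, where effect sizes are smaller and presentations
messier.

## Evaluation protocol

Participant-level predictions come from leave-one-participant-out cross
validation (all three tests of the held-out participant leave together, so no
leakage). Metrics are accuracy, sensitivity TP/(TP+FN) and specificity
TN/(TN+FP), summarized by a participant-level nonparametric bootstrap (10,000
replicates, percentile 95 % CIs); replicates that lose a class are skipped
for the affected metric and counted in the output rather than redrawn.
Features are computed once per recording and reused across folds — only the
per-class SVDs are refit — which keeps the full LOO run at seconds.

Inter-eye coordination is the Spearman rank correlation between the left and
right eye series per axis, computed on smoothed recordings (smoothing precedes
all analysis) over samples where both eyes are valid; group means carry
participant-level bootstrap CIs (2,000 replicates). The ablation reruns the
LOO protocol with the deformation set included and excluded (2 variants × 4
rows: Dot, H, OKN, Ensemble). Learning curves draw class-balanced training
subsets of a given size (5 repeats), evaluate on the held-out remainder and
average.

Problem sizes used throughout the tests and the reproduction script — 24
abnormal + 18 control participants, 10 s recordings at 120 Hz, 10,000
bootstrap replicates — are the package's default study conditions.

## Known limitations

- The deformation set spans translations only; large rotations/shears degrade
  gracefully rather than being absorbed.
- Hard voting discards the distance margins; a soft fusion could calibrate
  confidence.
- At the default (clinically marked) synthetic effect sizes the classifier
  saturates near-perfect accuracy, so the with/without-deformation ablation
  contrast shows up in distances, margins and small-seed variation rather
  than in large accuracy gaps.
- Binary classes only; distinguishing abnormality subtypes is out of scope.
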