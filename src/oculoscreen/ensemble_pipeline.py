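"""Per-test DRCDT-NS models fused into one binary screening decision.

Each ocular motor test (Dot, H, OKN) probes a different abnormality —
saccade accuracy, pursuit smoothness, optokinetic reflexes — so the
pipeline trains one nearest-subspace model per test and combines the
three per-test labels into a single diagnosis.  The default fusion rule
is ANY-POSITIVE: a participant screens positive when at least one test
does, trading specificity for the sensitivity clinicians prioritize in
stroke triage.  Non-compliant recordings abstain and drop out of the
vote rather than counting as negative.

Class convention: label 1 = abnormal eye movement (positive),
label 0 = normal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .drcdt import AngleGrid, binocular_feature
from .gaze_model import GazeRecording, Test, check_compliance, smooth_recording, to_point_sets
from .ns_classifier import NSModel, classify, fit_ns_model

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "FusionRule",
    "TestPrediction",
    "EnsembleDiagnosis",
    "featurize_recording",
    "fit_ensemble",
    "predict_participant",
]

POSITIVE = 1
NEGATIVE = 0


class FusionRule(str, enum.Enum):
    ANY_POSITIVE = "any"
    MAJORITY = "majority"
    ALL_POSITIVE = "all"


@dataclass(frozen=True)
class TestPrediction:
    """One per-test vote; ``label`` is None when the test abstains."""

    test: Test
    label: int | None
    distances: dict[int, float]
    compliant: bool


@dataclass(frozen=True)
class EnsembleDiagnosis:
    participant_id: str
    per_test: dict[Test, TestPrediction]
    final: int
    rule: FusionRule


def featurize_recording(rec: GazeRecording, config: PipelineConfig) -> np.ndarray | None:
    """Raw recording -> composite DRCDT feature, or None if non-compliant.

    Compliance is checked on the raw validity flags; compliant
    recordings are smoothed, split into per-eye and disparity point
    sets, and embedded.
    """
    report = check_compliance(rec, config.compliance_threshold)
    if not report.passed:
        return None
    sm = smooth_recording(rec, config.smooth_window, config.smooth_polyorder,
                          config.max_gap_s)
    left, right, disparity = to_point_sets(sm)
    grid = AngleGrid.uniform(config.n_angles)
    return binocular_feature(left, right, disparity, grid, config.n_quantiles,
                             include_disparity=config.include_disparity)


def fit_ensemble(
    cohort: dict[Test, list[tuple[int, GazeRecording]]],
    config: PipelineConfig | None = None,
) -> dict[Test, NSModel]:
    """Train one NS model per test from labeled recordings.

    ``cohort`` maps each test to (label, recording) pairs.  Every test
    must retain at least one compliant recording per class; a deficit is
    reported naming the offending test and class.
    """
    config = config or PipelineConfig()
    grid = AngleGrid.uniform(config.n_angles)
    models: dict[Test, NSModel] = {}
    for test, pairs in cohort.items():
        feats: dict[int, list[np.ndarray]] = {NEGATIVE: [], POSITIVE: []}
        for label, rec in pairs:
            f = featurize_recording(rec, config)
            if f is not None:
                feats[int(label)].append(f)
        deficits = [k for k, fs in feats.items() if not fs]
        if deficits:
            raise ValueError(
                f"test {Test(test).value}: no compliant training recordings "
                f"for class(es) {deficits}"
            )
        models[Test(test)] = fit_ns_model(
            feats, grid, config.n_quantiles, config.n_blocks,
            deformation=config.deformation, energy_tol=config.energy_tol,
        )
    return models


def _fuse(labels: list[int], rule: FusionRule) -> int:
    """Combine non-abstaining per-test labels into the final diagnosis."""
    if rule is FusionRule.ANY_POSITIVE:
        return POSITIVE if any(l == POSITIVE for l in labels) else NEGATIVE
    if rule is FusionRule.ALL_POSITIVE:
        return POSITIVE if all(l == POSITIVE for l in labels) else NEGATIVE
    pos = sum(1 for l in labels if l == POSITIVE)
    neg = len(labels) - pos
    # tie -> positive: screening favors sensitivity
    return POSITIVE if pos >= neg else NEGATIVE


def predict_participant(
    recordings: dict[Test, GazeRecording],
    models: dict[Test, NSModel],
    config: PipelineConfig | None = None,
    rule: FusionRule | str | None = None,
) -> EnsembleDiagnosis:
    """Run the three per-test models on one participant and fuse the votes.

    Non-compliant recordings (and tests with no recording) abstain.  At
    least one test must cast a vote; otherwise the participant is
    undiagnosable and an error is raised.
    """
    config = config or PipelineConfig()
    rule = FusionRule(rule) if rule is not None else FusionRule(config.rule)
    pid = next(iter(recordings.values())).participant_id
    per_test: dict[Test, TestPrediction] = {}
    votes: list[int] = []
    for test in sorted(models, key=lambda t: t.value):
        rec = recordings.get(test)
        if rec is None:
            continue
        f = featurize_recording(rec, config)
        if f is None:
            per_test[test] = TestPrediction(test, None, {}, compliant=False)
            continue
        label, dists = classify(f, models[test])
        per_test[test] = TestPrediction(test, label, dists, compliant=True)
        votes.append(label)
    if not votes:
        raise ValueError(f"participant {pid}: no compliant recording, undiagnosable")
    return EnsembleDiagnosis(
        participant_id=pid,
        per_test=per_test,
        final=_fuse(votes, rule),
        rule=rule,
    )
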