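"""Evaluation protocol: LOO predictions, bootstrap metrics, correlations.

Participant-level predictions come from leave-one-participant-out cross
validation (all three of a participant's tests are held out together, so
nothing leaks across folds).  Diagnostic metrics — accuracy, sensitivity
TP/(TP+FN), specificity TN/(TN+FP) — are summarized with a
participant-level nonparametric bootstrap (resample participants with
replacement; percentile 95% CIs).  Replicates that lose a class are
skipped for the affected metric and counted.  The module also computes
the inter-eye Spearman coordination table per test and axis, the
with/without-deformation ablation, and data-efficiency learning curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .config import PipelineConfig
from .drcdt import AngleGrid
from .ensemble_pipeline import NEGATIVE, POSITIVE, FusionRule, _fuse, featurize_recording
from .gaze_model import Test, smooth_recording
from .ns_classifier import classify, fit_ns_model
from .synthetic_gaze import Cohort

__all__ = [
    "MetricSummary",
    "confusion_metrics",
    "bootstrap_metrics",
    "cohort_features",
    "loo_predictions",
    "inter_eye_correlation",
    "learning_curve",
    "ablation_run",
]

METRICS = ("accuracy", "sensitivity", "specificity")


@dataclass(frozen=True)
class MetricSummary:
    metric: str
    mean: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if np.isnan(self.mean):  # metric undefined in every replicate
            return
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("CI must bracket the mean")


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Accuracy, sensitivity and specificity of binary predictions.

    A metric whose denominator class is absent is reported as NaN.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("need equal-length nonempty label arrays")
    tp = int(np.sum((y_true == POSITIVE) & (y_pred == POSITIVE)))
    fn = int(np.sum((y_true == POSITIVE) & (y_pred == NEGATIVE)))
    tn = int(np.sum((y_true == NEGATIVE) & (y_pred == NEGATIVE)))
    fp = int(np.sum((y_true == NEGATIVE) & (y_pred == POSITIVE)))
    return {
        "accuracy": (tp + tn) / y_true.size,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def bootstrap_metrics(preds: pd.DataFrame, pred_col: str = "ensemble",
                      n_boot: int = 10_000, seed: int = 0) -> dict[str, MetricSummary]:
    """Participant-level bootstrap of the three diagnostic metrics.

    ``preds`` has one row per participant with columns ``y_true`` and
    ``pred_col``.  Each replicate resamples participants with
    replacement; replicates lacking a class are skipped for the affected
    metric and counted in ``n_skipped``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if preds.empty:
        raise ValueError("empty prediction set")
    y = preds["y_true"].to_numpy(int)
    p = preds[pred_col].to_numpy(int)
    rng = np.random.default_rng(seed)
    n = y.size
    samples: dict[str, list[float]] = {m: [] for m in METRICS}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        vals = confusion_metrics(y[idx], p[idx])
        for m in METRICS:
            if not np.isnan(vals[m]):
                samples[m].append(vals[m])
    out = {}
    for m in METRICS:
        arr = np.asarray(samples[m])
        if arr.size == 0:
            out[m] = MetricSummary(m, float("nan"), float("nan"), float("nan"),
                                   n_boot, n_boot)
            continue
        lo, hi = np.percentile(arr, [2.5, 97.5])
        out[m] = MetricSummary(m, float(arr.mean()), float(lo), float(hi),
                               n_boot, n_boot - arr.size)
    return out


def cohort_features(cohort: Cohort, config: PipelineConfig) -> pd.DataFrame:
    """Featurize every recording once: one row per (participant, test).

    Columns: participant_id, label, test, feature (ndarray or None for
    non-compliant recordings).  Computing features up front lets LOO,
    learning-curve and ablation runs refit subspaces cheaply.
    """
    rows = []
    for p in cohort.participants:
        for test, rec in p.recordings.items():
            rows.append({
                "participant_id": p.participant_id,
                "label": p.label,
                "test": test,
                "feature": featurize_recording(rec, config),
            })
    return pd.DataFrame(rows)


def _predict_from_features(
    feats: pd.DataFrame, train_pids: set[str], test_pids: list[str],
    config: PipelineConfig, deformation: bool,
) -> pd.DataFrame:
    """Fit per-test NS models on ``train_pids``, predict ``test_pids``."""
    grid = AngleGrid.uniform(config.n_angles)
    models = {}
    for test in Test:
        sub = feats[(feats["test"] == test)
                    & feats["participant_id"].isin(train_pids)
                    & feats["feature"].notna()]
        by_class = {
            NEGATIVE: list(sub[sub["label"] == NEGATIVE]["feature"]),
            POSITIVE: list(sub[sub["label"] == POSITIVE]["feature"]),
        }
        models[test] = fit_ns_model(by_class, grid, config.n_quantiles,
                                    config.n_blocks, deformation=deformation,
                                    energy_tol=config.energy_tol)
    rule = FusionRule(config.rule)
    rows = []
    for pid in test_pids:
        prow = {"participant_id": pid}
        votes = []
        sub = feats[feats["participant_id"] == pid]
        prow["y_true"] = int(sub["label"].iloc[0])
        for test in Test:
            frow = sub[sub["test"] == test]
            f = frow["feature"].iloc[0] if len(frow) else None
            if f is None:
                prow[test.value.lower()] = -1  # abstain
                continue
            label, _ = classify(f, models[test])
            prow[test.value.lower()] = label
            votes.append(label)
        prow["ensemble"] = _fuse(votes, rule) if votes else -1
        rows.append(prow)
    return pd.DataFrame(rows)


def loo_predictions(cohort: Cohort, config: PipelineConfig | None = None,
                    deformation: bool | None = None,
                    feats: pd.DataFrame | None = None) -> pd.DataFrame:
    """Leave-one-participant-out predictions for a whole cohort.

    Returns one row per participant: true label, per-test labels
    (-1 = abstained) and the fused ensemble label.
    """
    config = config or PipelineConfig()
    if deformation is None:
        deformation = config.deformation
    if feats is None:
        feats = cohort_features(cohort, config)
    pids = [p.participant_id for p in cohort.participants]
    parts = []
    for pid in pids:
        parts.append(_predict_from_features(
            feats, set(pids) - {pid}, [pid], config, deformation))
    return pd.concat(parts, ignore_index=True)


def inter_eye_correlation(cohort: Cohort, n_boot: int = 2000,
                          seed: int = 0,
                          config: PipelineConfig | None = None) -> pd.DataFrame:
    """Left-right Spearman coordination per test, axis and group.

    Recordings first pass through the standard smoothing post-processing;
    per recording, the rank correlation between the left and right eye
    coordinate series on each axis is taken over samples where both eyes
    are valid.  Group means carry participant-level bootstrap 95% CIs.
    Recordings with a constant series are excluded and counted.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    smoothed = {
        (p.participant_id, test): smooth_recording(
            rec, config.smooth_window, config.smooth_polyorder, config.max_gap_s)
        for p in cohort.participants for test, rec in p.recordings.items()
    }
    rows = []
    for test in Test:
        for axis_i, axis in enumerate("xy"):
            for group, label in (("control", 0), ("patient", 1)):
                rhos = []
                n_excluded = 0
                for p in cohort.participants:
                    if p.label != label:
                        continue
                    rec = smoothed[(p.participant_id, test)]
                    both = rec.left_valid & rec.right_valid
                    lx = rec.left[both, axis_i]
                    rx = rec.right[both, axis_i]
                    if both.sum() < 3 or np.ptp(lx) == 0 or np.ptp(rx) == 0:
                        n_excluded += 1
                        continue
                    rhos.append(spearmanr(lx, rx).statistic)
                rhos = np.asarray(rhos)
                if rhos.size == 0:
                    continue
                boot = np.array([
                    rhos[rng.integers(0, rhos.size, rhos.size)].mean()
                    for _ in range(n_boot)
                ])
                lo, hi = np.percentile(boot, [2.5, 97.5])
                rows.append({
                    "test": test.value, "axis": axis.upper(), "group": group,
                    "mean": float(rhos.mean()), "ci_low": float(lo),
                    "ci_high": float(hi), "n": int(rhos.size),
                    "n_excluded": n_excluded,
                })
    return pd.DataFrame(rows)


def learning_curve(cohort: Cohort, train_sizes: list[int], k_repeats: int = 5,
                   seed: int = 0, config: PipelineConfig | None = None,
                   feats: pd.DataFrame | None = None) -> pd.DataFrame:
    """Ensemble accuracy vs per-class training-set size.

    For each size n, draw ``k_repeats`` class-balanced training subsets
    of n participants per class, fit the ensemble, evaluate on the
    held-out participants and average.
    """
    config = config or PipelineConfig()
    if feats is None:
        feats = cohort_features(cohort, config)
    pos = [p.participant_id for p in cohort.participants if p.label == POSITIVE]
    neg = [p.participant_id for p in cohort.participants if p.label == NEGATIVE]
    rng = np.random.default_rng(seed)
    rows = []
    for size in train_sizes:
        if size > min(len(pos), len(neg)) - 1:
            raise ValueError(f"training size {size} leaves no held-out participants")
        accs = []
        for _ in range(k_repeats):
            train = set(rng.choice(pos, size, replace=False)) | set(
                rng.choice(neg, size, replace=False))
            held = [pid for pid in pos + neg if pid not in train]
            preds = _predict_from_features(feats, train, held, config,
                                           config.deformation)
            accs.append(confusion_metrics(preds["y_true"], preds["ensemble"])
                        ["accuracy"])
        rows.append({"train_size_per_class": size,
                     "accuracy_mean": float(np.mean(accs)),
                     "accuracy_sd": float(np.std(accs)),
                     "k_repeats": k_repeats})
    return pd.DataFrame(rows)


def ablation_run(cohort: Cohort, seed: int = 0,
                 config: PipelineConfig | None = None,
                 feats: pd.DataFrame | None = None) -> pd.DataFrame:
    """LOO metrics with and without deformation modeling.

    Emits exactly 2 variants x 4 rows (Dot, H, OKN, Ensemble) with the
    three diagnostic metrics per row.
    """
    config = config or PipelineConfig()
    if feats is None:
        feats = cohort_features(cohort, config)
    rows = []
    for variant, deform in (("DRCDT-NS", False), ("DRCDT-NS+deformation", True)):
        preds = loo_predictions(cohort, config, deformation=deform, feats=feats)
        for name, col in (("Dot", "dot"), ("H", "h"), ("OKN", "okn"),
                          ("Ensemble", "ensemble")):
            sub = preds[preds[col] >= 0]
            vals = confusion_metrics(sub["y_true"], sub[col])
            rows.append({"variant": variant, "test": name, **vals})
    return pd.DataFrame(rows)
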