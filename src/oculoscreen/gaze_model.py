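"""Binocular gaze recordings: domain types, compliance gating, smoothing.

A recording is a timestamped sequence of binocular gaze samples as an
uncalibrated screen-based eye tracker emits them: left and right eye
coordinates in tracker units with per-eye validity flags (an eye the
tracker lost — during a blink, say — is marked invalid, never zero).

The preprocessing chain mirrors a bedside acquisition protocol: a
recording is usable when the tracker detected at least one eye and
captured at least 90% of samples; usable recordings are smoothed with a
Savitzky-Golay filter to suppress blink artifacts and sensor jitter, then
converted into per-eye 2-D point sets (plus a left-minus-right disparity
set encoding conjugacy) for the transform stage.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .drcdt import PointSet

__all__ = [
    "Test",
    "GazeSample",
    "GazeRecording",
    "ComplianceReport",
    "check_compliance",
    "smooth_recording",
    "to_point_sets",
    "read_recording_csv",
    "write_recording_csv",
]

CSV_COLUMNS = ["participant_id", "test", "t", "lx", "ly", "rx", "ry", "lvalid", "rvalid"]


class Test(str, enum.Enum):
    """The three computer-adapted ocular motor examinations."""

    DOT = "DOT"  # volitional saccades between jumping fixation dots
    H = "H"      # smooth pursuit of a target tracing the letter H
    OKN = "OKN"  # optokinetic nystagmus elicited by drifting bars


class GazeSample(NamedTuple):
    """One binocular sample; invalid eyes carry NaN coordinates."""

    t: float
    left: tuple[float, float]
    right: tuple[float, float]
    left_valid: bool
    right_valid: bool


@dataclass
class GazeRecording:
    """One participant x one test, as column arrays.

    ``left``/``right`` are (N, 2) float arrays in tracker units; invalid
    samples hold NaN.  ``left_imputed``/``right_imputed`` mark samples
    whose coordinates were filled in by preprocessing (short-gap
    interpolation); they start all-False on raw recordings.
    """

    participant_id: str
    test: Test
    rate_hz: float
    t: np.ndarray
    left: np.ndarray
    right: np.ndarray
    left_valid: np.ndarray
    right_valid: np.ndarray
    left_imputed: np.ndarray = None  # type: ignore[assignment]
    right_imputed: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.test = Test(self.test)
        self.t = np.asarray(self.t, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.left_valid = np.asarray(self.left_valid, dtype=bool)
        self.right_valid = np.asarray(self.right_valid, dtype=bool)
        n = self.t.size
        if n < 2:
            raise ValueError("a recording needs at least 2 samples")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(self.t)) or self.t[0] < 0:
            raise ValueError("timestamps must be finite and non-negative")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        for name in ("left", "right"):
            arr = getattr(self, name)
            if arr.shape != (n, 2):
                raise ValueError(f"{name} must have shape (N, 2)")
        # invalid coordinates are missing, never silently numeric
        self.left = self.left.copy()
        self.right = self.right.copy()
        self.left[~self.left_valid] = np.nan
        self.right[~self.right_valid] = np.nan
        if self.left_imputed is None:
            self.left_imputed = np.zeros(n, dtype=bool)
        if self.right_imputed is None:
            self.right_imputed = np.zeros(n, dtype=bool)
        self.left_imputed = np.asarray(self.left_imputed, dtype=bool)
        self.right_imputed = np.asarray(self.right_imputed, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.t.size

    def samples(self) -> list[GazeSample]:
        return [
            GazeSample(
                float(self.t[k]),
                (float(self.left[k, 0]), float(self.left[k, 1])),
                (float(self.right[k, 0]), float(self.right[k, 1])),
                bool(self.left_valid[k]),
                bool(self.right_valid[k]),
            )
            for k in range(self.n_samples)
        ]


@dataclass(frozen=True)
class ComplianceReport:
    """Outcome of the acquisition-protocol gate."""

    capture_fraction: float
    any_eye_detected: bool
    passed: bool


def check_compliance(rec: GazeRecording, threshold: float = 0.90) -> ComplianceReport:
    """Apply the acquisition gate: >=1 eye detected and enough capture.

    ``capture_fraction`` is the fraction of samples with at least one
    valid eye; the comparison with ``threshold`` is inclusive.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    either = rec.left_valid | rec.right_valid
    frac = float(either.mean())
    any_eye = bool(rec.left_valid.any() or rec.right_valid.any())
    return ComplianceReport(
        capture_fraction=frac,
        any_eye_detected=any_eye,
        passed=any_eye and frac >= threshold,
    )


def _fill_gaps(t: np.ndarray, coords: np.ndarray, valid: np.ndarray,
               max_gap_s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate invalid runs over time.

    Returns (filled coords, imputed mask, excluded mask).  Runs longer
    than ``max_gap_s`` and runs touching the recording edges are still
    filled (the filter needs finite input) but marked excluded so they
    never enter a point set.
    """
    coords = coords.copy()
    imputed = np.zeros(t.size, dtype=bool)
    excluded = np.zeros(t.size, dtype=bool)
    if valid.all():
        return coords, imputed, excluded
    idx_valid = np.flatnonzero(valid)
    for dim in range(2):
        coords[~valid, dim] = np.interp(t[~valid], t[idx_valid], coords[idx_valid, dim])
    # classify each invalid run
    inv = ~valid
    edges = np.flatnonzero(np.diff(np.concatenate(([0], inv.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        run_t = t[stop - 1] - t[start] + (t[1] - t[0])
        interior = start > 0 and stop < t.size
        if interior and run_t <= max_gap_s:
            imputed[start:stop] = True
        else:
            excluded[start:stop] = True
    return coords, imputed, excluded


def smooth_recording(rec: GazeRecording, window: int = 31, polyorder: int = 3,
                     max_gap_s: float = 0.25) -> GazeRecording:
    """Savitzky-Golay smooth each coordinate channel of a recording.

    Invalid samples are first gap-filled by linear interpolation over t;
    the four coordinate channels are then filtered independently.  The
    returned recording has identical length and timestamps; originally
    valid flags are preserved and interpolated samples are flagged
    imputed.  An eye with no valid sample at all is left missing
    (monocular path); a recording with neither eye ever valid is
    rejected.
    """
    if window < polyorder + 1:
        raise ValueError("window must be at least polyorder + 1")
    if window > rec.n_samples:
        raise ValueError("recording shorter than smoothing window")
    if not (rec.left_valid.any() or rec.right_valid.any()):
        raise ValueError("no valid samples in either eye")

    out = {}
    for eye in ("left", "right"):
        valid = getattr(rec, f"{eye}_valid")
        coords = getattr(rec, eye)
        if not valid.any():
            out[eye] = (coords.copy(), np.zeros(rec.n_samples, bool), valid.copy())
            continue
        filled, imputed, excluded = _fill_gaps(rec.t, coords, valid, max_gap_s)
        smoothed = savgol_filter(filled, window, polyorder, axis=0, mode="interp")
        # excluded (long-gap / edge) samples stay invalid
        new_valid = valid | imputed
        smoothed[~new_valid] = np.nan
        out[eye] = (smoothed, imputed & ~excluded, new_valid & ~excluded)

    sm = GazeRecording(
        participant_id=rec.participant_id,
        test=rec.test,
        rate_hz=rec.rate_hz,
        t=rec.t.copy(),
        left=out["left"][0],
        right=out["right"][0],
        left_valid=out["left"][2],
        right_valid=out["right"][2],
        left_imputed=out["left"][1],
        right_imputed=out["right"][1],
    )
    return sm


def to_point_sets(rec: GazeRecording) -> tuple[PointSet, PointSet, PointSet]:
    """Convert a smoothed, compliant recording into point sets.

    Returns ``(left, right, disparity)`` where each per-eye set collects
    the valid-or-imputed 2-D coordinates and ``disparity`` is the
    multiset of left-minus-right differences over samples where both
    eyes are present — the explicit conjugacy signal.  A fully missing
    eye yields an empty set for that eye and an empty disparity set.
    """
    lmask = rec.left_valid
    rmask = rec.right_valid
    both = lmask & rmask
    left = PointSet(rec.left[lmask]) if lmask.any() else PointSet.empty()
    right = PointSet(rec.right[rmask]) if rmask.any() else PointSet.empty()
    if both.any() and lmask.any() and rmask.any():
        disparity = PointSet(rec.left[both] - rec.right[both])
    else:
        disparity = PointSet.empty()
    return left, right, disparity


def write_recording_csv(rec: GazeRecording, path: str | Path) -> None:
    """Write one recording in the documented gaze CSV dialect.

    Header ``participant_id,test,t,lx,ly,rx,ry,lvalid,rvalid``; missing
    coordinates are empty fields; one recording per file.
    """
    df = pd.DataFrame(
        {
            "participant_id": rec.participant_id,
            "test": rec.test.value,
            "t": rec.t,
            "lx": rec.left[:, 0],
            "ly": rec.left[:, 1],
            "rx": rec.right[:, 0],
            "ry": rec.right[:, 1],
            "lvalid": rec.left_valid.astype(int),
            "rvalid": rec.right_valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g", columns=CSV_COLUMNS)


def read_recording_csv(path: str | Path, rate_hz: float = 120.0) -> GazeRecording:
    """Read one recording written by :func:`write_recording_csv`."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gaze CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"empty gaze CSV: {path}")
    pid = str(df["participant_id"].iloc[0])
    test = Test(str(df["test"].iloc[0]))
    return GazeRecording(
        participant_id=pid,
        test=test,
        rate_hz=rate_hz,
        t=df["t"].to_numpy(float),
        left=df[["lx", "ly"]].to_numpy(float),
        right=df[["rx", "ry"]].to_numpy(float),
        left_valid=df["lvalid"].to_numpy(bool),
        right_valid=df["rvalid"].to_numpy(bool),
    )
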