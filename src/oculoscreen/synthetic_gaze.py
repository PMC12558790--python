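"""Synthetic binocular eye-tracker recordings for the three ocular motor tests.

The simulator emulates what a 120 Hz screen-based tracker returns while a
participant performs the computer-adapted Dot (volitional saccades), H
(smooth pursuit) and OKN (optokinetic nystagmus) examinations.  It
produces normal responses and four abnormal response classes seen with
central (brainstem/cerebellar) lesions:

* DYSCONJUGATE — the two eyes no longer move together: one eye tracks
  with reduced gain and a constant offset, widening the left-minus-right
  disparity distribution.
* NYSTAGMUS — a stimulus-independent sawtooth (slow drift plus quick
  resetting phase) superimposed on both eyes, with inter-eye amplitude
  asymmetry.
* SACCADIC_PURSUIT — smooth pursuit gain far below one, compensated by
  catch-up saccades, plus hypometric volitional saccades.
* COMBINED — two or more of the above signs at once, the most common
  clinical presentation.

Every trace carries per-eye Gaussian jitter, slow per-eye drift
(Ornstein-Uhlenbeck), and blink dropouts marked invalid.  Because the
tracker is uncalibrated, each eye's output is finally passed through a
random affine deformation (translation, scaling, rotation, shearing).
All randomness flows from a single seed; cohorts are bit-reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gaze_model import GazeRecording, Test, write_recording_csv

__all__ = [
    "SCREEN_W",
    "SCREEN_H",
    "Condition",
    "StimulusTrace",
    "ResponderProfile",
    "AffineMap",
    "DeformationParams",
    "CohortConfig",
    "Participant",
    "Cohort",
    "make_stimulus",
    "simulate_response",
    "apply_deformation",
    "generate_cohort",
]

SCREEN_W = 1920.0
SCREEN_H = 1080.0
_CENTER = np.array([SCREEN_W / 2, SCREEN_H / 2])


class Condition(str, enum.Enum):
    NORMAL = "NORMAL"
    DYSCONJUGATE = "DYSCONJUGATE"
    NYSTAGMUS = "NYSTAGMUS"
    SACCADIC_PURSUIT = "SACCADIC_PURSUIT"
    COMBINED = "COMBINED"


# ---------------------------------------------------------------------------
# stimuli


@dataclass(frozen=True)
class StimulusTrace:
    """Target positions over time for one test.

    For DOT the positions are piecewise constant (discrete target
    jumps); for H a continuous constant-speed path tracing the letter;
    for OKN the drifting bar-field phase, one constant-velocity segment
    per direction.
    """

    test: Test
    t: np.ndarray
    positions: np.ndarray  # (N, 2) pixels
    meta: dict = field(default_factory=dict)

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


# Dot-test target sequence: jumps span horizontal, vertical and oblique
# displacements across the screen (margins keep dots comfortably on-screen).
_DOT_TARGETS = np.array(
    [
        [960, 540],
        [360, 540],
        [1560, 540],
        [960, 240],
        [960, 840],
        [360, 240],
        [1560, 840],
        [1560, 240],
        [360, 840],
    ],
    dtype=float,
)

# H-test box and waypoint path: left stroke, crossbar, right stroke,
# visiting all four corners (cardinal directions and quadrants).
_H_BOX = {"xmin": 360.0, "xmax": 1560.0, "ytop": 240.0, "ybot": 840.0}
_H_WAYPOINTS = np.array(
    [
        [960, 540],
        [360, 540],
        [360, 240],
        [360, 840],
        [360, 540],
        [1560, 540],
        [1560, 240],
        [1560, 840],
    ],
    dtype=float,
)


def make_stimulus(test: Test | str, duration_s: float = 10.0, rate_hz: float = 120.0,
                  okn_speed: float = 300.0) -> StimulusTrace:
    """Build the deterministic target trace for one test.

    DOT: equal dwell on each of 9 targets (8 jumps).  H: constant-speed
    traversal of the H waypoint path.  OKN: two constant-velocity bar
    phases, right-to-left then left-to-right, at ``okn_speed`` px/s.
    """
    test = Test(test)
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    if test is Test.DOT:
        dwell = duration_s / len(_DOT_TARGETS)
        idx = np.minimum((t / dwell).astype(int), len(_DOT_TARGETS) - 1)
        pos = _DOT_TARGETS[idx]
        return StimulusTrace(test, t, pos, {"dwell_s": dwell, "targets": _DOT_TARGETS})
    if test is Test.H:
        seg = np.diff(_H_WAYPOINTS, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        s = t / duration_s * cum[-1]  # arc length, constant speed
        pos = np.empty((n, 2))
        for d in range(2):
            pos[:, d] = np.interp(s, cum, _H_WAYPOINTS[:, d])
        return StimulusTrace(test, t, pos, {"box": dict(_H_BOX)})
    if test is Test.OKN:
        half = duration_s / 2
        vel = np.where(t < half, -okn_speed, okn_speed)
        phase = np.concatenate([[0.0], np.cumsum(vel[:-1] / rate_hz)])
        pos = np.column_stack([_CENTER[0] + phase, np.full(n, _CENTER[1])])
        return StimulusTrace(test, t, pos, {"speed": okn_speed,
                                            "segment_velocities": (-okn_speed, okn_speed)})
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# responder profiles


@dataclass(frozen=True)
class ResponderProfile:
    """Oculomotor parameters of one simulated participant.

    Gains are dimensionless in (0, 1.5]; velocities and amplitudes in
    pixels(/s).  Three noise components per axis: ``wander_sd`` is slow
    conjugate gaze wander shared by both eyes (fixational drift of the
    binocular gaze point), ``drift_sd`` is slow per-eye independent
    drift (tracker/ocular instability that breaks conjugacy), and
    ``noise_sd`` is white per-eye tracker jitter.  All are stationary
    standard deviations in pixels; the slow components are
    Ornstein-Uhlenbeck processes with the given time constants.
    """

    condition: Condition
    saccade_gain: tuple[float, float] = (0.98, 0.98)
    pursuit_gain: tuple[float, float] = (0.95, 0.95)
    saccade_latency_ms: float = 200.0
    catchup_threshold_px: float = 60.0
    nystagmus_slow_velocity: float = 0.0   # px/s, 0 disables
    nystagmus_amplitude: float = 120.0     # px, sawtooth reset amplitude
    nystagmus_axis: float = 0.0            # radians, 0 = horizontal
    nystagmus_eye_asymmetry: float = 1.0   # right-eye amplitude factor
    inter_eye_offset: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 8.0
    drift_sd: float = 22.0
    drift_tau_s: float = 1.0
    wander_sd: float = 55.0
    wander_tau_s: float = 2.0
    blink_rate_per_min: float = 12.0
    blink_duration_s: tuple[float, float] = (0.10, 0.20)

    def __post_init__(self) -> None:
        for g in (*self.saccade_gain, *self.pursuit_gain):
            if not 0 < g <= 1.5:
                raise ValueError("gains must lie in (0, 1.5]")
        if self.saccade_latency_ms < 0 or self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("latency and noise parameters must be non-negative")

    @classmethod
    def sample(cls, condition: Condition | str, rng: np.random.Generator) -> "ResponderProfile":
        """Draw a participant-level profile for a condition.

        Normal participants get near-unity, nearly symmetric gains;
        abnormal participants get the condition's signature deficit plus
        the elevated inter-eye drift seen with impaired binocular
        coordination.
        """
        condition = Condition(condition)
        base = dict(
            saccade_latency_ms=float(rng.uniform(170, 230)),
            blink_rate_per_min=float(rng.uniform(8, 16)),
        )
        if condition is Condition.NORMAL:
            g = rng.uniform(0.94, 1.02)
            p = rng.uniform(0.90, 1.00)
            return cls(condition=condition,
                       saccade_gain=(g + rng.normal(0, 0.01), g + rng.normal(0, 0.01)),
                       pursuit_gain=(p + rng.normal(0, 0.01), p + rng.normal(0, 0.01)),
                       **base)

        signs = {condition}
        if condition is Condition.COMBINED:
            signs = set(rng.choice(
                [Condition.DYSCONJUGATE, Condition.NYSTAGMUS, Condition.SACCADIC_PURSUIT],
                size=rng.integers(2, 4), replace=False))

        kw: dict = dict(base, drift_sd=float(rng.uniform(90, 130)))
        sg = rng.uniform(0.92, 1.0)
        pg = rng.uniform(0.88, 0.98)
        kw["saccade_gain"] = (sg, sg)
        kw["pursuit_gain"] = (pg, pg)
        if Condition.DYSCONJUGATE in signs:
            weak = float(rng.uniform(0.50, 0.70))  # paretic-eye gain factor
            side = int(rng.integers(2))
            sgain = [sg, sg]
            pgain = [pg, pg]
            sgain[side] *= weak
            pgain[side] *= weak
            kw["saccade_gain"] = tuple(sgain)
            kw["pursuit_gain"] = tuple(pgain)
            kw["inter_eye_offset"] = tuple(rng.uniform(-60, 60, size=2))
        if Condition.NYSTAGMUS in signs:
            kw["nystagmus_slow_velocity"] = float(rng.uniform(60, 110))
            kw["nystagmus_amplitude"] = float(rng.uniform(90, 150))
            kw["nystagmus_axis"] = float(rng.uniform(-0.35, 0.35))
            kw["nystagmus_eye_asymmetry"] = float(rng.uniform(0.45, 0.75))
        if Condition.SACCADIC_PURSUIT in signs:
            kw["pursuit_gain"] = tuple(g * rng.uniform(0.30, 0.45) / pg
                                       for g in kw["pursuit_gain"])
            kw["saccade_gain"] = tuple(g * 0.85 for g in kw["saccade_gain"])
            kw["catchup_threshold_px"] = float(rng.uniform(80, 120))
        return cls(condition=condition, **kw)


# ---------------------------------------------------------------------------
# tracking models (one eye, noiseless)


def _sigmoid_profile(n: int) -> np.ndarray:
    """Smooth 0->1 saccade position profile over n samples."""
    x = np.linspace(-3.0, 3.0, n)
    s = 1.0 / (1.0 + np.exp(-x))
    return (s - s[0]) / (s[-1] - s[0])


def _saccade_duration_s(amplitude_px: float) -> float:
    # main-sequence-style: duration grows with amplitude, saturating
    return min(0.03 + 1e-4 * amplitude_px, 0.12)


def _track_dot(stim: StimulusTrace, gain: float, latency_s: float) -> np.ndarray:
    t, target = stim.t, stim.positions
    rate = stim.rate_hz
    pos = np.empty_like(target)
    cur = target[0].copy()
    jumps = np.flatnonzero(np.any(np.diff(target, axis=0) != 0, axis=1)) + 1
    k = 0
    events = list(jumps) + [len(t)]
    pos[: events[0]] = cur
    for e_i, jump in enumerate(jumps):
        tgt = target[jump]
        land = cur + gain * (tgt - cur)
        start = jump + int(round(latency_s * rate))
        dur_n = max(2, int(round(_saccade_duration_s(np.linalg.norm(tgt - cur)) * rate)))
        stop = min(start + dur_n, len(t))
        nxt = events[e_i + 1]
        if start >= len(t):
            pos[jump:] = cur
            break
        pos[jump:start] = cur
        prof = _sigmoid_profile(stop - start)[:, None]
        pos[start:stop] = cur + prof * (land - cur)
        pos[stop:nxt] = land
        cur = land
    return pos


def _track_pursuit(stim: StimulusTrace, pursuit_gain: float, saccade_gain: float,
                   latency_s: float, catchup_px: float) -> np.ndarray:
    """Pursuit with gain < 1 plus catch-up saccades on large error."""
    t, target = stim.t, stim.positions
    rate = stim.rate_hz
    lag = int(round(latency_s * rate))
    delayed = np.roll(target, lag, axis=0)
    delayed[:lag] = target[0]
    vel = np.vstack([[0.0, 0.0], np.diff(delayed, axis=0)])
    pos = np.empty_like(target)
    cur = target[0].astype(float).copy()
    for k in range(len(t)):
        cur = cur + pursuit_gain * vel[k]
        err = delayed[k] - cur
        if np.linalg.norm(err) > catchup_px:
            cur = cur + saccade_gain * err  # catch-up saccade (fast: 1 sample)
        pos[k] = cur
    return pos


def _track_okn(stim: StimulusTrace, okn_gain: float, reset_px: float = 150.0) -> np.ndarray:
    """Optokinetic sawtooth: slow phase follows the bar drift, quick
    phase resets the eye once it strays ``reset_px`` from center."""
    t = stim.t
    vel = np.vstack([[0.0, 0.0], np.diff(stim.positions, axis=0)])
    pos = np.empty_like(stim.positions)
    x = _CENTER[0]
    for k in range(len(t)):
        x = x + okn_gain * vel[k, 0]
        dev = x - _CENTER[0]
        if abs(dev) > reset_px:
            # quick phase: near-instant reset past center
            x = _CENTER[0] - 0.25 * np.sign(dev) * reset_px
        pos[k, 0] = x
        pos[k, 1] = _CENTER[1]
    return pos


def _nystagmus_wave(t: np.ndarray, slow_vel: float, amplitude: float) -> np.ndarray:
    """Sawtooth along one axis: slow drift at slow_vel, instant reset at
    +amplitude/2 back to -amplitude/2."""
    if slow_vel <= 0 or amplitude <= 0:
        return np.zeros_like(t)
    period = amplitude / slow_vel
    phase = np.mod(t, period) / period
    return amplitude * (phase - 0.5)


def _ou_drift(n: int, dt: float, sd: float, tau: float,
              rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path, per-axis, shape (n, 2)."""
    if sd <= 0:
        return np.zeros((n, 2))
    a = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1 - a * a)
    x = rng.normal(0, sd, size=2)
    out = np.empty((n, 2))
    for k in range(n):
        out[k] = x
        x = a * x + rng.normal(0, innov_sd, size=2)
    return out


def simulate_response(stim: StimulusTrace, profile: ResponderProfile,
                      seed: int | np.random.Generator = 0,
                      participant_id: str = "sim") -> GazeRecording:
    """Simulate one binocular recording of a responder viewing a stimulus.

    Deterministic given (stimulus, profile, seed).  The per-eye trace is
    the condition-dependent tracking model plus stimulus-independent
    nystagmus, slow per-eye drift, white jitter and blink-driven invalid
    runs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = stim.t
    n = len(t)
    dt = 1.0 / stim.rate_hz
    latency = profile.saccade_latency_ms / 1000.0

    # conjugate gaze wander, shared by both eyes
    wander = _ou_drift(n, dt, profile.wander_sd, profile.wander_tau_s, rng)

    eyes = []
    for e in range(2):
        if stim.test is Test.DOT:
            base = _track_dot(stim, profile.saccade_gain[e], latency)
        elif stim.test is Test.H:
            base = _track_pursuit(stim, profile.pursuit_gain[e], profile.saccade_gain[e],
                                  latency, profile.catchup_threshold_px)
        else:
            base = _track_okn(stim, profile.pursuit_gain[e])
        if profile.nystagmus_slow_velocity > 0:
            amp = profile.nystagmus_amplitude
            if e == 1:
                amp *= profile.nystagmus_eye_asymmetry
            wave = _nystagmus_wave(t, profile.nystagmus_slow_velocity, amp)
            axis = np.array([np.cos(profile.nystagmus_axis), np.sin(profile.nystagmus_axis)])
            base = base + wave[:, None] * axis
        if e == 1 and any(profile.inter_eye_offset):
            base = base + np.asarray(profile.inter_eye_offset)
        base = base + wander
        base = base + _ou_drift(n, dt, profile.drift_sd, profile.drift_tau_s, rng)
        base = base + rng.normal(0, profile.noise_sd, size=(n, 2))
        eyes.append(base)

    valid = np.ones(n, dtype=bool)
    n_blinks = rng.poisson(profile.blink_rate_per_min * (t[-1] + dt) / 60.0)
    for _ in range(n_blinks):
        start = rng.uniform(0, t[-1])
        dur = rng.uniform(*profile.blink_duration_s)
        valid[(t >= start) & (t < start + dur)] = False

    return GazeRecording(
        participant_id=participant_id,
        test=stim.test,
        rate_hz=stim.rate_hz,
        t=t.copy(),
        left=eyes[0],
        right=eyes[1],
        left_valid=valid.copy(),
        right_valid=valid.copy(),
    )


# ---------------------------------------------------------------------------
# uncalibrated-tracker deformation


@dataclass(frozen=True)
class AffineMap:
    """x -> R(rot) @ Shear(shear) @ diag(sx, sy) @ x + (tx, ty)."""

    tx: float = 0.0
    ty: float = 0.0
    sx: float = 1.0
    sy: float = 1.0
    rot: float = 0.0    # radians
    shear: float = 0.0

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rot), np.sin(self.rot)
        R = np.array([[c, -s], [s, c]])
        H = np.array([[1.0, self.shear], [0.0, 1.0]])
        S = np.diag([self.sx, self.sy])
        return R @ H @ S

    def __call__(self, points: np.ndarray) -> np.ndarray:
        A = self.matrix
        if abs(np.linalg.det(A)) < 1e-12:
            raise ValueError("singular affine map")
        return points @ A.T + np.array([self.tx, self.ty])


@dataclass(frozen=True)
class DeformationParams:
    """Per-eye affine deformation of an uncalibrated tracker."""

    left: AffineMap = field(default_factory=AffineMap)
    right: AffineMap = field(default_factory=AffineMap)

    @classmethod
    def identity(cls) -> "DeformationParams":
        return cls()

    @classmethod
    def sample(cls, rng: np.random.Generator,
               max_translation: float = 200.0,
               scale_range: tuple[float, float] = (0.8, 1.2),
               max_rotation_deg: float = 10.0,
               max_shear: float = 0.1,
               eye_jitter: float = 0.1) -> "DeformationParams":
        """Draw an uncalibrated-tracker deformation.

        Miscalibration is dominated by rig/camera/screen geometry common
        to both eyes, so one affine map is drawn from the full ranges
        and each eye receives it plus a small independent perturbation
        (``eye_jitter`` times the common ranges).
        """
        smid = 0.5 * (scale_range[0] + scale_range[1])
        shalf = 0.5 * (scale_range[1] - scale_range[0])
        common = dict(
            tx=rng.uniform(-max_translation, max_translation),
            ty=rng.uniform(-max_translation, max_translation),
            sx=rng.uniform(*scale_range),
            sy=rng.uniform(*scale_range),
            rot=np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg)),
            shear=rng.uniform(-max_shear, max_shear),
        )

        def one() -> AffineMap:
            j = eye_jitter
            return AffineMap(
                tx=float(common["tx"] + rng.uniform(-j, j) * max_translation),
                ty=float(common["ty"] + rng.uniform(-j, j) * max_translation),
                sx=float(common["sx"] + rng.uniform(-j, j) * shalf),
                sy=float(common["sy"] + rng.uniform(-j, j) * shalf),
                rot=float(common["rot"]
                          + np.deg2rad(rng.uniform(-j, j) * max_rotation_deg)),
                shear=float(common["shear"] + rng.uniform(-j, j) * max_shear),
            )

        return cls(left=one(), right=one())


def apply_deformation(rec: GazeRecording, d: DeformationParams) -> GazeRecording:
    """Map each eye's coordinates through its affine map; flags untouched."""
    left = rec.left.copy()
    right = rec.right.copy()
    left[rec.left_valid] = d.left(left[rec.left_valid])
    right[rec.right_valid] = d.right(right[rec.right_valid])
    return GazeRecording(
        participant_id=rec.participant_id,
        test=rec.test,
        rate_hz=rec.rate_hz,
        t=rec.t.copy(),
        left=left,
        right=right,
        left_valid=rec.left_valid.copy(),
        right_valid=rec.right_valid.copy(),
        left_imputed=rec.left_imputed.copy(),
        right_imputed=rec.right_imputed.copy(),
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs of the simulated cohort.

    The abnormal condition mix puts 48% of patients in COMBINED
    (multiple concurrent signs, the most common clinical presentation)
    and splits the rest across single-sign conditions.
    """

    duration_s: float = 10.0
    rate_hz: float = 120.0
    apply_deformations: bool = True
    max_translation: float = 200.0
    scale_range: tuple[float, float] = (0.8, 1.2)
    max_rotation_deg: float = 10.0
    max_shear: float = 0.1
    abnormal_mix: tuple[tuple[str, float], ...] = (
        ("COMBINED", 0.48),
        ("DYSCONJUGATE", 0.20),
        ("NYSTAGMUS", 0.18),
        ("SACCADIC_PURSUIT", 0.14),
    )


@dataclass(frozen=True)
class Participant:
    participant_id: str
    label: int  # 1 = abnormal (positive), 0 = normal
    condition: Condition
    seed: int
    profile: ResponderProfile
    deformation: DeformationParams
    recordings: dict[Test, GazeRecording]


@dataclass(frozen=True)
class Cohort:
    participants: list[Participant]
    config: CohortConfig
    seed: int

    def __len__(self) -> int:
        return len(self.participants)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            d = p.deformation
            rows.append({
                "participant_id": p.participant_id,
                "label": p.label,
                "condition": p.condition.value,
                "seed": p.seed,
                "left_tx": d.left.tx, "left_ty": d.left.ty,
                "left_sx": d.left.sx, "left_sy": d.left.sy,
                "left_rot": d.left.rot, "left_shear": d.left.shear,
                "right_tx": d.right.tx, "right_ty": d.right.ty,
                "right_sx": d.right.sx, "right_sy": d.right.sy,
                "right_rot": d.right.rot, "right_shear": d.right.shear,
            })
        return pd.DataFrame(rows)

    def save(self, out_dir: str | Path) -> None:
        """Write one gaze CSV per recording plus the cohort manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for p in self.participants:
            for test, rec in p.recordings.items():
                write_recording_csv(rec, out / f"{p.participant_id}_{test.value}.csv")
        self.manifest().to_csv(out / "manifest.csv", index=False, float_format="%.12g")

    def by_test(self) -> dict[Test, list[tuple[int, GazeRecording]]]:
        """Regroup as {test: [(label, recording), ...]} for training."""
        out: dict[Test, list[tuple[int, GazeRecording]]] = {t: [] for t in Test}
        for p in self.participants:
            for test, rec in p.recordings.items():
                out[test].append((p.label, rec))
        return out


def generate_cohort(n_abnormal: int, n_normal: int,
                    config: CohortConfig | None = None,
                    seed: int = 0) -> Cohort:
    """Simulate a labeled cohort: three recordings per participant.

    Abnormal participants draw a condition from the configured mix;
    every participant gets an independent responder profile, a random
    per-eye affine deformation (if enabled) and child seeds derived from
    the master seed, so regeneration with the same seed is bit-identical.
    """
    if n_abnormal < 0 or n_normal < 0:
        raise ValueError("cohort counts must be non-negative")
    config = config or CohortConfig()
    master = np.random.default_rng(seed)
    names, probs = zip(*config.abnormal_mix)
    probs = np.asarray(probs) / np.sum(probs)

    stimuli = {test: make_stimulus(test, config.duration_s, config.rate_hz)
               for test in Test}

    participants: list[Participant] = []
    labels = [1] * n_abnormal + [0] * n_normal
    for i, label in enumerate(labels):
        pid = f"p{i:03d}"
        child_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(child_seed)
        condition = Condition(str(master.choice(names, p=probs))) if label else Condition.NORMAL
        profile = ResponderProfile.sample(condition, rng)
        if config.apply_deformations:
            deform = DeformationParams.sample(
                rng, config.max_translation, config.scale_range,
                config.max_rotation_deg, config.max_shear)
        else:
            deform = DeformationParams.identity()
        recs = {}
        for test in Test:
            rec = simulate_response(stimuli[test], profile, rng, participant_id=pid)
            recs[test] = apply_deformation(rec, deform)
        participants.append(Participant(
            participant_id=pid, label=label, condition=condition,
            seed=child_seed, profile=profile, deformation=deform,
            recordings=recs,
        ))
    return Cohort(participants=participants, config=config, seed=seed)
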