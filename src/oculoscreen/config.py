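"""Pipeline configuration.

A single dataclass holds every knob of the screening pipeline: smoothing,
compliance gating, the DRCDT angle/quantile discretization, the
nearest-subspace options and the ensemble fusion rule.  Configs round-trip
through YAML so that a run is fully described by one file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Configuration of the full screening pipeline.

    Attributes
    ----------
    smooth_window : int
        Savitzky-Golay window length in samples.  Must be odd; the default
        31 is the nearest odd width to a quarter-second at 120 Hz.
    smooth_polyorder : int
        Polynomial order of the smoother (cubic by default).
    compliance_threshold : float
        Minimum fraction of samples with at least one valid eye
        (inclusive) for a recording to be usable.
    max_gap_s : float
        Invalid runs up to this duration are treated as blinks and
        linearly interpolated; longer runs are excluded from point sets.
    n_angles : int
        Number L of Radon projection directions, uniform on [0, pi).
    n_quantiles : int
        Number M of quantile levels per projection direction.
    include_disparity : bool
        Whether the composite feature carries the left-minus-right
        disparity block in addition to the two per-eye blocks.
    deformation : bool
        Whether class subspaces include the translation spanning set U_T.
    energy_tol : float
        Fraction of singular-value energy retained when truncating a class
        subspace; 1.0 keeps every numerically nonzero direction.
    rule : str
        Ensemble fusion rule: "any", "majority" or "all".
    """

    smooth_window: int = 31
    smooth_polyorder: int = 3
    compliance_threshold: float = 0.90
    max_gap_s: float = 0.25
    n_angles: int = 8
    n_quantiles: int = 64
    include_disparity: bool = True
    deformation: bool = True
    energy_tol: float = 1.0
    rule: str = "any"

    def __post_init__(self) -> None:
        if self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        if not 0 < self.compliance_threshold <= 1:
            raise ValueError("compliance_threshold must be in (0, 1]")
        if self.rule not in ("any", "majority", "all"):
            raise ValueError(f"unknown fusion rule {self.rule!r}")

    @property
    def n_blocks(self) -> int:
        return 3 if self.include_disparity else 2

    @property
    def feature_length(self) -> int:
        return self.n_blocks * self.n_angles * self.n_quantiles

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
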