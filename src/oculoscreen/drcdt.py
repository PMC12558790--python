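"""Discrete Radon cumulative distribution transform of 2-D point sets.

A gaze recording reduces to a finite set of 2-D points carrying uniform
mass.  For each direction w_theta = (cos theta, sin theta) on an angle
grid, the points are projected onto the line (x . w_theta), the
projections are sorted — the discrete CDT, i.e. the empirical quantile
function of the projected distribution — and resampled at M fixed
quantile levels so that recordings of different lengths map to vectors
of one common length.  Stacking the per-angle rows (angle-major) gives
the DRCDT feature.

The embedding is a transport-based one: translating the point set by t
adds the constant t . w_theta to the theta-row, and scaling by alpha > 0
scales the feature by alpha, so affine distortions of an uncalibrated
tracker become low-dimensional linear families in feature space — the
structure the nearest-subspace classifier's deformation set absorbs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PointSet",
    "AngleGrid",
    "SortedProjection",
    "DRCDTFeature",
    "radon_project",
    "quantile_resample",
    "drcdt_transform",
    "binocular_feature",
    "save_feature_matrix",
    "load_feature_matrix",
]


@dataclass(frozen=True)
class PointSet:
    """Finite multiset of 2-D coordinates with uniform mass 1/n per point."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        object.__setattr__(self, "points", pts)

    @classmethod
    def empty(cls) -> "PointSet":
        return cls(np.empty((0, 2)))

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def mass(self) -> float:
        """Uniform per-point weight; total mass is 1 by construction."""
        if len(self) == 0:
            raise ValueError("empty point set has no mass")
        return 1.0 / len(self)

    def translate(self, t) -> "PointSet":
        return PointSet(self.points + np.asarray(t, dtype=float))

    def scale(self, alpha: float) -> "PointSet":
        return PointSet(self.points * float(alpha))


@dataclass(frozen=True)
class AngleGrid:
    """Ordered projection angles in [0, pi) with their unit directions."""

    angles: np.ndarray

    def __post_init__(self) -> None:
        ang = np.asarray(self.angles, dtype=float)
        if ang.ndim != 1 or ang.size == 0:
            raise ValueError("angles must be a nonempty 1-D array")
        if np.any(ang < 0) or np.any(ang >= np.pi):
            raise ValueError("angles must lie in [0, pi)")
        if np.any(np.diff(ang) <= 0):
            raise ValueError("angles must be strictly increasing")
        object.__setattr__(self, "angles", ang)

    @classmethod
    def uniform(cls, n_angles: int) -> "AngleGrid":
        """L equispaced angles theta_j = j*pi/L, j = 0..L-1."""
        if n_angles < 1:
            raise ValueError("need at least one angle")
        return cls(np.arange(n_angles) * np.pi / n_angles)

    def __len__(self) -> int:
        return self.angles.size

    @property
    def directions(self) -> np.ndarray:
        """(L, 2) array of unit vectors (cos theta, sin theta)."""
        return np.column_stack([np.cos(self.angles), np.sin(self.angles)])


@dataclass(frozen=True)
class SortedProjection:
    """Nondecreasing projections of a point set onto one direction."""

    theta: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError("sorted projection cannot be empty")
        if np.any(np.diff(v) < 0):
            raise ValueError("projection values must be nondecreasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class DRCDTFeature:
    """Per-angle quantile rows of the sorted Radon projections.

    ``matrix`` has shape (L, M); ``vector`` flattens it angle-major
    (row for angle 0 first), the fixed layout used everywhere downstream.
    """

    grid: AngleGrid
    n_quantiles: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.grid), self.n_quantiles):
            raise ValueError("matrix shape must be (L, M)")
        object.__setattr__(self, "matrix", m)

    @property
    def quantile_levels(self) -> np.ndarray:
        M = self.n_quantiles
        return (np.arange(1, M + 1) - 0.5) / M

    @property
    def vector(self) -> np.ndarray:
        return self.matrix.reshape(-1)


def radon_project(ps: PointSet, theta: float) -> SortedProjection:
    """Project a point set onto direction theta and sort.

    The result is the discrete CDT of the projected distribution: its
    values are the order statistics of {x . w_theta : x in ps}.
    """
    if len(ps) == 0:
        raise ValueError("cannot project an empty point set")
    w = np.array([np.cos(theta), np.sin(theta)])
    return SortedProjection(theta=float(theta), values=np.sort(ps.points @ w))


def quantile_resample(sp: SortedProjection, n_quantiles: int) -> np.ndarray:
    """Empirical quantile function of a sorted projection at M fixed levels.

    Levels are the midpoints (i - 0.5)/M, i = 1..M; values interpolate
    linearly between order statistics placed at plotting positions
    (j - 0.5)/n and clamp to the extremes beyond them.  A single-point
    projection yields a constant vector.
    """
    if n_quantiles < 2:
        raise ValueError("need at least 2 quantile levels")
    n = len(sp)
    levels = (np.arange(1, n_quantiles + 1) - 0.5) / n_quantiles
    if n == 1:
        return np.full(n_quantiles, sp.values[0])
    positions = (np.arange(1, n + 1) - 0.5) / n
    return np.interp(levels, positions, sp.values)


def drcdt_transform(ps: PointSet, grid: AngleGrid, n_quantiles: int) -> DRCDTFeature:
    """DRCDT of a point set: per-angle sorted projections on a quantile grid.

    Deterministic, and invariant to any reordering of the input points
    (sorting discards order).
    """
    rows = np.empty((len(grid), n_quantiles))
    for j, theta in enumerate(grid.angles):
        rows[j] = quantile_resample(radon_project(ps, theta), n_quantiles)
    return DRCDTFeature(grid=grid, n_quantiles=n_quantiles, matrix=rows)


def binocular_feature(
    left: PointSet,
    right: PointSet,
    disparity: PointSet,
    grid: AngleGrid,
    n_quantiles: int,
    include_disparity: bool = True,
) -> np.ndarray:
    """Composite feature [left | right | disparity], fixed block order.

    The disparity block (transform of the left-minus-right multiset)
    encodes conjugacy explicitly.  If one eye is entirely missing its
    block is filled with the present eye's block (monocular recording)
    and the disparity block with zeros — the transform of a point mass
    at the origin.
    """
    if len(left) == 0 and len(right) == 0:
        raise ValueError("both eyes empty: no feature can be built")
    L, M = len(grid), n_quantiles
    if len(left) > 0:
        left_block = drcdt_transform(left, grid, M).vector
    else:
        left_block = None
    if len(right) > 0:
        right_block = drcdt_transform(right, grid, M).vector
    else:
        right_block = None
    if left_block is None:
        left_block = right_block
    if right_block is None:
        right_block = left_block
    blocks = [left_block, right_block]
    if include_disparity:
        if len(disparity) > 0:
            blocks.append(drcdt_transform(disparity, grid, M).vector)
        else:
            blocks.append(np.zeros(L * M))
    return np.concatenate(blocks)


def save_feature_matrix(path: str | Path, features: np.ndarray, grid: AngleGrid,
                        n_quantiles: int, blocks: tuple[str, ...] =
                        ("left", "right", "disparity")) -> None:
    """Write a (n_samples, dim) feature matrix as CSV with a JSON sidecar.

    The sidecar (``<path>.json``) records the angle grid, quantile count
    and block order so the flat layout is self-describing.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    np.savetxt(path, F, delimiter=",", fmt="%.12g")
    sidecar = {
        "angles": list(map(float, grid.angles)),
        "n_quantiles": int(n_quantiles),
        "blocks": list(blocks),
        "layout": "block-major, angle-major within block, quantile-minor",
        "dim": int(F.shape[1]),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_feature_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a feature matrix written by :func:`save_feature_matrix`."""
    F = np.atleast_2d(np.loadtxt(path, delimiter=","))
    meta = json.loads(Path(str(path) + ".json").read_text())
    if F.shape[1] != meta["dim"]:
        raise ValueError("feature matrix does not match its sidecar")
    return F, meta
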