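"""Nearest-subspace classification in DRCDT feature space.

Each class is represented by the linear span of its training features,
optionally augmented with the deformation spanning set U_T: for every
angle theta on the grid, two directions that are constant (cos theta and
sin theta respectively) over that angle's quantile stripe and zero
elsewhere, replicated across the per-eye/disparity blocks.  Because a
translation t of the underlying point set shifts the theta-row of the
feature by the constant t . w_theta, every translation-induced feature
change lies exactly in span(U_T) — so a subspace that includes U_T
classifies uncalibrated (translated) recordings identically to
calibrated ones.  A test feature is assigned to the class whose subspace
has the smallest orthogonal-projection residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .drcdt import AngleGrid

__all__ = [
    "DeformationSet",
    "ClassSubspace",
    "NSModel",
    "build_deformation_set",
    "fit_subspace",
    "subspace_distance",
    "classify",
    "fit_ns_model",
]


@dataclass(frozen=True)
class DeformationSet:
    """Translation spanning set U_T as explicit feature-space columns.

    ``columns`` is (ambient_dim, 2*L*blocks): per block and per angle j,
    one column constant cos(theta_j) over the (block, angle) stripe of M
    entries and one constant sin(theta_j), zero elsewhere.
    """

    columns: np.ndarray
    n_angles: int
    n_quantiles: int
    n_blocks: int


@dataclass(frozen=True)
class ClassSubspace:
    """Orthonormal basis of one class's training-span (plus U_T)."""

    label: int
    basis: np.ndarray  # (ambient_dim, r), orthonormal columns
    source_rank: int   # number of training features stacked
    includes_deformation: bool

    @property
    def ambient_dim(self) -> int:
        return self.basis.shape[0]


@dataclass(frozen=True)
class NSModel:
    """One subspace per class plus a snapshot of the feature config."""

    subspaces: dict[int, ClassSubspace]
    ambient_dim: int
    config: dict

    def __post_init__(self) -> None:
        if len(self.subspaces) < 2:
            raise ValueError("classification needs at least 2 classes")
        for sub in self.subspaces.values():
            if sub.ambient_dim != self.ambient_dim:
                raise ValueError("subspace ambient dimension mismatch")


def build_deformation_set(grid: AngleGrid, n_quantiles: int, n_blocks: int) -> DeformationSet:
    """Construct U_T for a given angle grid, quantile count and block count."""
    if n_quantiles < 1 or n_blocks < 1:
        raise ValueError("n_quantiles and n_blocks must be >= 1")
    L, M = len(grid), n_quantiles
    dim = n_blocks * L * M
    cols = np.zeros((dim, 2 * L * n_blocks))
    c = 0
    for b in range(n_blocks):
        for j, theta in enumerate(grid.angles):
            start = (b * L + j) * M
            stripe = slice(start, start + M)
            cols[stripe, c] = np.cos(theta)
            cols[stripe, c + 1] = np.sin(theta)
            c += 2
    return DeformationSet(columns=cols, n_angles=L, n_quantiles=M, n_blocks=n_blocks)


def fit_subspace(
    features: list[np.ndarray] | np.ndarray,
    deformation: DeformationSet | None = None,
    energy_tol: float = 1.0,
    label: int = 0,
) -> ClassSubspace:
    """Orthonormalize the span of training features (and U_T) via SVD.

    Directions with singular value at machine scale are dropped; with
    ``energy_tol`` < 1 the basis is further truncated to the leading
    directions holding that fraction of squared singular-value energy.
    Untruncated (the default), every training feature lies in the
    subspace to numerical precision.
    """
    if not 0 < energy_tol <= 1:
        raise ValueError("energy_tol must be in (0, 1]")
    F = np.atleast_2d(np.asarray(features, dtype=float))
    if F.shape[0] == 0:
        raise ValueError("need at least one training feature")
    A = F.T  # features as columns
    if deformation is not None:
        if deformation.columns.shape[0] != A.shape[0]:
            raise ValueError("deformation set dimension mismatch")
        A = np.hstack([A, deformation.columns])
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    tol = s[0] * max(A.shape) * np.finfo(float).eps if s.size else 0.0
    keep = s > tol
    if energy_tol < 1.0 and keep.any():
        energy = np.cumsum(s**2) / np.sum(s**2)
        # retain the smallest leading set reaching energy_tol
        k = int(np.searchsorted(energy, energy_tol) + 1)
        keep &= np.arange(s.size) < k
    return ClassSubspace(
        label=label,
        basis=U[:, keep],
        source_rank=F.shape[0],
        includes_deformation=deformation is not None,
    )


def subspace_distance(f: np.ndarray, sub: ClassSubspace) -> float:
    """Orthogonal-projection residual ||f - B B^T f||_2.

    Equals the least-squares minimum over coefficients c of ||f - B c||_2.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (sub.ambient_dim,):
        raise ValueError(
            f"feature length {f.shape} does not match ambient dim {sub.ambient_dim}"
        )
    B = sub.basis
    return float(np.linalg.norm(f - B @ (B.T @ f)))


def classify(f: np.ndarray, model: NSModel) -> tuple[int, dict[int, float]]:
    """Nearest-subspace decision: argmin over class residuals.

    Returns the winning label and the per-class distances.  Exact ties
    go to the lowest class index.
    """
    distances = {k: subspace_distance(f, sub) for k, sub in sorted(model.subspaces.items())}
    best = min(distances, key=lambda k: (distances[k], k))
    return best, distances


def fit_ns_model(
    features_by_class: dict[int, list[np.ndarray]],
    grid: AngleGrid,
    n_quantiles: int,
    n_blocks: int,
    deformation: bool = True,
    energy_tol: float = 1.0,
) -> NSModel:
    """Fit one subspace per class over a shared ambient dimension."""
    if len(features_by_class) < 2:
        raise ValueError("need at least 2 classes")
    dims = {np.asarray(fs[0]).size for fs in features_by_class.values() if len(fs)}
    missing = [k for k, fs in features_by_class.items() if len(fs) == 0]
    if missing:
        raise ValueError(f"classes without training features: {missing}")
    if len(dims) != 1:
        raise ValueError("inconsistent feature lengths across classes")
    udef = build_deformation_set(grid, n_quantiles, n_blocks) if deformation else None
    subspaces = {
        k: fit_subspace(fs, udef, energy_tol=energy_tol, label=k)
        for k, fs in features_by_class.items()
    }
    dim = dims.pop()
    return NSModel(
        subspaces=subspaces,
        ambient_dim=dim,
        config={
            "n_angles": len(grid),
            "n_quantiles": n_quantiles,
            "n_blocks": n_blocks,
            "deformation": deformation,
            "energy_tol": energy_tol,
        },
    )
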