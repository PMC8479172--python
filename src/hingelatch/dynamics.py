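"""Cross-correlation matrices, Cartesian PCA, subspace overlap, and
projection densities.

Cross-correlations are the normalized covariances of atomic positional
fluctuations, C_ij = <Δr_i·Δr_j> / sqrt(<|Δr_i|²><|Δr_j|²>), computed over
core-aligned frames; C ≥ 0.7 corresponds to motion vectors within 45° of
each other and is the conventional threshold for building the residue
network.  PCA diagonalizes the 3N coordinate covariance; the RMSIP of two
eigenvector sets measures how much essential subspace they share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "CrossCorrelationMatrix",
    "PCAModel",
    "ProjectionDensity",
    "cross_correlation",
    "cartesian_pca",
    "project",
    "rmsip",
    "projection_density",
    "jackknife_projection",
]


@dataclass
class CrossCorrelationMatrix:
    matrix: np.ndarray            # (N, N), symmetric, unit diagonal
    node_ids: tuple[int, ...]     # residue ids (or atom ids) per row

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")


@dataclass
class PCAModel:
    mean: np.ndarray          # (3N,)
    eigenvectors: np.ndarray  # (3N, K) columns, orthonormal
    eigenvalues: np.ndarray   # (K,) non-increasing, Å²
    node_ids: tuple[int, ...] = ()

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


@dataclass
class ProjectionDensity:
    grid_x: np.ndarray
    grid_y: np.ndarray
    densities: dict[str, np.ndarray]   # each integrates to 1 on the grid
    summaries: dict[str, dict]


def cross_correlation(
    coords_list: Sequence[np.ndarray],
    node_ids: Sequence[int],
    frame_masks: Sequence[np.ndarray] | None = None,
) -> CrossCorrelationMatrix:
    """Normalized fluctuation correlations over pooled, pre-aligned frames.

    ``coords_list`` holds per-replica arrays of shape (F, N, 3) restricted
    to the atoms of interest (one per node).  Zero-variance nodes get zero
    off-diagonal correlation with a warning.
    """
    stacks = []
    for k, x in enumerate(coords_list):
        m = (np.ones(x.shape[0], dtype=bool) if frame_masks is None
             else np.asarray(frame_masks[k], dtype=bool))
        stacks.append(np.asarray(x)[m])
    x = np.concatenate(stacks, axis=0)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 frames for correlations")
    dx = x - x.mean(axis=0)
    cov = np.einsum("fia,fja->ij", dx, dx) / x.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance node(s); their "
                      "correlations are set to 0", stacklevel=2)
        var[zero] = 1.0
    denom = np.sqrt(np.outer(var, var))
    c = cov / denom
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    return CrossCorrelationMatrix(matrix=c, node_ids=tuple(node_ids))


def cartesian_pca(
    coords_list: Sequence[np.ndarray],
    node_ids: Sequence[int] = (),
    frame_masks: Sequence[np.ndarray] | None = None,
) -> tuple[PCAModel, np.ndarray]:
    """PCA of the pooled coordinate covariance; returns (model, projections).

    ``coords_list``: per-replica/per-condition (F, N, 3) arrays, already
    aligned on the core and restricted to the analysis atoms (the caller
    applies any residue exclusions).  Projections cover every pooled input
    frame, in input order.
    """
    stacks = []
    for k, x in enumerate(coords_list):
        m = (np.ones(x.shape[0], dtype=bool) if frame_masks is None
             else np.asarray(frame_masks[k], dtype=bool))
        stacks.append(np.asarray(x)[m])
    x = np.concatenate(stacks, axis=0)
    f = x.shape[0]
    if f < 2:
        raise ValueError("PCA needs at least 2 frames")
    flat = x.reshape(f, -1)
    if f < flat.shape[1]:
        warnings.warn(
            "fewer frames than coordinate dimensions; trailing eigenvalues "
            "are rank-deficient", stacklevel=2,
        )
    mean = flat.mean(axis=0)
    centered = flat - mean
    # economy SVD: eigenvalues of the covariance are s^2 / F
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = (s * s) / f
    model = PCAModel(mean=mean, eigenvectors=vt.T, eigenvalues=eigvals,
                     node_ids=tuple(node_ids))
    projections = centered @ vt.T
    return model, projections


def project(model: PCAModel, coords: np.ndarray, k: int = 2) -> np.ndarray:
    flat = np.asarray(coords).reshape(coords.shape[0], -1)
    return (flat - model.mean) @ model.eigenvectors[:, :k]


def rmsip(model_a: PCAModel, model_b: PCAModel, k: int = 10) -> float:
    """Root mean square inner product of the first k eigenvectors."""
    va = model_a.eigenvectors[:, :k]
    vb = model_b.eigenvectors[:, :k]
    if va.shape[0] != vb.shape[0]:
        raise ValueError("models live in different coordinate spaces")
    k = min(k, va.shape[1], vb.shape[1])
    ip = va[:, :k].T @ vb[:, :k]
    return float(np.sqrt((ip * ip).sum() / k))


def projection_density(
    projections: Mapping[str, np.ndarray],
    grid_size: int = 60,
    padding: float = 0.1,
) -> ProjectionDensity:
    """Gaussian-KDE densities of (PC1, PC2) clouds on one shared grid.

    Scott's-rule bandwidth; each condition's density is normalized to
    integrate to 1.  Summaries report the fraction of points inside the
    condition's own 1-sd ellipse and the complementary tail fraction.
    """
    all_pts = []
    for cond, pts in projections.items():
        pts = np.asarray(pts)
        if pts.shape[0] == 0:
            raise ValueError(f"condition {cond}: no projection points")
        if pts.shape[0] < 100:
            warnings.warn(f"condition {cond}: fewer than 100 points; the "
                          "density estimate will be rough", stacklevel=2)
        all_pts.append(pts[:, :2])
    stacked = np.concatenate(all_pts)
    lo = stacked.min(axis=0)
    hi = stacked.max(axis=0)
    span = hi - lo
    lo -= padding * span
    hi += padding * span
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])

    densities = {}
    summaries = {}
    for cond, pts in projections.items():
        p = np.asarray(pts)[:, :2]
        kde = gaussian_kde(p.T)
        z = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
        densities[cond] = z / (z.sum() * cell)  # integrates to 1 on the grid
        center = p.mean(axis=0)
        sd = p.std(axis=0, ddof=1)
        sd[sd == 0] = 1e-12
        r2 = (((p - center) / sd) ** 2).sum(axis=1)
        central = float(np.mean(r2 <= 1.0))
        summaries[cond] = {
            "central_fraction": central,
            "tail_fraction": 1.0 - central,
            "sd_pc1": float(sd[0]),
            "sd_pc2": float(sd[1]),
        }
    return ProjectionDensity(grid_x=gx, grid_y=gy, densities=densities,
                             summaries=summaries)


def jackknife_projection(
    coords_list: Sequence[np.ndarray],
    frame_masks: Sequence[np.ndarray] | None = None,
    k: int = 2,
) -> list[float]:
    """Leave-one-replica-out PCA overlap with the full model.

    For each replica excluded in turn, PCA is recomputed on the remainder
    and the RMSIP of the first ``k`` components against the full model is
    reported.  Values near 1 mean no single replica dominates the
    essential subspace.
    """
    n = len(coords_list)
    if n < 3:
        raise ValueError("jack-knife needs at least 3 replicas")
    full, _ = cartesian_pca(coords_list, frame_masks=frame_masks)
    overlaps = []
    for i in range(n):
        rest = [c for j, c in enumerate(coords_list) if j != i]
        masks = (None if frame_masks is None
                 else [m for j, m in enumerate(frame_masks) if j != i])
        sub, _ = cartesian_pca(rest, frame_masks=masks)
        overlaps.append(rmsip(sub, full, k=k))
    return overlaps
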