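"""Superposition, stable core, average structures, distance-difference maps,
hinge scan, and latch-distance histograms.

All comparative geometry assumes frames have first been brought into a
common reference frame by superposing on the stable core — the residue set
with the least positional variation over the combined trajectories.  RMSDs
between average structures are then computed directly, without
re-superposition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .trajectory_io import Ensemble, Frame, Topology, Trajectory

__all__ = [
    "Superposition",
    "StableCore",
    "AverageStructure",
    "DistanceDifferenceMap",
    "HingeReport",
    "kabsch_superpose",
    "apply_superposition",
    "align_trajectory",
    "find_stable_core",
    "average_structure",
    "rmsd_between_structures",
    "most_populated_structure",
    "distance_difference_map",
    "hinge_scan",
    "latch_distance_histograms",
    "per_residue_backbone_rmsd",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class Superposition:
    rotation: np.ndarray     # 3x3, det +1
    translation: np.ndarray  # applied after rotation, Å
    atom_ids: tuple[int, ...]
    rmsd: float


@dataclass
class StableCore:
    residue_ids: tuple[int, ...]
    rigidity: dict[int, float]  # per-residue mean distance fluctuation, Å


@dataclass
class AverageStructure:
    coords: np.ndarray        # (n_atoms, 3) mean positions, Å
    rmsf: np.ndarray          # (n_atoms,) Å
    n_frames: int
    topology: Topology
    mask_note: str = ""


@dataclass
class DistanceDifferenceMap:
    residue_ids: tuple[int, ...]
    delta: np.ndarray  # (R, R)  <D_ij>_A - <D_ij>_B, Å
    block_means: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class HingeReport:
    candidates: tuple[int, ...]
    correlations: np.ndarray      # Pearson r per candidate
    ranked: tuple[tuple[int, float], ...]   # (residue_id, r) descending
    degenerate: bool = False

    @property
    def best(self) -> int:
        return self.ranked[0][0]


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: Frame | np.ndarray, reference: Frame | np.ndarray,
                     atom_indices: Sequence[int],
                     atom_ids: Sequence[int] | None = None) -> Superposition:
    """Least-squares optimal rigid transform of mobile onto reference.

    ``atom_indices`` are 0-based coordinate rows used for the fit.  The
    returned transform maps mobile coordinates as ``x @ R.T + t``.
    """
    xm = np.asarray(mobile.coords if isinstance(mobile, Frame) else mobile, float)
    xr = np.asarray(reference.coords if isinstance(reference, Frame) else reference, float)
    idx = np.asarray(atom_indices, dtype=int)
    if idx.size < 3:
        raise ValueError("superposition needs at least 3 atoms")
    a = xm[idx]
    b = xr[idx]
    ca = a - a.mean(axis=0)
    cb = b - b.mean(axis=0)
    # collinearity check: rank of the centered coordinates
    if np.linalg.matrix_rank(ca, tol=1e-8) < 2:
        raise ValueError("alignment atoms are collinear or degenerate")
    h = ca.T @ cb
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = b.mean(axis=0) - a.mean(axis=0) @ rot.T
    fitted = a @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))
    return Superposition(
        rotation=rot, translation=trans,
        atom_ids=tuple(atom_ids) if atom_ids is not None else tuple(idx + 1),
        rmsd=rmsd,
    )


def apply_superposition(coords: np.ndarray, sup: Superposition) -> np.ndarray:
    return coords @ sup.rotation.T + sup.translation


def align_trajectory(traj: Trajectory, core_indices: Sequence[int],
                     reference: np.ndarray | None = None) -> Trajectory:
    """Superpose every frame on the reference (default: first frame) using
    the core atom rows; returns a new Trajectory."""
    ref = traj.coords[0] if reference is None else np.asarray(reference)
    out = np.empty_like(traj.coords)
    for t in range(traj.n_frames):
        sup = kabsch_superpose(traj.coords[t], ref, core_indices)
        out[t] = apply_superposition(traj.coords[t], sup)
    return Trajectory(traj.topology, out, traj.dt, replica_id=traj.replica_id,
                      condition=traj.condition, t0=traj.t0)


# ---------------------------------------------------------------------------
# Stable core
# ---------------------------------------------------------------------------

def _ca_indices(top: Topology, atom_name: str,
                residue_ids: Sequence[int] | None = None) -> tuple[list[int], np.ndarray]:
    rids = []
    rows = []
    wanted = set(residue_ids) if residue_ids is not None else None
    for i, a in enumerate(top.atoms):
        if a.name == atom_name and (wanted is None or a.residue_id in wanted):
            rids.append(a.residue_id)
            rows.append(i)
    return rids, np.asarray(rows, dtype=int)


def distance_fluctuation_matrix(ensemble: Ensemble,
                                atom_name: str = "CA",
                                residue_ids: Sequence[int] | None = None
                                ) -> tuple[list[int], np.ndarray]:
    """SD over frames of each inter-residue distance, pooled over replicas."""
    top = ensemble.topology
    rids, rows = _ca_indices(top, atom_name, residue_ids)
    r = len(rids)
    s1 = np.zeros((r, r))
    s2 = np.zeros((r, r))
    n = 0
    for traj in ensemble:
        x = traj.coords[:, rows]          # (F, R, 3)
        for t in range(x.shape[0]):
            d = np.linalg.norm(x[t, :, None, :] - x[t, None, :, :], axis=-1)
            s1 += d
            s2 += d * d
            n += 1
    if n < 2:
        raise ValueError("need at least 2 frames for distance fluctuations")
    mean = s1 / n
    var = np.maximum(s2 / n - mean * mean, 0.0)
    return rids, np.sqrt(var)


def find_stable_core(ensemble: Ensemble, atom_name: str = "CA",
                     n_clusters: int = 5,
                     residue_ids: Sequence[int] | None = None) -> StableCore:
    """Residue cluster with the least internal distance fluctuation.

    Residues are clustered by average-linkage hierarchical clustering of the
    pairwise distance-fluctuation matrix; the cluster minimizing the mean
    intra-cluster fluctuation is the core.  Exact ties go to the cluster
    containing the lowest residue id.
    """
    rids, fluct = distance_fluctuation_matrix(ensemble, atom_name, residue_ids)
    if len(rids) < n_clusters:
        raise ValueError(
            f"{len(rids)} residues but {n_clusters} clusters requested"
        )
    condensed = squareform(fluct, checks=False)
    z = linkage(condensed, method="average")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")

    clusters: list[tuple[float, int, list[int]]] = []
    for c in sorted(set(labels)):
        members = [i for i, l in enumerate(labels) if l == c]
        if len(members) < 2:
            # a singleton has no internal fluctuation to measure; it cannot
            # represent a rigid core, so it is ineligible unless every
            # cluster degenerates to a singleton
            score = math.inf
        else:
            sub = fluct[np.ix_(members, members)]
            iu = np.triu_indices(len(members), k=1)
            score = float(sub[iu].mean())
        clusters.append((score, min(rids[i] for i in members), members))
    if all(math.isinf(s) for s, _, _ in clusters):
        clusters = [(0.0, rid, members) for _, rid, members in clusters]
    clusters.sort(key=lambda t: (round(t[0], 12), t[1]))
    if len(clusters) > 1 and abs(clusters[0][0] - clusters[-1][0]) < 1e-12:
        warnings.warn("all clusters tie on fluctuation; returning the cluster "
                      "with the lowest residue id", stacklevel=2)
    best_members = clusters[0][2]
    rigidity = {
        rids[i]: float(np.mean(np.delete(fluct[i], i))) for i in range(len(rids))
    }
    core_rids = tuple(sorted(rids[i] for i in best_members))
    return StableCore(residue_ids=core_rids, rigidity=rigidity)


# ---------------------------------------------------------------------------
# Average / most populated structures
# ---------------------------------------------------------------------------

def average_structure(source: Trajectory | Ensemble,
                      frame_mask: np.ndarray | Sequence[np.ndarray] | None = None,
                      mask_note: str = "") -> AverageStructure:
    """Arithmetic per-atom mean and RMSF over the masked, pre-aligned frames."""
    trajs = list(source) if isinstance(source, Ensemble) else [source]
    top = trajs[0].topology
    if frame_mask is None:
        masks = [np.ones(t.n_frames, dtype=bool) for t in trajs]
    elif isinstance(frame_mask, np.ndarray) and frame_mask.dtype == np.bool_:
        masks = [frame_mask] * len(trajs)
    else:
        masks = [np.asarray(m, dtype=bool) for m in frame_mask]
    stacks = [t.coords[m] for t, m in zip(trajs, masks)]
    x = np.concatenate(stacks, axis=0)
    if x.shape[0] == 0:
        raise ValueError("frame mask selects no frames")
    mean = x.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))
    return AverageStructure(coords=mean, rmsf=rmsf, n_frames=x.shape[0],
                            topology=top, mask_note=mask_note)


def rmsd_between_structures(a: AverageStructure, b: AverageStructure,
                            atom_indices: Sequence[int]) -> float:
    """RMSD over an atom subset, computed in the shared core-aligned frame
    (no re-superposition)."""
    idx = np.asarray(atom_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("atom subset is empty")
    diff = a.coords[idx] - b.coords[idx]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def per_residue_backbone_rmsd(a: AverageStructure, b: AverageStructure,
                              residue_ids: Sequence[int]) -> np.ndarray:
    """Backbone (N, CA, C, O) RMSD per residue between two average
    structures in the common frame."""
    top = a.topology
    out = np.empty(len(residue_ids))
    for k, rid in enumerate(residue_ids):
        rows = [top.index_of(top.atom_id(rid, nm)) for nm in BACKBONE_NAMES
                if top.has_atom(rid, nm)]
        out[k] = rmsd_between_structures(a, b, rows)
    return out


def most_populated_structure(
    traj_coords: np.ndarray,
    dist_pairs: tuple[np.ndarray, np.ndarray],
    reference: AverageStructure,
    backbone_rows: np.ndarray,
    dist_bin: float = 0.5,
    rmsd_bin: float = 0.25,
) -> tuple[int, float, float]:
    """Frame nearest the densest (inter-domain distance, RMSD) histogram bin.

    ``dist_pairs`` is (rows of the residue-set Cα atoms, rows of the single
    residue Cα); the distance metric is between the set centroid and the
    single Cα.  Ties break to the earliest frame.
    Returns (frame index, distance value, rmsd value).
    """
    set_rows, res_rows = dist_pairs
    centroid = traj_coords[:, set_rows].mean(axis=1)
    single = traj_coords[:, res_rows].mean(axis=1)
    dist = np.linalg.norm(centroid - single, axis=1)
    diff = traj_coords[:, backbone_rows] - reference.coords[backbone_rows]
    rmsd = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))

    di = np.floor(dist / dist_bin).astype(int)
    ri = np.floor(rmsd / rmsd_bin).astype(int)
    counts: dict[tuple[int, int], int] = {}
    for key in zip(di, ri):
        counts[key] = counts.get(key, 0) + 1
    best_bin = max(counts, key=lambda k: (counts[k], -k[0], -k[1]))
    cx = (best_bin[0] + 0.5) * dist_bin
    cy = (best_bin[1] + 0.5) * rmsd_bin
    score = ((dist - cx) / dist_bin) ** 2 + ((rmsd - cy) / rmsd_bin) ** 2
    frame = int(np.argmin(score))  # argmin takes the earliest on ties
    return frame, float(dist[frame]), float(rmsd[frame])


# ---------------------------------------------------------------------------
# Distance-difference map
# ---------------------------------------------------------------------------

def _mean_ca_distances(ensemble: Ensemble, rows: np.ndarray,
                       masks: Sequence[np.ndarray]) -> np.ndarray:
    r = rows.size
    s1 = np.zeros((r, r))
    n = 0
    for traj, mask in zip(ensemble, masks):
        x = traj.coords[:, rows][mask]
        for t in range(x.shape[0]):
            s1 += np.linalg.norm(x[t, :, None, :] - x[t, None, :, :], axis=-1)
        n += x.shape[0]
    if n == 0:
        raise ValueError("frame mask selects no frames")
    return s1 / n


def distance_difference_map(
    ens_a: Ensemble,
    ens_b: Ensemble,
    atom_name: str = "CA",
    mask_a=None,
    mask_b=None,
    blocks: Mapping[str, Sequence[int]] | None = None,
) -> DistanceDifferenceMap:
    """Δ⟨D_ij⟩ = ⟨D_ij⟩_A − ⟨D_ij⟩_B over residue pairs, plus block means.

    ``blocks`` maps a label (e.g. domain name) to residue ids; block means
    average Δ over all (i, j) with i in one block, j in the other
    (off-diagonal pairs for a block against itself).
    """
    rids_a, rows_a = _ca_indices(ens_a.topology, atom_name)
    rids_b, rows_b = _ca_indices(ens_b.topology, atom_name)
    if rids_a != rids_b:
        raise ValueError("the two ensembles have different residue sets")
    masks_a = _as_masks(ens_a, mask_a)
    masks_b = _as_masks(ens_b, mask_b)
    da = _mean_ca_distances(ens_a, rows_a, masks_a)
    db = _mean_ca_distances(ens_b, rows_b, masks_b)
    delta = da - db
    out = DistanceDifferenceMap(residue_ids=tuple(rids_a), delta=delta)
    if blocks:
        pos = {rid: i for i, rid in enumerate(rids_a)}
        for la, ra in blocks.items():
            for lb, rb in blocks.items():
                ia = [pos[r] for r in ra if r in pos]
                ib = [pos[r] for r in rb if r in pos]
                sub = delta[np.ix_(ia, ib)]
                if la == lb:
                    iu = np.triu_indices(len(ia), k=1)
                    val = float(sub[iu].mean()) if iu[0].size else 0.0
                else:
                    val = float(sub.mean())
                out.block_means[(la, lb)] = val
    return out


def _as_masks(ensemble: Ensemble, mask) -> list[np.ndarray]:
    if mask is None:
        return [np.ones(t.n_frames, dtype=bool) for t in ensemble]
    if isinstance(mask, np.ndarray) and mask.dtype == np.bool_:
        return [mask] * len(ensemble)
    return [np.asarray(m, dtype=bool) for m in mask]


# ---------------------------------------------------------------------------
# Hinge scan
# ---------------------------------------------------------------------------

def hinge_scan(
    avg_a: AverageStructure,
    avg_b: AverageStructure,
    candidates: Sequence[int],
    mobile: Sequence[int],
) -> HingeReport:
    """Correlate distance-from-candidate with per-residue displacement.

    For each candidate residue, the Pearson correlation between (i) the
    distance from the candidate's Cα to each mobile residue's Cα in the
    reference average structure and (ii) that residue's backbone RMSD
    between the two averages.  A true hinge pivot shows displacement
    growing linearly with distance, hence r near 1.
    """
    if len(mobile) < 10:
        raise ValueError("mobile set must contain at least 10 residues "
                         "(correlation is unstable below that)")
    top = avg_a.topology
    disp = per_residue_backbone_rmsd(avg_a, avg_b, mobile)
    if np.allclose(disp, 0.0, atol=1e-12):
        warnings.warn("the two averages are identical over the mobile set; "
                      "hinge correlations are undefined", stacklevel=2)
        return HingeReport(
            candidates=tuple(candidates),
            correlations=np.full(len(candidates), np.nan),
            ranked=tuple((c, float("nan")) for c in candidates),
            degenerate=True,
        )
    mobile_ca = np.array([
        avg_a.coords[top.index_of(top.atom_id(rid, "CA"))] for rid in mobile
    ])
    corrs = np.empty(len(candidates))
    for k, cand in enumerate(candidates):
        ca = avg_a.coords[top.index_of(top.atom_id(cand, "CA"))]
        dist = np.linalg.norm(mobile_ca - ca, axis=1)
        if np.std(dist) == 0:
            corrs[k] = np.nan
            continue
        corrs[k] = pearsonr(dist, disp)[0]
    order = np.argsort(-np.nan_to_num(corrs, nan=-2.0), kind="stable")
    ranked = tuple((int(candidates[i]), float(corrs[i])) for i in order)
    return HingeReport(candidates=tuple(candidates), correlations=corrs,
                       ranked=ranked)


def low_rmsd_candidates(avg_a: AverageStructure, avg_b: AverageStructure,
                        pool: Sequence[int],
                        quantile: float = 0.25) -> list[int]:
    """Candidates: pool residues at or below the per-residue-RMSD quantile.

    RMSDs are floored at twice the median standard error of the mean
    coordinates (rmsf/sqrt(n_frames), combined over both averages): average
    structures cannot resolve displacements below that, so residues under
    the floor form an exact tie and are kept or dropped together rather
    than split by estimation noise.
    """
    rmsd = per_residue_backbone_rmsd(avg_a, avg_b, pool)
    sem = np.sqrt(avg_a.rmsf ** 2 / avg_a.n_frames
                  + avg_b.rmsf ** 2 / avg_b.n_frames)
    floor = 2.0 * float(np.median(sem))
    eff = np.maximum(rmsd, floor)
    cut = np.quantile(eff, quantile)
    return [rid for rid, v in zip(pool, eff) if v <= cut]


# ---------------------------------------------------------------------------
# Latch-distance histograms
# ---------------------------------------------------------------------------

def latch_distance_histograms(
    ensembles: Mapping[str, Ensemble],
    pair: tuple[tuple[int, str], tuple[int, str]],
    bins: np.ndarray,
    masks: Mapping[str, Sequence[np.ndarray]] | None = None,
    tail_offset: float = 2.0,
) -> dict[str, dict]:
    """Normalized histograms of one atom-pair distance per condition.

    Identical bin edges across conditions; each histogram sums to 1 so
    conditions with different frame counts are comparable.  The summary
    reports the modal bin center, the SD of the distances, and the tail
    fraction beyond mode + ``tail_offset`` Å.
    """
    bins = np.asarray(bins, dtype=float)
    out: dict[str, dict] = {}
    for cond, ens in ensembles.items():
        top = ens.topology
        i = top.index_of(top.atom_id(*pair[0]))
        j = top.index_of(top.atom_id(*pair[1]))
        cond_masks = (masks or {}).get(cond)
        ms = _as_masks(ens, cond_masks)
        vals = np.concatenate([
            np.linalg.norm(t.coords[m, i] - t.coords[m, j], axis=1)
            for t, m in zip(ens, ms)
        ])
        if vals.size == 0:
            raise ValueError(f"condition {cond}: empty frame mask")
        counts, _ = np.histogram(vals, bins=bins)
        hist = counts / counts.sum() if counts.sum() else counts.astype(float)
        centers = 0.5 * (bins[:-1] + bins[1:])
        mode = float(centers[int(np.argmax(hist))])
        tail = float(np.mean(vals > mode + tail_offset))
        out[cond] = {
            "hist": hist,
            "bin_edges": bins,
            "mode": mode,
            "sd": float(vals.std()),
            "tail_fraction": tail,
        }
    return out
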