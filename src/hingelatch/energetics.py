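"""Pairwise nonbonded interaction energies and sampling checks.

Energies follow the standard protein force-field nonbonded form: Coulomb
``k_e q_i q_j / (eps_r r_ij)`` with k_e = 332.0636 kcal·Å/(mol·e²), and
Lennard-Jones ``eps_ij [ (r_min,ij/r)^12 - 2 (r_min,ij/r)^6 ]`` with
Lorentz–Berthelot-style combination ``eps_ij = sqrt(eps_i eps_j)`` and
``r_min,ij = r_min,i/2 + r_min,j/2``.  No cutoff or switching is applied by
default; an optional residue-level center-of-mass prefilter reproduces the
computational shortcut of evaluating only residues within a stated radius
of the group of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectory_io import Topology, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyDecomposition",
    "interaction_energy",
    "per_residue_difference",
    "jackknife_check",
]

COULOMB_CONSTANT = 332.0636  # kcal·Å·mol^-1·e^-2

MIN_DISTANCE = 0.1  # Å; anything closer means overlapping atoms


@dataclass
class EnergyDecomposition:
    """Per-frame totals and per-residue-pair mean energies (kcal/mol)."""

    elec: np.ndarray          # (n_frames,)
    vdw: np.ndarray           # (n_frames,)
    pair_table: pd.DataFrame  # residue_a, residue_b, elec, vdw, total (means)
    group_a_residues: tuple[int, ...] = ()
    group_b_residues: tuple[int, ...] = ()

    @property
    def total(self) -> np.ndarray:
        return self.elec + self.vdw

    def per_residue(self, side: str = "b") -> pd.DataFrame:
        """Mean energy summed over the opposite group, per residue."""
        key = "residue_b" if side.lower() == "b" else "residue_a"
        return (
            self.pair_table.groupby(key)[["elec", "vdw", "total"]]
            .sum()
            .rename_axis("residue")
        )


def _gather_params(top: Topology, atom_ids: Sequence[int]):
    q = np.empty(len(atom_ids))
    eps = np.empty(len(atom_ids))
    rmh = np.empty(len(atom_ids))
    rows = np.empty(len(atom_ids), dtype=int)
    resid = np.empty(len(atom_ids), dtype=int)
    for k, aid in enumerate(atom_ids):
        a = top.atom(aid)
        if not a.parameterized:
            raise ValueError(
                f"atom {aid} ({a.residue_name} {a.residue_id} {a.name}) "
                "has no charge/LJ parameters"
            )
        q[k] = a.charge
        eps[k] = a.lj_epsilon
        rmh[k] = a.lj_rmin_half
        rows[k] = top.index_of(aid)
        resid[k] = a.residue_id
    return q, eps, rmh, rows, resid


def interaction_energy(
    traj: Trajectory,
    group_a: Sequence[int],
    group_b: Sequence[int],
    frame_mask: np.ndarray | None = None,
    dielectric: float = 1.0,
    prefilter_com: float | None = None,
) -> EnergyDecomposition:
    """Group–group nonbonded energy, per frame and per residue pair.

    Groups are 1-based atom-id lists and must be disjoint.  With
    ``prefilter_com`` set, group-B residues whose mean center of mass lies
    farther than that radius (Å) from the group-A center of mass (over the
    masked frames) are skipped entirely.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    top = traj.topology
    qa, epsa, rmha, rows_a, res_a = _gather_params(top, group_a)
    qb, epsb, rmhb, rows_b, res_b = _gather_params(top, group_b)
    mask = (np.ones(traj.n_frames, dtype=bool)
            if frame_mask is None else np.asarray(frame_mask, dtype=bool))
    frames = np.nonzero(mask)[0]
    if frames.size == 0:
        raise ValueError("frame mask selects no frames")

    if prefilter_com is not None:
        keep = _com_prefilter(traj, top, rows_a, rows_b, res_b, frames,
                              prefilter_com)
        sel = np.isin(res_b, keep)
        qb, epsb, rmhb, rows_b, res_b = (
            qb[sel], epsb[sel], rmhb[sel], rows_b[sel], res_b[sel]
        )
        if rows_b.size == 0:
            raise ValueError("prefilter removed every group-B residue")

    ke = COULOMB_CONSTANT / dielectric
    qq = ke * np.outer(qa, qb)
    eij = np.sqrt(np.outer(epsa, epsb))
    rmin = rmha[:, None] + rmhb[None, :]

    n = frames.size
    elec_t = np.empty(n)
    vdw_t = np.empty(n)
    elec_sum = np.zeros_like(qq)
    vdw_sum = np.zeros_like(qq)
    for k, f in enumerate(frames):
        xa = traj.coords[f, rows_a]
        xb = traj.coords[f, rows_b]
        diff = xa[:, None, :] - xb[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        if np.any(r < MIN_DISTANCE):
            i, j = np.unravel_index(np.argmin(r), r.shape)
            raise ValueError(
                f"frame {f}: atoms {group_a[i]} and "
                f"{int(np.asarray(group_b)[j])} overlap (r = {r[i, j]:.3f} Å)"
            )
        e_el = qq / r
        sr6 = (rmin / r) ** 6
        e_vdw = eij * (sr6 * sr6 - 2.0 * sr6)
        elec_t[k] = e_el.sum()
        vdw_t[k] = e_vdw.sum()
        elec_sum += e_el
        vdw_sum += e_vdw

    elec_mean = elec_sum / n
    vdw_mean = vdw_sum / n
    records = {}
    for i, ra in enumerate(res_a):
        for j, rb in enumerate(res_b):
            key = (int(ra), int(rb))
            if key not in records:
                records[key] = [0.0, 0.0]
            records[key][0] += elec_mean[i, j]
            records[key][1] += vdw_mean[i, j]
    table = pd.DataFrame(
        [(ra, rb, e, v, e + v) for (ra, rb), (e, v) in sorted(records.items())],
        columns=["residue_a", "residue_b", "elec", "vdw", "total"],
    )
    return EnergyDecomposition(
        elec=elec_t, vdw=vdw_t, pair_table=table,
        group_a_residues=tuple(sorted(set(int(r) for r in res_a))),
        group_b_residues=tuple(sorted(set(int(r) for r in res_b))),
    )


def _com_prefilter(traj, top, rows_a, rows_b, res_b, frames, radius):
    masses = top.masses()
    ma = masses[rows_a]
    com_a = np.zeros(3)
    for f in frames:
        com_a += (traj.coords[f, rows_a] * ma[:, None]).sum(axis=0) / ma.sum()
    com_a /= frames.size
    keep = []
    for rb in np.unique(res_b):
        rows = rows_b[res_b == rb]
        m = masses[rows]
        com = np.zeros(3)
        for f in frames:
            com += (traj.coords[f, rows] * m[:, None]).sum(axis=0) / m.sum()
        com /= frames.size
        if np.linalg.norm(com - com_a) <= radius:
            keep.append(rb)
    return np.array(keep, dtype=int)


def per_residue_difference(
    decomp_a: EnergyDecomposition,
    decomp_b: EnergyDecomposition,
    threshold: float = 0.5,
    side: str = "b",
) -> pd.DataFrame:
    """Residues whose mean interaction energy differs by at least the
    threshold between two conditions, ranked by |Δ| descending.

    Sign convention: Δ = condition A − condition B (reported in the
    ``delta`` column).
    """
    pa = decomp_a.per_residue(side)["total"]
    pb = decomp_b.per_residue(side)["total"]
    if set(pa.index) != set(pb.index):
        raise ValueError("the two decompositions cover different residues")
    delta = (pa - pb).rename("delta")
    df = delta.reset_index()
    df["abs_delta"] = df["delta"].abs()
    df = df[df["abs_delta"] >= threshold].sort_values(
        ["abs_delta", "residue"], ascending=[False, True]
    )
    return df.drop(columns="abs_delta").reset_index(drop=True)


def jackknife_check(
    per_replica_means: Sequence[float],
    per_frame_values: Sequence[float] | None = None,
) -> tuple[float, float, float]:
    """Leave-one-out sampling check.

    Returns (sd of the leave-one-out means, reference sd, their ratio).
    The reference sd is the pooled per-frame sd when frame values are
    given, otherwise the sd across replicas.  For i.i.d. replicas the
    jack-knife sd equals sd(replicas)/(n−1).
    """
    y = np.asarray(per_replica_means, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("jack-knife needs at least 3 replicas")
    loo = (n * y.mean() - y) / (n - 1)
    sd_jk = float(loo.std(ddof=1))
    if per_frame_values is not None:
        ref_sd = float(np.asarray(per_frame_values, dtype=float).std(ddof=1))
    else:
        ref_sd = float(y.std(ddof=1))
    ratio = sd_jk / ref_sd if ref_sd > 0 else float("nan")
    return sd_jk, ref_sd, ratio
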