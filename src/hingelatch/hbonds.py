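"""Hydrogen-bond detection, occupancy statistics, and the binding-state
machine.

A hydrogen bond is present when the donor–acceptor distance is below 3.5 Å
and the donor–hydrogen–acceptor angle (measured at the hydrogen) lies in
(130°, 180°).  Bonds with several chemically equivalent acceptors (e.g. the
two carboxylate oxygens) count as present if any acceptor satisfies the
criterion.

The peptide's binding state is a three-level machine driven by two bond
groups: group A (three bonds whose presence defines tight binding) and
group B (three bonds that keep a partially bound peptide attached).
Transitions are hysteretic: a state persists until the next state's full
criterion — including its persistence window — is met.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np

from .trajectory_io import Topology, Trajectory

__all__ = [
    "HBondSpec",
    "HBondTrace",
    "BindingState",
    "BindingTrace",
    "TerminationMetricSpec",
    "detect_hbonds",
    "hbond_probability",
    "joint_occupancy",
    "classify_binding",
    "termination_metric",
    "equilibration_mask",
]

DIST_CUTOFF = 3.5      # Å, donor-acceptor
ANGLE_MIN = 130.0      # degrees, D-H-A at the hydrogen
ANGLE_MAX = 180.0


class BindingState(IntEnum):
    FULLY_BOUND = 0
    PARTIALLY_BOUND = 1
    UNBOUND = 2


@dataclass(frozen=True)
class HBondSpec:
    """One monitored hydrogen bond, by 1-based atom ids."""

    label: str
    donor: int
    hydrogen: int
    acceptors: tuple[int, ...]
    group: str = "OTHER"  # A | B | CATALYTIC | OTHER

    @staticmethod
    def from_names(topology: Topology, label: str,
                   donor: tuple[int, str], hydrogen: tuple[int, str],
                   acceptors: Sequence[tuple[int, str]],
                   group: str = "OTHER") -> "HBondSpec":
        return HBondSpec(
            label=label,
            donor=topology.atom_id(*donor),
            hydrogen=topology.atom_id(*hydrogen),
            acceptors=tuple(topology.atom_id(*a) for a in acceptors),
            group=group,
        )


@dataclass
class HBondTrace:
    """Per-bond, per-frame occupancy and minimum donor-acceptor distance."""

    labels: tuple[str, ...]
    occupancy: np.ndarray   # (n_bonds, n_frames) bool
    distances: np.ndarray   # (n_bonds, n_frames) Å, min over acceptor set
    dt: float
    replica_id: str = "0"

    @property
    def n_frames(self) -> int:
        return self.occupancy.shape[1]

    def bond_index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class BindingTrace:
    states: np.ndarray                 # (n_frames,) BindingState codes
    termination_frame: int | None = None
    dt: float = 1.0
    replica_id: str = "0"


@dataclass(frozen=True)
class TerminationMetricSpec:
    """Sum of three donor-acceptor distances plus one heavy-atom distance.

    The heavy-atom pair proxies the key van-der-Waals contact (the real
    system uses the p+2 Cβ — I572 Cδ distance); the default threshold of
    80 Å marks a peptide far outside the binding pocket.
    """

    pairs: tuple[tuple[int, int], ...]  # exactly four (atom_id, atom_id)
    threshold: float = 80.0

    def __post_init__(self):
        if len(self.pairs) != 4:
            raise ValueError("termination metric requires exactly four pairs")


def _check_hydrogen_geometry(traj: Trajectory, spec: HBondSpec) -> None:
    top = traj.topology
    d = traj.coords[0, top.index_of(spec.donor)]
    h = traj.coords[0, top.index_of(spec.hydrogen)]
    if np.linalg.norm(h - d) > 1.5:
        warnings.warn(
            f"H-bond {spec.label!r}: hydrogen is {np.linalg.norm(h - d):.2f} Å "
            "from its donor in the first frame; check atom assignment",
            stacklevel=3,
        )


def detect_hbonds(traj: Trajectory, specs: Sequence[HBondSpec]) -> HBondTrace:
    """Evaluate the geometric H-bond criterion for every bond and frame."""
    top = traj.topology
    n_frames = traj.n_frames
    occupancy = np.zeros((len(specs), n_frames), dtype=bool)
    distances = np.full((len(specs), n_frames), np.inf)

    for b, spec in enumerate(specs):
        for atom_id in (spec.donor, spec.hydrogen, *spec.acceptors):
            if atom_id not in top._index_of:
                raise KeyError(f"H-bond {spec.label!r}: atom {atom_id} not in topology")
        _check_hydrogen_geometry(traj, spec)
        d_xyz = traj.coords[:, top.index_of(spec.donor)]     # (F, 3)
        h_xyz = traj.coords[:, top.index_of(spec.hydrogen)]
        for acc in spec.acceptors:
            a_xyz = traj.coords[:, top.index_of(acc)]
            da = np.linalg.norm(a_xyz - d_xyz, axis=1)
            hd = d_xyz - h_xyz
            ha = a_xyz - h_xyz
            cos_t = np.einsum("ij,ij->i", hd, ha) / (
                np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1)
            )
            theta = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
            ok = (da < DIST_CUTOFF) & (theta > ANGLE_MIN) & (theta < ANGLE_MAX)
            occupancy[b] |= ok
            distances[b] = np.minimum(distances[b], da)

    return HBondTrace(
        labels=tuple(s.label for s in specs),
        occupancy=occupancy,
        distances=distances,
        dt=traj.dt,
        replica_id=traj.replica_id,
    )


def equilibration_mask(n_frames: int, dt: float,
                       exclude_ns: float = 50.0) -> np.ndarray:
    """Boolean frame mask dropping the initial equilibration stretch."""
    start = min(n_frames, int(math.ceil(exclude_ns / dt)))
    mask = np.zeros(n_frames, dtype=bool)
    mask[start:] = True
    return mask


def hbond_probability(
    traces: Sequence[HBondTrace],
    frame_mask: np.ndarray | Sequence[np.ndarray] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-bond occupancy: mean of per-replica means, SD across replicas.

    ``frame_mask`` may be one mask shared by all replicas or one per replica.
    The SD is the sample standard deviation (ddof=1) of the per-replica
    means; it is 0.0 with a single replica.
    """
    if not traces:
        raise ValueError("need at least one trace")
    masks = _per_replica_masks(traces, frame_mask)
    labels = traces[0].labels
    per_rep = np.empty((len(traces), len(labels)))
    for r, (trace, mask) in enumerate(zip(traces, masks)):
        if not mask.any():
            raise ValueError("frame mask is empty")
        per_rep[r] = trace.occupancy[:, mask].mean(axis=1)
    mean = per_rep.mean(axis=0)
    sd = per_rep.std(axis=0, ddof=1) if len(traces) > 1 else np.zeros(len(labels))
    return {lab: (float(mean[i]), float(sd[i])) for i, lab in enumerate(labels)}


def _per_replica_masks(traces, frame_mask):
    if frame_mask is None:
        return [np.ones(t.n_frames, dtype=bool) for t in traces]
    if isinstance(frame_mask, np.ndarray) and frame_mask.dtype == np.bool_:
        return [frame_mask] * len(traces)
    # sequence of masks
    masks = [np.asarray(m, dtype=bool) for m in frame_mask]
    if len(masks) != len(traces):
        raise ValueError("one frame mask per replica required")
    return masks


def joint_occupancy(
    traces: Sequence[HBondTrace],
    bonds: Sequence[str],
    mode: str = "all_present",
    frame_mask=None,
) -> float:
    """Fraction of masked frames (pooled over replicas) where every bond in
    ``bonds`` is simultaneously present (or absent)."""
    if not bonds:
        raise ValueError("bond subset must be non-empty")
    if mode not in ("all_present", "all_absent"):
        raise ValueError("mode must be 'all_present' or 'all_absent'")
    masks = _per_replica_masks(traces, frame_mask)
    hits = 0
    total = 0
    for trace, mask in zip(traces, masks):
        idx = [trace.bond_index(b) for b in bonds]
        occ = trace.occupancy[idx][:, mask]
        joint = occ.all(axis=0) if mode == "all_present" else (~occ).all(axis=0)
        hits += int(joint.sum())
        total += int(mask.sum())
    if total == 0:
        raise ValueError("frame mask is empty")
    return hits / total


def classify_binding(
    trace: HBondTrace,
    group_a: Sequence[str],
    group_b: Sequence[str],
    persistence_ns: float = 5.0,
    dt: float | None = None,
    allow_rebinding: bool = False,
) -> BindingTrace:
    """Run the three-state binding machine over an H-bond trace.

    The machine starts FULLY_BOUND (trajectories begin from the bound pose).
    It moves to PARTIALLY_BOUND at the first frame where all group-A bonds
    have been simultaneously absent for strictly longer than the persistence
    window while at least one group-B bond is present, and to UNBOUND at the
    first frame where all six bonds have been simultaneously absent for
    strictly longer than the window.  If the A bonds return before the
    window completes, the state never leaves FULLY_BOUND; once
    PARTIALLY_BOUND, return to FULLY_BOUND requires ``allow_rebinding=True``
    (stable rebinding is not observed in the source system, so the default
    forbids it).  UNBOUND is absorbing.

    The window in frames is ``ceil(persistence_ns / dt)``; "absent for
    longer than the window" means a run of at least window+1 absent frames.
    """
    dt = trace.dt if dt is None else dt
    window = max(1, math.ceil(persistence_ns / dt))
    if set(group_a) & set(group_b):
        raise ValueError("groups A and B must be disjoint")
    ia = [trace.bond_index(b) for b in group_a]
    ib = [trace.bond_index(b) for b in group_b]
    n = trace.n_frames
    if n <= window:
        warnings.warn(
            "trace is shorter than the persistence window; "
            "returning a single-state trace", stacklevel=2,
        )
    a_on = trace.occupancy[ia].any(axis=0)
    b_on = trace.occupancy[ib].any(axis=0)

    states = np.empty(n, dtype=int)
    state = BindingState.FULLY_BOUND
    run_a = 0      # consecutive frames with every group-A bond absent
    run_all = 0    # consecutive frames with all six bonds absent
    for t in range(n):
        run_a = 0 if a_on[t] else run_a + 1
        run_all = 0 if (a_on[t] or b_on[t]) else run_all + 1
        if state == BindingState.FULLY_BOUND:
            if run_all > window:
                state = BindingState.UNBOUND
            elif run_a > window and b_on[t]:
                state = BindingState.PARTIALLY_BOUND
        elif state == BindingState.PARTIALLY_BOUND:
            if run_all > window:
                state = BindingState.UNBOUND
            elif allow_rebinding and a_on[t] and b_on[t]:
                state = BindingState.FULLY_BOUND
        states[t] = state
    return BindingTrace(states=states, dt=dt, replica_id=trace.replica_id)


def termination_metric(
    traj: Trajectory, spec: TerminationMetricSpec
) -> tuple[np.ndarray, int | None]:
    """Per-frame distance sum (Å) and the first frame strictly above the
    threshold (or None)."""
    top = traj.topology
    total = np.zeros(traj.n_frames)
    for a, b in spec.pairs:
        xa = traj.coords[:, top.index_of(a)]
        xb = traj.coords[:, top.index_of(b)]
        total += np.linalg.norm(xa - xb, axis=1)
    over = np.nonzero(total > spec.threshold)[0]
    return total, (int(over[0]) if over.size else None)
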