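"""Synthetic multi-replica ensembles with known ground truth.

The generator does not pretend to be physics: it manufactures coordinate time
series that carry exactly the statistical structure the downstream analyses
assume — hydrogen-bond geometries toggling under a two-state Markov schedule
at target occupancies, a rigid-body rotation of the mobile (periplasmic-like)
domain about a known pivot, blocks of atoms sharing a latent correlated
displacement, scripted peptide-unbinding drifts, and isotropic Gaussian
positional noise on top.  Every stochastic ingredient is recorded in a
:class:`GroundTruth` so parameter-recovery tests have an exact reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import (
    AtomRecord,
    DomainLabel,
    Ensemble,
    Topology,
    Trajectory,
)

__all__ = [
    "HBondSchedule",
    "CorrBlock",
    "HingeSpec",
    "SyntheticSpec",
    "GroundTruth",
    "build_topology",
    "simulate",
    "nat_like_spec",
    "nas_like_spec",
]

# backbone offsets from Cα, Å (idealized local geometry; not a force field)
_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.40, 0.00]),
    "H": np.array([-1.80, 0.40, 0.80]),   # 1.0 Å from N, pointing away from CA
    "CA": np.array([0.00, 0.00, 0.00]),
    "C": np.array([1.20, 0.40, 0.00]),
    "O": np.array([1.20, 1.60, 0.00]),
    "CB": np.array([0.00, -1.53, 0.00]),
}
_ELEMENT_OF = {"N": "N", "H": "H", "CA": "C", "C": "C", "O": "O", "CB": "C"}
_MASS_OF = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}
# per-element Lennard-Jones parameters (kcal/mol, Å); polar hydrogens get a
# near-zero radius, as in protein force fields, so hydrogen-bond contacts
# (H...acceptor ~2 Å) are not treated as steric clashes
_LJ_OF = {
    "H": (0.046, 0.2245),
    "C": (0.070, 2.000),
    "N": (0.200, 1.850),
    "O": (0.120, 1.700),
}


@dataclass
class HBondSchedule:
    """One programmed hydrogen bond.

    Atoms are addressed as ``(residue_id, atom_name)``.  ``p_on`` is the
    target stationary occupancy; ``mean_dwell_on`` the mean dwell time of the
    on state in ns (the off dwell follows from the occupancy).
    """

    label: str
    donor: tuple[int, str]
    hydrogen: tuple[int, str]
    acceptors: tuple[tuple[int, str], ...]
    p_on: float
    mean_dwell_on: float = 10.0  # ns
    group: str = "OTHER"         # A | B | CATALYTIC | OTHER

    def __post_init__(self):
        if not 0.0 <= self.p_on <= 1.0:
            raise ValueError(f"{self.label}: p_on must be in [0, 1]")
        self.acceptors = tuple(tuple(a) for a in self.acceptors)


@dataclass
class CorrBlock:
    """Atoms sharing a common latent displacement at a target correlation."""

    atoms: tuple[tuple[int, str], ...]
    target_correlation: float

    def __post_init__(self):
        if not 0.0 < self.target_correlation <= 1.0:
            raise ValueError("target correlation must be in (0, 1]")
        self.atoms = tuple(tuple(a) for a in self.atoms)


@dataclass
class HingeSpec:
    """Rigid-body rotation of the mobile domain about a pivot residue.

    The hinge angle follows an Ornstein–Uhlenbeck process with stationary
    mean/sd (degrees) and correlation time (ns), discretized as an AR(1).
    """

    pivot_residue_id: int
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    mean_deg: float = 0.0
    sd_deg: float = 0.0
    corr_time_ns: float = 5.0


@dataclass
class SyntheticSpec:
    """Full description of a synthetic multi-replica ensemble."""

    n_replicas: int = 3
    n_frames: int = 2000
    dt: float = 0.1  # ns/frame
    n_tm: int = 60   # residues in the static (transmembrane-like) domain
    n_pp: int = 40   # residues in the mobile (periplasmic-like) domain
    n_peptide: int = 8
    hinge: HingeSpec | None = None
    hbonds: tuple[HBondSchedule, ...] = ()
    unbind_events: dict[str, float] = field(default_factory=dict)  # replica -> ns
    corr_blocks: tuple[CorrBlock, ...] = ()
    noise_sd: float = 0.05   # Å
    unbind_speed: float = 0.5  # Å/ns
    seed: int = 0
    condition: str = "SYN"

    def __post_init__(self):
        self.hbonds = tuple(self.hbonds)
        self.corr_blocks = tuple(self.corr_blocks)
        longest_dwell = max((hb.mean_dwell_on for hb in self.hbonds), default=0.0)
        if longest_dwell and self.n_frames * self.dt < 10 * longest_dwell:
            warnings.warn(
                "trajectory length is under 10x the longest H-bond dwell "
                "time; occupancy estimates will be noisy",
                stacklevel=2,
            )

    # residue-id layout: TM = 1..n_tm, PP follows, peptide follows
    @property
    def tm_range(self) -> tuple[int, int]:
        return (1, self.n_tm)

    @property
    def pp_range(self) -> tuple[int, int]:
        return (self.n_tm + 1, self.n_tm + self.n_pp)

    @property
    def peptide_range(self) -> tuple[int, int]:
        lo = self.n_tm + self.n_pp + 1
        return (lo, lo + self.n_peptide - 1)


@dataclass
class GroundTruth:
    """Everything the generator actually did, for recovery tests."""

    pivot_residue_id: int | None
    occupancies: dict[str, float]                      # bond label -> p_on
    schedules: dict[str, np.ndarray]                   # replica -> (n_bonds, n_frames) bool
    binding_states: dict[str, np.ndarray]              # replica -> int array (0/1/2)
    hinge_angles: dict[str, np.ndarray]                # replica -> degrees
    block_correlations: tuple[float, ...]
    unbind_starts: dict[str, float]
    bond_labels: tuple[str, ...]


# binding-state codes shared with hbonds.BindingState
_FULLY, _PARTIALLY, _UNBOUND = 0, 1, 2


def _ca_template(spec: SyntheticSpec) -> dict[int, np.ndarray]:
    """Cα positions for the template.

    The static domain is a tall coil around the origin.  The mobile domain
    is a flat spiral fan in the plane of its first residue (the natural
    hinge point at the domain interface): each residue sits at a growing
    radius and winding angle from the pivot, so a rotation about the
    vertical axis through the pivot displaces every mobile residue in exact
    proportion to its distance from the pivot, while distance measured from
    any other point mixes in the winding angle and decorrelates — the
    geometry that makes the hinge scan identifiable.  The peptide lies in
    the groove between the two domains.
    """
    ca: dict[int, np.ndarray] = {}
    # static domain: coil around the origin, rise 1.0 Å/residue
    for i in range(spec.n_tm):
        theta = 0.6 * i
        ca[1 + i] = np.array([8.0 * math.cos(theta), 8.0 * math.sin(theta), float(i)])
    # mobile domain: spiral fan around the pivot at (20, 0, 30); the fan
    # lies 6 Å above the pivot plane so it clears the peptide groove
    x0 = np.array([20.0, 0.0, 30.0])
    for i in range(spec.n_pp):
        rho = 3.0 * min(i, 1) + 1.2 * i
        phi = 0.7 * i
        lift = 6.0 * min(i, 1)
        ca[spec.pp_range[0] + i] = x0 + np.array(
            [rho * math.cos(phi), rho * math.sin(phi),
             lift + 0.8 * math.sin(1.1 * i)]
        )
    # peptide: strand in the interface groove
    for i in range(spec.n_peptide):
        ca[spec.peptide_range[0] + i] = np.array([15.0, -8.0 + 2.5 * i, 28.0])
    return ca


def build_topology(spec: SyntheticSpec) -> Topology:
    """Construct the template topology with backbone atoms per residue plus
    any extra atoms the declared H-bonds require.

    Every atom receives alternating ±0.4 e charges and uniform LJ parameters
    so the energetics module can run on any synthetic system.
    """
    for n, label in ((spec.n_tm, "TM"), (spec.n_pp, "PP"), (spec.n_peptide, "peptide")):
        if n < 1:
            raise ValueError(f"layout requires at least one {label} residue")

    ca = _ca_template(spec)
    extra: dict[int, list[str]] = {}
    for hb in spec.hbonds:
        for rid, name in (hb.donor, hb.hydrogen, *hb.acceptors):
            if rid not in ca:
                raise ValueError(
                    f"H-bond {hb.label!r} references residue {rid}, which is "
                    "not in the layout"
                )
            if name not in _BACKBONE_OFFSETS:
                extra.setdefault(rid, [])
                if name not in extra[rid]:
                    extra[rid].append(name)

    atoms: list[AtomRecord] = []
    aid = 0
    sign = 1.0
    tm_lo, tm_hi = spec.tm_range
    pp_lo, pp_hi = spec.pp_range
    for rid in sorted(ca):
        if tm_lo <= rid <= tm_hi:
            label, resname, seg = DomainLabel.TM, "TMR", "PROT"
        elif pp_lo <= rid <= pp_hi:
            label, resname, seg = DomainLabel.PP, "PPR", "PROT"
        else:
            label, resname, seg = DomainLabel.PEPTIDE, "PEP", "PEPT"
        names = list(_BACKBONE_OFFSETS) + sorted(extra.get(rid, []))
        for k, name in enumerate(names):
            aid += 1
            element = _ELEMENT_OF.get(
                name, next((e for e in ("O", "N", "H") if name.startswith(e)),
                           "C"))
            eps, rmh = _LJ_OF[element]
            atoms.append(
                AtomRecord(
                    atom_id=aid,
                    name=name,
                    element=element,
                    residue_id=rid,
                    residue_name=resname,
                    segment=seg,
                    domain_label=label,
                    mass=_MASS_OF.get(element, 12.011),
                    charge=sign * 0.4,
                    lj_epsilon=eps,
                    lj_rmin_half=rmh,
                )
            )
            sign = -sign
    return Topology(atoms)


def _template_coords(spec: SyntheticSpec, top: Topology) -> np.ndarray:
    ca = _ca_template(spec)
    coords = np.zeros((top.n_atoms, 3))
    side_slots = {}  # extra side-chain atoms fan out around Cα
    for i, a in enumerate(top.atoms):
        base = ca[a.residue_id]
        if a.name in _BACKBONE_OFFSETS:
            coords[i] = base + _BACKBONE_OFFSETS[a.name]
        else:
            k = side_slots.setdefault(a.residue_id, 0)
            side_slots[a.residue_id] = k + 1
            ang = 2.4 * k
            coords[i] = base + np.array(
                [1.8 * math.cos(ang), -1.8, 1.8 * math.sin(ang)]
            )
    # non-backbone donor hydrogens sit 1.0 Å from their donor heavy atom
    # (the H-bond detector requires a covalently plausible D-H geometry)
    unit = np.array([0.6, 0.0, 0.8])
    for hb in spec.hbonds:
        if hb.hydrogen[1] not in _BACKBONE_OFFSETS:
            h_i = top.index_of(top.atom_id(*hb.hydrogen))
            d_i = top.index_of(top.atom_id(*hb.donor))
            coords[h_i] = coords[d_i] + unit
    return coords


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(axis * angle_rad).as_matrix()


def _markov_schedule(rng: np.random.Generator, n_frames: int, dt: float,
                     p_on: float, mean_dwell_on: float) -> np.ndarray:
    """Two-state CTMC discretized at dt, stationary occupancy p_on.

    The discretization preserves the stationary occupancy and the
    relaxation time exactly; mean dwell times are approximate (they
    stretch when the off rate times dt is not small).
    """
    if p_on <= 0.0:
        return np.zeros(n_frames, dtype=bool)
    if p_on >= 1.0:
        return np.ones(n_frames, dtype=bool)
    k_off = 1.0 / mean_dwell_on                       # on -> off rate (1/ns)
    k_on = k_off * p_on / (1.0 - p_on)                # off -> on rate
    # exact discrete-time transition matrix of the two-state CTMC: the
    # naive per-rate form 1 - exp(-k dt) biases the stationary occupancy
    # whenever k dt is not small
    relax = 1.0 - math.exp(-(k_on + k_off) * dt)
    p_off_step = (1.0 - p_on) * relax
    p_on_step = p_on * relax
    state = rng.random() < p_on
    out = np.empty(n_frames, dtype=bool)
    u = rng.random(n_frames)
    for t in range(n_frames):
        out[t] = state
        if state:
            if u[t] < p_off_step:
                state = False
        else:
            if u[t] < p_on_step:
                state = True
    return out


def _ou_angles(rng: np.random.Generator, n_frames: int, dt: float,
               mean: float, sd: float, tau: float) -> np.ndarray:
    """AR(1) discretization of an OU process, in degrees."""
    if sd <= 0:
        return np.full(n_frames, mean)
    phi = math.exp(-dt / tau)
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    x = np.empty(n_frames)
    x[0] = rng.normal(mean, sd)
    eps = rng.normal(0.0, innov_sd, n_frames)
    for t in range(1, n_frames):
        x[t] = mean + phi * (x[t - 1] - mean) + eps[t]
    return x


def _place_acceptor(rng: np.random.Generator, d_pos: np.ndarray,
                    h_pos: np.ndarray) -> np.ndarray:
    """Place an acceptor so the bond geometry is decisively 'on'.

    Draws D–A distance in [2.7, 3.2] Å and D–H–A angle in [155°, 175°],
    inside the generator's contract of [2.6, 3.3] Å / [150°, 180°].
    """
    d_target = rng.uniform(2.7, 3.2)
    theta = math.radians(rng.uniform(155.0, 175.0))
    dh = h_pos - d_pos
    ldh = np.linalg.norm(dh)
    u = dh / ldh
    # law of cosines at H: |DA|^2 = |DH|^2 + |HA|^2 - 2 |DH||HA| cos(theta)
    b = -2.0 * ldh * math.cos(theta)
    c = ldh * ldh - d_target * d_target
    disc = b * b - 4.0 * c
    lha = (-b + math.sqrt(max(disc, 0.0))) / 2.0
    # direction of H->A: rotate the extension of D->H by (180 - theta)
    perp = np.cross(u, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(u, np.array([0.0, 1.0, 0.0]))
    perp /= np.linalg.norm(perp)
    alpha = math.pi - theta
    direction = math.cos(alpha) * u + math.sin(alpha) * perp
    return h_pos + lha * direction


def _binding_oracle(schedules: np.ndarray, groupA: list[int], groupB: list[int],
                    window_frames: int) -> np.ndarray:
    """State machine over true schedules (same reading as the classifier)."""
    n = schedules.shape[1]
    states = np.empty(n, dtype=int)
    state = _FULLY
    run_a = 0
    run_all = 0
    for t in range(n):
        a_on = schedules[groupA, t].any()
        b_on = schedules[groupB, t].any()
        run_a = 0 if a_on else run_a + 1
        run_all = 0 if (a_on or b_on) else run_all + 1
        if state == _FULLY:
            if run_all > window_frames:
                state = _UNBOUND
            elif run_a > window_frames and b_on:
                state = _PARTIALLY
        elif state == _PARTIALLY:
            if run_all > window_frames:
                state = _UNBOUND
        states[t] = state
    return states


def simulate(spec: SyntheticSpec) -> tuple[Ensemble, GroundTruth]:
    """Generate the ensemble and its ground truth.

    Per-frame assembly order: rigid template → hinge rotation of the mobile
    domain → correlated-block latent displacements → peptide unbinding drift
    → H-bond acceptor placement → isotropic Gaussian noise.  Replica r uses
    the substream seeded with ``seed + r`` so replicas are independent but
    individually reproducible.
    """
    top = build_topology(spec)
    template = _template_coords(spec, top)
    n_atoms = top.n_atoms

    pp_idx = np.array(
        [i for i, a in enumerate(top.atoms) if a.domain_label == DomainLabel.PP],
        dtype=int,
    )
    pep_idx = np.array(
        [i for i, a in enumerate(top.atoms)
         if a.domain_label == DomainLabel.PEPTIDE],
        dtype=int,
    )

    hinge = spec.hinge
    if hinge is not None:
        if hinge.pivot_residue_id not in top.residues:
            raise ValueError(
                f"hinge pivot residue {hinge.pivot_residue_id} does not exist"
            )
        pivot = template[top.index_of(
            top.atom_id(hinge.pivot_residue_id, "CA"))]
        axis = np.asarray(hinge.axis, dtype=float)
        # the fulcrum residue itself does not swing: it belongs to both
        # domains, so only mobile residues past it rotate
        pp_idx = np.array(
            [i for i, a in enumerate(top.atoms)
             if a.domain_label == DomainLabel.PP
             and a.residue_id != hinge.pivot_residue_id],
            dtype=int,
        )

    # resolve H-bond atoms once
    bond_atoms = []
    for hb in spec.hbonds:
        try:
            d = top.index_of(top.atom_id(*hb.donor))
            h = top.index_of(top.atom_id(*hb.hydrogen))
            accs = [top.index_of(top.atom_id(*a)) for a in hb.acceptors]
        except KeyError as exc:
            raise ValueError(f"H-bond {hb.label!r}: {exc}") from exc
        touches_peptide = any(
            top.atoms[i].domain_label == DomainLabel.PEPTIDE
            for i in (d, h, *accs)
        )
        bond_atoms.append((d, h, accs, touches_peptide))

    # correlated blocks: latent scalar amplitude per block per frame
    block_info = []
    for blk in spec.corr_blocks:
        idx = np.array(
            [top.index_of(top.atom_id(*a)) for a in blk.atoms], dtype=int
        )
        rho = blk.target_correlation
        # shared 3-vector displacement s(t) (iid components, sd sigma_s)
        # plus isotropic noise (sd noise_sd per component) per atom gives
        # C = sigma_s^2 / (sigma_s^2 + noise_sd^2)  =>  solve for sigma_s
        if rho >= 1.0:
            sigma_s = None  # handled as noise-free copy below
        else:
            sigma_s = spec.noise_sd * math.sqrt(rho / (1.0 - rho))
        block_info.append((idx, sigma_s))

    trajectories = []
    gt_sched: dict[str, np.ndarray] = {}
    gt_states: dict[str, np.ndarray] = {}
    gt_angles: dict[str, np.ndarray] = {}

    groupA = [i for i, hb in enumerate(spec.hbonds) if hb.group == "A"]
    groupB = [i for i, hb in enumerate(spec.hbonds) if hb.group == "B"]
    window_frames = max(1, math.ceil(5.0 / spec.dt))  # 5 ns reference window

    for r in range(spec.n_replicas):
        rep_id = str(r)
        rng = np.random.default_rng(spec.seed + r)
        n = spec.n_frames

        # schedules
        schedules = np.zeros((len(spec.hbonds), n), dtype=bool)
        for b, hb in enumerate(spec.hbonds):
            schedules[b] = _markov_schedule(rng, n, spec.dt, hb.p_on,
                                            hb.mean_dwell_on)

        unbind_t0 = spec.unbind_events.get(rep_id)
        unbind_frame = None
        if unbind_t0 is not None:
            unbind_frame = int(round(unbind_t0 / spec.dt))
            for b, (hb, (_, _, _, touches)) in enumerate(
                zip(spec.hbonds, bond_atoms)
            ):
                if touches and schedules[b, unbind_frame:].any():
                    if hb.p_on >= 1.0:
                        warnings.warn(
                            f"H-bond {hb.label!r} has p_on=1 but its peptide "
                            "unbinds; schedule forced off after the event",
                            stacklevel=2,
                        )
                    schedules[b, unbind_frame:] = False

        angles = (
            _ou_angles(rng, n, spec.dt, hinge.mean_deg, hinge.sd_deg,
                       hinge.corr_time_ns)
            if hinge is not None
            else np.zeros(n)
        )

        block_amp = [
            (idx, sigma_s,
             rng.normal(0.0, 1.0, (n, 3)))  # latent unit-variance 3-vector
            for idx, sigma_s in block_info
        ]

        coords = np.empty((n, n_atoms, 3))
        for t in range(n):
            frame = template.copy()
            if hinge is not None:
                R = _rotation_matrix(axis, math.radians(angles[t]))
                frame[pp_idx] = (frame[pp_idx] - pivot) @ R.T + pivot
            for idx, sigma_s, lat in block_amp:
                if sigma_s is not None:
                    frame[idx] += sigma_s * lat[t]
            if unbind_frame is not None and t >= unbind_frame:
                drift = spec.unbind_speed * (t - unbind_frame) * spec.dt
                frame[pep_idx] += drift * np.array([0.0, -1.0, 0.0]) / 1.0
            for b, (d, h, accs, touches) in enumerate(bond_atoms):
                past_unbind = unbind_frame is not None and t >= unbind_frame and touches
                if past_unbind:
                    continue  # leave acceptor at its drifted/template spot
                if schedules[b, t]:
                    pos = _place_acceptor(rng, frame[d], frame[h])
                    frame[accs[0]] = pos
                    for extra_a in accs[1:]:
                        frame[extra_a] = pos + rng.normal(0.0, 0.05, 3)
                else:
                    dh = frame[h] - frame[d]
                    u = dh / np.linalg.norm(dh)
                    frame[accs[0]] = frame[d] + 5.5 * u
                    for extra_a in accs[1:]:
                        frame[extra_a] = frame[accs[0]] + rng.normal(0.0, 0.05, 3)
            coords[t] = frame
        coords += rng.normal(0.0, spec.noise_sd, coords.shape)

        # perfect-correlation blocks: overwrite noise so copies are exact
        for (idx, sigma_s), blk in zip(block_info, spec.corr_blocks):
            if sigma_s is None and len(idx) > 1:
                coords[:, idx[1:], :] = (
                    coords[:, [idx[0]], :]
                    - template[idx[0]] + template[idx[1:]]
                )

        trajectories.append(
            Trajectory(top, coords, spec.dt, replica_id=rep_id,
                       condition=spec.condition)
        )
        gt_sched[rep_id] = schedules
        gt_angles[rep_id] = angles
        if groupA and groupB:
            gt_states[rep_id] = _binding_oracle(schedules, groupA, groupB,
                                                window_frames)
        else:
            gt_states[rep_id] = np.zeros(n, dtype=int)

    truth = GroundTruth(
        pivot_residue_id=hinge.pivot_residue_id if hinge else None,
        occupancies={hb.label: hb.p_on for hb in spec.hbonds},
        schedules=gt_sched,
        binding_states=gt_states,
        hinge_angles=gt_angles,
        block_correlations=tuple(b.target_correlation for b in spec.corr_blocks),
        unbind_starts=dict(spec.unbind_events),
        bond_labels=tuple(hb.label for hb in spec.hbonds),
    )
    return Ensemble(trajectories), truth


# ---------------------------------------------------------------------------
# Reference study conditions
# ---------------------------------------------------------------------------

def _standard_bonds(occupancies: dict[str, float]) -> tuple[HBondSchedule, ...]:
    """Six binding-indicator bonds on the synthetic layout.

    Groups mirror the binding-state table: group A (tight binding) are the
    three bonds whose joint loss marks partial unbinding; group B keep a
    partially bound peptide attached.  Donor/acceptor placement alternates
    between protein and peptide as in the real pocket.
    """
    # layout: TM 1..60, PP 61..100, peptide 101..108; p+2-like residue = 106
    # acceptors are side-chain-like extra atoms on residues lining the
    # interface groove, so toggling them never perturbs backbone geometry
    defs = [
        ("A1", (101, "N"), (101, "H"), ((63, "OE1"),), "A"),
        ("A2", (106, "N"), (106, "H"), ((64, "OD1"), (64, "OD2")), "A"),
        ("A3", (103, "N"), (103, "H"), ((65, "NE2"),), "A"),
        ("B1", (106, "OG1"), (106, "HG1"), ((62, "OE1"),), "B"),
        ("B2", (104, "N"), (104, "H"), ((28, "OE1"),), "B"),
        ("B3", (107, "N"), (107, "H"), ((29, "OE1"),), "B"),
    ]
    out = []
    for label, d, h, accs, grp in defs:
        out.append(
            HBondSchedule(
                label=label, donor=d, hydrogen=h, acceptors=accs,
                p_on=occupancies[label], mean_dwell_on=10.0, group=grp,
            )
        )
    return tuple(out)


# Bond-wise target occupancies follow the two experimental conditions of the
# source system: the optimal (threonine-like, "tight") and impaired
# (serine-like, "loose") acceptor peptides.
_TIGHT_OCC = {"A1": 0.83, "A2": 0.91, "A3": 0.78, "B1": 0.92, "B2": 0.32, "B3": 0.81}
_LOOSE_OCC = {"A1": 0.61, "A2": 0.68, "A3": 0.38, "B1": 0.58, "B2": 0.16, "B3": 0.36}

def nat_like_spec(n_replicas: int = 3, n_frames: int = 2000, seed: int = 0,
                  **overrides) -> SyntheticSpec:
    """'Tight' condition: high bond occupancies, small hinge amplitude."""
    kw = dict(
        n_replicas=n_replicas,
        n_frames=n_frames,
        dt=0.1,
        hinge=HingeSpec(pivot_residue_id=61, axis=(0.0, 0.0, 1.0),
                        mean_deg=0.0, sd_deg=1.5, corr_time_ns=5.0),
        hbonds=_standard_bonds(_TIGHT_OCC),
        noise_sd=0.05,
        seed=seed,
        condition="TIGHT",
    )
    kw.update(overrides)
    return SyntheticSpec(**kw)


def nas_like_spec(n_replicas: int = 3, n_frames: int = 2000, seed: int = 1000,
                  **overrides) -> SyntheticSpec:
    """'Loose' condition: lowered occupancies, opened and wobblier hinge."""
    kw = dict(
        n_replicas=n_replicas,
        n_frames=n_frames,
        dt=0.1,
        hinge=HingeSpec(pivot_residue_id=61, axis=(0.0, 0.0, 1.0),
                        mean_deg=10.0, sd_deg=4.0, corr_time_ns=5.0),
        hbonds=_standard_bonds(_LOOSE_OCC),
        noise_sd=0.05,
        seed=seed,
        condition="LOOSE",
    )
    kw.update(overrides)
    return SyntheticSpec(**kw)
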