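"""Structures, trajectory ensembles, and selections.

The data model is deliberately small: a :class:`Topology` (ordered atoms with
residue, segment, domain label, and optional nonbonded parameters), per-frame
coordinate arrays in Å, and a :class:`Trajectory` that pairs the two with a
constant frame spacing ``dt`` in ns.  Readers accept PDB structures and
DCD/XTC trajectories (via MDAnalysis) plus a documented plain-text columnar
trajectory format so that test fixtures stay human-readable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DomainLabel",
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "Ensemble",
    "SelectionExpr",
    "select",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_columnar_trajectory",
    "read_parameter_table",
    "apply_parameters",
    "assign_domains",
]


class DomainLabel(str, Enum):
    """Coarse structural partition of the system.

    ``TM``/``PP`` are the transmembrane and periplasmic domains, ``EL1``/``EL5``
    the long external loops, ``PEPTIDE`` the acceptor substrate, ``ION`` any
    ion, and ``OTHER`` everything else.
    """

    TM = "TM"
    PP = "PP"
    EL1 = "EL1"
    EL5 = "EL5"
    PEPTIDE = "PEPTIDE"
    ION = "ION"
    OTHER = "OTHER"


# minimal element masses (amu); enough for protein/ion systems handled here
_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "MG": 24.305, "NA": 22.990, "CL": 35.45, "K": 39.098,
    "CA": 40.078, "ZN": 65.38, "FE": 55.845,
}


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "C"
    if name[:2].upper() in ("MG", "NA", "CL", "ZN", "FE") and len(name) <= 2:
        return name[:2].upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


@dataclass(frozen=True)
class AtomRecord:
    atom_id: int            # 1-based, unique within a Topology
    name: str
    element: str
    residue_id: int         # 1-based, preserved from the source file
    residue_name: str
    segment: str = ""
    domain_label: DomainLabel = DomainLabel.OTHER
    mass: float = 12.011    # amu
    charge: float | None = None        # e
    lj_epsilon: float | None = None    # kcal/mol
    lj_rmin_half: float | None = None  # Å

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"atom {self.atom_id}: mass must be > 0")

    @property
    def parameterized(self) -> bool:
        return (
            self.charge is not None
            and self.lj_epsilon is not None
            and self.lj_rmin_half is not None
        )


class Topology:
    """Ordered atom list with residue and name indices.

    Atom order is the canonical coordinate order for every frame that
    references this topology.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("atom_id values must be unique within a Topology")
        self._index_of = {a.atom_id: i for i, a in enumerate(self.atoms)}
        self.residues: dict[int, list[int]] = {}
        for a in self.atoms:
            self.residues.setdefault(a.residue_id, []).append(a.atom_id)
        self._by_res_name = {
            (a.residue_id, a.name): a.atom_id for a in self.atoms
        }

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index_of(self, atom_id: int) -> int:
        """0-based coordinate-array index of a 1-based atom id."""
        return self._index_of[atom_id]

    def indices_of(self, atom_ids: Iterable[int]) -> np.ndarray:
        return np.array([self._index_of[i] for i in atom_ids], dtype=int)

    def atom(self, atom_id: int) -> AtomRecord:
        return self.atoms[self._index_of[atom_id]]

    def atom_id(self, residue_id: int, name: str) -> int:
        try:
            return self._by_res_name[(residue_id, name)]
        except KeyError:
            raise KeyError(
                f"no atom named {name!r} in residue {residue_id}"
            ) from None

    def has_atom(self, residue_id: int, name: str) -> bool:
        return (residue_id, name) in self._by_res_name

    def residue_ids(self) -> list[int]:
        return sorted(self.residues)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def with_atoms(self, atoms: Sequence[AtomRecord]) -> "Topology":
        return Topology(atoms)


@dataclass
class Frame:
    coords: np.ndarray  # (n_atoms, 3) Å
    time: float = 0.0   # ns

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")


class Trajectory:
    """A coordinate time series on one topology, with constant spacing dt."""

    def __init__(
        self,
        topology: Topology,
        coords: np.ndarray,
        dt: float,
        replica_id: str = "0",
        condition: str = "",
        t0: float = 0.0,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if coords.shape[1] != topology.n_atoms:
            raise ValueError(
                f"frame atom count {coords.shape[1]} does not match "
                f"topology atom count {topology.n_atoms}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.topology = topology
        self.coords = coords
        self.dt = float(dt)
        self.replica_id = str(replica_id)
        self.condition = condition
        self.t0 = float(t0)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_frames)

    def frame(self, i: int) -> Frame:
        return Frame(self.coords[i], time=self.times[i])

    def __len__(self) -> int:
        return self.n_frames

    def sliced(self, start: int, stop: int) -> "Trajectory":
        """Half-open frame interval [start, stop)."""
        return Trajectory(
            self.topology, self.coords[start:stop], self.dt,
            replica_id=self.replica_id, condition=self.condition,
            t0=self.t0 + start * self.dt,
        )


class Ensemble:
    """Trajectories sharing one topology (multiple replicas, one condition
    or several)."""

    def __init__(self, trajectories: Sequence[Trajectory],
                 metadata: Mapping[str, Mapping] | None = None):
        if not trajectories:
            raise ValueError("an Ensemble needs at least one trajectory")
        n = trajectories[0].topology.n_atoms
        for t in trajectories:
            if t.topology.n_atoms != n:
                raise ValueError("all ensemble members must share atom count")
        self.trajectories = list(trajectories)
        self.metadata = dict(metadata or {})

    @property
    def topology(self) -> Topology:
        return self.trajectories[0].topology

    def __iter__(self):
        return iter(self.trajectories)

    def __len__(self):
        return len(self.trajectories)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionExpr:
    """Composable atom selection.

    A primitive expression intersects its own criteria (residue ranges,
    atom names, domain labels, explicit atom ids); ``|`` and ``&`` compose
    expressions by union and intersection.  Resolution is deterministic and
    returns a sorted atom-id list.
    """

    residue_ranges: tuple[tuple[int, int], ...] = ()   # inclusive ranges
    atom_names: tuple[str, ...] = ()
    domain_labels: tuple[DomainLabel, ...] = ()
    atom_ids: tuple[int, ...] = ()
    _op: str = "primitive"          # "primitive" | "union" | "intersection"
    _parts: tuple = ()

    def __or__(self, other: "SelectionExpr") -> "SelectionExpr":
        return SelectionExpr(_op="union", _parts=(self, other))

    def __and__(self, other: "SelectionExpr") -> "SelectionExpr":
        return SelectionExpr(_op="intersection", _parts=(self, other))

    def resolve(self, topology: Topology) -> list[int]:
        if self._op == "union":
            out: set[int] = set()
            for p in self._parts:
                out |= set(p.resolve_quiet(topology))
            return sorted(out)
        if self._op == "intersection":
            sets = [set(p.resolve_quiet(topology)) for p in self._parts]
            return sorted(set.intersection(*sets))
        # primitive
        existing = set(topology.residues)
        for lo, hi in self.residue_ranges:
            for rid in (lo, hi):
                if rid not in existing:
                    raise KeyError(f"residue {rid} does not exist in topology")
        names = set(self.atom_names)
        labels = set(self.domain_labels)
        ids = set(self.atom_ids)
        out = []
        for a in topology.atoms:
            if self.residue_ranges and not any(
                lo <= a.residue_id <= hi for lo, hi in self.residue_ranges
            ):
                continue
            if names and a.name not in names:
                continue
            if labels and a.domain_label not in labels:
                continue
            if ids and a.atom_id not in ids:
                continue
            out.append(a.atom_id)
        return sorted(out)

    def resolve_quiet(self, topology: Topology) -> list[int]:
        return self.resolve(topology)


def select(topology: Topology, expr: SelectionExpr) -> list[int]:
    """Resolve a selection to a sorted atom-id list; warns if empty."""
    result = expr.resolve(topology)
    if not result:
        warnings.warn("selection resolved to an empty atom set", stacklevel=2)
    return result


def assign_domains(
    topology: Topology,
    domains: Mapping[DomainLabel | str, Sequence[tuple[int, int]]],
) -> Topology:
    """Return a topology with domain labels set from residue-range maps."""
    lookup: dict[int, DomainLabel] = {}
    for label, ranges in domains.items():
        label = DomainLabel(label)
        for lo, hi in ranges:
            for rid in range(lo, hi + 1):
                lookup[rid] = label
    atoms = [
        replace(a, domain_label=lookup.get(a.residue_id, a.domain_label))
        for a in topology.atoms
    ]
    return Topology(atoms)


# ---------------------------------------------------------------------------
# PDB structures (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> tuple[Topology, Frame]:
    """Read a PDB file into (Topology, Frame).

    Residue ids are preserved verbatim; coordinates are in Å.  Multi-model
    files yield the first model with a warning.
    """
    import MDAnalysis as mda

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass/element guessing chatter
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # noqa: BLE001 - normalize the parse error
            raise ValueError(f"could not parse PDB file {path}: {exc}") from exc
        if len(u.trajectory) > 1:
            warnings.simplefilter("default")
            warnings.warn(
                f"{path.name}: {len(u.trajectory)} models present; "
                "using the first model",
                stacklevel=2,
            )
    atoms = []
    for i, a in enumerate(u.atoms):
        element = getattr(a, "element", "") or _guess_element(a.name)
        element = element.upper()
        mass = float(a.mass) if a.mass > 0 else _ELEMENT_MASS.get(element, 12.011)
        try:
            segment = str(a.segid) or str(a.chainID)
        except Exception:  # noqa: BLE001 - chainID absent in some files
            segment = str(a.segid)
        atoms.append(
            AtomRecord(
                atom_id=i + 1,
                name=str(a.name),
                element=element,
                residue_id=int(a.resid),
                residue_name=str(a.resname),
                segment=segment,
                mass=mass,
            )
        )
    top = Topology(atoms)
    u.trajectory[0]
    frame = Frame(u.atoms.positions.astype(float).copy(), time=0.0)
    return top, frame


def write_structure(
    topology: Topology,
    frame: Frame,
    path: str | Path,
    bfactors: np.ndarray | None = None,
) -> None:
    """Write a PDB file; ``bfactors`` (e.g. per-atom RMSF) fill the B column."""
    coords = np.asarray(frame.coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(coords) > 9999.0):
        raise ValueError("coordinate exceeds the PDB fixed-width field (9999 Å)")
    if coords.shape[0] != topology.n_atoms:
        raise ValueError("frame does not match topology atom count")
    if bfactors is None:
        bfactors = np.zeros(topology.n_atoms)
    bfactors = np.asarray(bfactors, dtype=float)

    lines = []
    for i, a in enumerate(topology.atoms):
        x, y, z = coords[i]
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        chain = (a.segment[:1] or "A") if a.segment else "A"
        lines.append(
            f"ATOM  {a.atom_id % 100000:5d} {name:<4.4s} "
            f"{a.residue_name:<4.4s}{chain}{a.residue_id % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{bfactors[i]:6.2f}"
            f"          {a.element:>2.2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Trajectories: DCD / XTC / columnar text
# ---------------------------------------------------------------------------

def read_trajectory(
    path: str | Path,
    topology: Topology,
    dt: float,
    replica_id: str = "0",
    condition: str = "",
) -> Trajectory:
    """Read a DCD, XTC, or columnar-text trajectory onto a topology.

    ``dt`` (ns/frame) is always supplied by the caller — frame times become
    ``i * dt``; the saving stride cannot be inferred from the files.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".txt", ".crd", ".coltraj"):
        coords = _read_columnar(path)
    elif suffix == ".dcd":
        from MDAnalysis.coordinates.DCD import DCDReader

        coords = _read_with(DCDReader, path)
    elif suffix == ".xtc":
        from MDAnalysis.coordinates.XTC import XTCReader

        coords = _read_with(XTCReader, path)
    else:
        raise ValueError(f"unsupported trajectory format: {path.suffix}")
    if coords.shape[0] == 0:
        raise ValueError(f"{path}: trajectory contains no frames")
    if coords.shape[1] != topology.n_atoms:
        raise ValueError(
            f"{path}: trajectory has {coords.shape[1]} atoms but topology "
            f"has {topology.n_atoms}"
        )
    return Trajectory(topology, coords, dt, replica_id=replica_id,
                      condition=condition)


def _read_with(reader_cls, path: Path) -> np.ndarray:
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = reader_cls(str(path))
        for ts in reader:
            frames.append(ts.positions.astype(float).copy())
        reader.close()
    if not frames:
        return np.zeros((0, 0, 3))
    return np.stack(frames)


_COLUMNAR_MAGIC = "# hingelatch columnar trajectory v1"


def write_columnar_trajectory(traj: Trajectory, path: str | Path) -> None:
    """One frame per ``FRAME i time`` block; three columns x y z in Å."""
    out = [_COLUMNAR_MAGIC, f"# natoms {traj.topology.n_atoms} dt {traj.dt}"]
    for i in range(traj.n_frames):
        out.append(f"FRAME {i} {traj.times[i]:.6f}")
        for x, y, z in traj.coords[i]:
            out.append(f"{x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def _read_columnar(path: Path) -> np.ndarray:
    lines = path.read_text().splitlines()
    frames: list[list[list[float]]] = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("FRAME"):
            frames.append([])
            continue
        if not frames:
            raise ValueError(f"{path}: coordinates before first FRAME header")
        frames.append(frames.pop() + [[float(v) for v in line.split()]])
    if not frames:
        return np.zeros((0, 0, 3))
    return np.array(frames, dtype=float)


# ---------------------------------------------------------------------------
# Sidecar nonbonded-parameter table
# ---------------------------------------------------------------------------

def read_parameter_table(path: str | Path) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Read a TSV with header ``residue_name atom_name charge epsilon rmin_half``.

    Charges in e, epsilon in kcal/mol, r_min/2 in Å (CHARMM convention).
    """
    table: dict[tuple[str, str], tuple[float, float, float]] = {}
    lines = Path(path).read_text().splitlines()
    header = lines[0].split()
    expected = ["residue_name", "atom_name", "charge", "epsilon", "rmin_half"]
    if header != expected:
        raise ValueError(f"parameter table header must be {' '.join(expected)}")
    for line in lines[1:]:
        if not line.strip():
            continue
        resname, atomname, q, eps, rmh = line.split()
        table[(resname, atomname)] = (float(q), float(eps), float(rmh))
    return table


def apply_parameters(
    topology: Topology,
    table: Mapping[tuple[str, str], tuple[float, float, float]],
) -> Topology:
    """Attach charge/LJ parameters from a (residue_name, atom_name) table."""
    atoms = []
    for a in topology.atoms:
        key = (a.residue_name, a.name)
        if key in table:
            q, eps, rmh = table[key]
            a = replace(a, charge=q, lj_epsilon=eps, lj_rmin_half=rmh)
        atoms.append(a)
    return Topology(atoms)
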