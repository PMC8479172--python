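"""Shared fixtures: tiny hand-built topologies and trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from hingelatch.trajectory_io import (
    AtomRecord,
    DomainLabel,
    Topology,
    Trajectory,
)


def make_atom(atom_id, name, residue_id, *, element=None, charge=0.0,
              eps=0.1, rmh=1.9, label=DomainLabel.OTHER, resname="RES",
              segment="SEG", mass=12.011):
    if element is None:
        element = name[0]
    return AtomRecord(
        atom_id=atom_id, name=name, element=element, residue_id=residue_id,
        residue_name=resname, segment=segment, domain_label=label,
        mass=mass, charge=charge, lj_epsilon=eps, lj_rmin_half=rmh,
    )


def line_topology(n_atoms, atoms_per_residue=1, **kw):
    """n_atoms single-atom (or grouped) residues named A1, A2, ..."""
    atoms = []
    for i in range(n_atoms):
        rid = i // atoms_per_residue + 1
        atoms.append(make_atom(i + 1, f"A{i % atoms_per_residue + 1}",
                               rid, element="C", **kw))
    return Topology(atoms)


def static_trajectory(top, coords_one_frame, n_frames=4, dt=0.1):
    coords = np.repeat(np.asarray(coords_one_frame, float)[None], n_frames,
                       axis=0)
    return Trajectory(top, coords, dt)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def hbond_top():
    """Donor(D) + hydrogen(H) + two acceptors (A1, A2), one residue each."""
    atoms = [
        make_atom(1, "N", 1, element="N"),
        make_atom(2, "H", 1, element="H"),
        make_atom(3, "O1", 2, element="O"),
        make_atom(4, "O2", 2, element="O"),
    ]
    return Topology(atoms)


def hbond_coords(d=2.8, theta_deg=170.0, second_acceptor=(30.0, 0.0, 0.0)):
    """Place D at origin, H at (1,0,0), acceptor at distance d from D with
    D-H-A angle theta (law of cosines); second acceptor far away."""
    theta = np.radians(theta_deg)
    # |HA| from the triangle D-H-A with |DH| = 1
    l = np.cos(theta) + np.sqrt(np.cos(theta) ** 2 - 1.0 + d * d)
    h = np.array([1.0, 0.0, 0.0])
    # direction from H making angle theta with H->D = (-1, 0, 0)
    a = h + l * np.array([-np.cos(theta), np.sin(theta), 0.0])
    return np.array([[0.0, 0.0, 0.0], h, a, list(second_acceptor)])
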