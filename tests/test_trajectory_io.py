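import numpy as np
import pytest

from hingelatch.trajectory_io import (
    AtomRecord,
    DomainLabel,
    Ensemble,
    Frame,
    SelectionExpr,
    Topology,
    Trajectory,
    apply_parameters,
    assign_domains,
    read_parameter_table,
    read_structure,
    read_trajectory,
    select,
    write_columnar_trajectory,
    write_structure,
)

from conftest import line_topology, make_atom


def test_atom_mass_must_be_positive():
    with pytest.raises(ValueError, match="mass"):
        make_atom(1, "C", 1, mass=0.0)


def test_topology_duplicate_atom_ids_rejected():
    atoms = [make_atom(1, "C", 1), make_atom(1, "N", 1)]
    with pytest.raises(ValueError, match="unique"):
        Topology(atoms)


def test_topology_lookups():
    top = line_topology(6, atoms_per_residue=2)
    assert top.n_atoms == 6
    assert top.index_of(4) == 3
    assert top.atom_id(2, "A1") == 3
    assert top.has_atom(3, "A2")
    assert not top.has_atom(3, "ZZ")
    assert top.residue_ids() == [1, 2, 3]
    with pytest.raises(KeyError, match="no atom named"):
        top.atom_id(1, "XY")


def test_trajectory_validation():
    top = line_topology(3)
    with pytest.raises(ValueError, match="atom count"):
        Trajectory(top, np.zeros((2, 4, 3)), dt=0.1)
    with pytest.raises(ValueError, match="dt"):
        Trajectory(top, np.zeros((2, 3, 3)), dt=0.0)
    with pytest.raises(ValueError, match="finite"):
        Trajectory(top, np.full((1, 3, 3), np.nan), dt=0.1)
    with pytest.raises(ValueError, match="at least one frame"):
        Trajectory(top, np.zeros((0, 3, 3)), dt=0.1)


def test_trajectory_slicing_and_times():
    top = line_topology(2)
    coords = np.arange(5 * 2 * 3, dtype=float).reshape(5, 2, 3)
    traj = Trajectory(top, coords, dt=0.5, t0=1.0)
    assert np.allclose(traj.times, [1.0, 1.5, 2.0, 2.5, 3.0])
    sub = traj.sliced(1, 3)
    assert sub.n_frames == 2
    assert sub.t0 == 1.5
    assert np.array_equal(sub.coords, coords[1:3])


def test_ensemble_requires_matching_atom_counts():
    t1 = Trajectory(line_topology(2), np.zeros((1, 2, 3)), 0.1)
    t2 = Trajectory(line_topology(3), np.zeros((1, 3, 3)), 0.1)
    with pytest.raises(ValueError, match="share atom count"):
        Ensemble([t1, t2])
    with pytest.raises(ValueError, match="at least one"):
        Ensemble([])


def test_selection_primitive_and_composition():
    atoms = [
        make_atom(1, "CA", 1, label=DomainLabel.TM),
        make_atom(2, "CB", 1, label=DomainLabel.TM),
        make_atom(3, "CA", 2, label=DomainLabel.PP),
        make_atom(4, "CA", 3, label=DomainLabel.PEPTIDE),
    ]
    top = Topology(atoms)
    assert SelectionExpr(atom_names=("CA",)).resolve(top) == [1, 3, 4]
    assert SelectionExpr(residue_ranges=((1, 2),)).resolve(top) == [1, 2, 3]
    assert SelectionExpr(domain_labels=(DomainLabel.PP,)).resolve(top) == [3]
    assert SelectionExpr(atom_ids=(4, 2)).resolve(top) == [2, 4]
    both = SelectionExpr(atom_names=("CA",)) & SelectionExpr(
        residue_ranges=((1, 2),))
    assert both.resolve(top) == [1, 3]
    either = SelectionExpr(atom_names=("CB",)) | SelectionExpr(
        domain_labels=(DomainLabel.PEPTIDE,))
    assert either.resolve(top) == [2, 4]


def test_selection_missing_residue_raises():
    top = line_topology(3)
    with pytest.raises(KeyError, match="does not exist"):
        SelectionExpr(residue_ranges=((1, 99),)).resolve(top)


def test_select_warns_on_empty():
    top = line_topology(3)
    with pytest.warns(UserWarning, match="empty"):
        out = select(top, SelectionExpr(atom_names=("ZZ",)))
    assert out == []


def test_assign_domains():
    top = line_topology(4)
    new = assign_domains(top, {"TM": [(1, 2)], DomainLabel.PP: [(3, 3)]})
    labels = [a.domain_label for a in new.atoms]
    assert labels == [DomainLabel.TM, DomainLabel.TM, DomainLabel.PP,
                      DomainLabel.OTHER]


def test_pdb_round_trip(tmp_path):
    top = line_topology(4, atoms_per_residue=2)
    coords = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0],
                       [-7.125, 8.25, 9.5], [0.0, 0.0, 0.001]])
    path = tmp_path / "x.pdb"
    write_structure(top, Frame(coords), path, bfactors=np.arange(4.0))
    top2, frame2 = read_structure(path)
    assert top2.n_atoms == 4
    assert [a.residue_id for a in top2.atoms] == [1, 1, 2, 2]
    assert [a.name for a in top2.atoms] == ["A1", "A2", "A1", "A2"]
    assert np.allclose(frame2.coords, coords, atol=1.5e-3)
    # B-factor column written
    text = path.read_text()
    assert "  3.00" in text


def _raw_frame(coords):
    # bypass Frame's own validation so write_structure's checks are exercised
    f = Frame.__new__(Frame)
    f.coords = np.asarray(coords, dtype=float)
    f.time = 0.0
    return f


def test_write_structure_rejects_bad_coords(tmp_path):
    top = line_topology(1)
    with pytest.raises(ValueError, match="finite"):
        write_structure(top, _raw_frame([[np.inf, 0, 0]]), tmp_path / "x.pdb")
    with pytest.raises(ValueError, match="9999"):
        write_structure(top, _raw_frame([[10000.0, 0, 0]]), tmp_path / "y.pdb")


def test_read_structure_error_names_file(tmp_path):
    bad = tmp_path / "broken.pdb"
    bad.write_text("not a pdb at all\x00\x01")
    with pytest.raises(ValueError, match="broken.pdb"):
        read_structure(bad)


def test_columnar_round_trip(tmp_path):
    top = line_topology(3)
    coords = np.random.default_rng(1).normal(size=(5, 3, 3)) * 10
    traj = Trajectory(top, coords, dt=0.2)
    path = tmp_path / "t.coltraj"
    write_columnar_trajectory(traj, path)
    back = read_trajectory(path, top, dt=0.2)
    assert back.n_frames == 5
    assert np.allclose(back.coords, coords, atol=1e-6)


def test_read_trajectory_atom_mismatch_names_counts(tmp_path):
    top = line_topology(3)
    traj = Trajectory(top, np.zeros((2, 3, 3)), dt=0.1)
    path = tmp_path / "t.coltraj"
    write_columnar_trajectory(traj, path)
    with pytest.raises(ValueError) as err:
        read_trajectory(path, line_topology(5), dt=0.1)
    assert "3" in str(err.value) and "5" in str(err.value)


def test_read_trajectory_empty_and_unknown_format(tmp_path):
    empty = tmp_path / "e.coltraj"
    empty.write_text("# hingelatch columnar trajectory v1\n")
    with pytest.raises(ValueError, match="no frames"):
        read_trajectory(empty, line_topology(1), dt=0.1)
    with pytest.raises(ValueError, match="unsupported"):
        read_trajectory(tmp_path / "x.zzz", line_topology(1), dt=0.1)


def test_dcd_round_trip(tmp_path):
    mda = pytest.importorskip("MDAnalysis")
    top = line_topology(4)
    coords = np.random.default_rng(3).normal(size=(3, 4, 3)).astype(
        np.float32) * 5
    u = mda.Universe.empty(4, trajectory=True)
    path = tmp_path / "t.dcd"
    with mda.Writer(str(path), 4) as w:
        for f in coords:
            u.atoms.positions = f
            w.write(u.atoms)
    back = read_trajectory(path, top, dt=0.1)
    assert back.n_frames == 3
    assert np.allclose(back.coords, coords, atol=1e-3)


def test_parameter_table_round_trip(tmp_path):
    path = tmp_path / "params.tsv"
    path.write_text(
        "residue_name atom_name charge epsilon rmin_half\n"
        "RES A1 0.25 0.1 1.8\n"
        "RES A2 -0.25 0.2 1.7\n".replace(" ", "\t")
    )
    table = read_parameter_table(path)
    assert table[("RES", "A1")] == (0.25, 0.1, 1.8)
    top = line_topology(2, atoms_per_residue=2)
    top = Topology([
        AtomRecord(**{**a.__dict__, "charge": None, "lj_epsilon": None,
                      "lj_rmin_half": None}) for a in top.atoms
    ])
    assert not top.atoms[0].parameterized
    newtop = apply_parameters(top, table)
    assert newtop.atoms[0].parameterized
    assert newtop.atoms[0].charge == 0.25
    assert newtop.atoms[1].lj_epsilon == 0.2


def test_parameter_table_bad_header(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("res atom q e r\n")
    with pytest.raises(ValueError, match="header"):
        read_parameter_table(path)
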