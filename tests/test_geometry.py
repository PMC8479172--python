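import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hingelatch import geometry
from hingelatch.geometry import (
    align_trajectory,
    apply_superposition,
    average_structure,
    distance_difference_map,
    distance_fluctuation_matrix,
    find_stable_core,
    hinge_scan,
    kabsch_superpose,
    latch_distance_histograms,
    low_rmsd_candidates,
    most_populated_structure,
    per_residue_backbone_rmsd,
    rmsd_between_structures,
)
from hingelatch.trajectory_io import Ensemble, Topology, Trajectory

from conftest import line_topology, make_atom


def _random_points(rng, n=20):
    return rng.normal(size=(n, 3)) * 5.0


def test_kabsch_identity(rng):
    x = _random_points(rng)
    sup = kabsch_superpose(x, x, range(len(x)))
    assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(sup.rotation, np.eye(3), atol=1e-10)


def test_kabsch_recovers_random_rigid_transforms(rng):
    x = _random_points(rng)
    for _ in range(20):
        rot = Rotation.random(random_state=rng).as_matrix()
        t = rng.normal(size=3) * 10
        y = x @ rot.T + t
        sup = kabsch_superpose(x, y, range(len(x)))
        fitted = apply_superposition(x, sup)
        assert np.sqrt(np.mean(np.sum((fitted - y) ** 2, -1))) < 1e-8
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_rejects_degenerate_input(rng):
    x = _random_points(rng)
    with pytest.raises(ValueError, match="at least 3"):
        kabsch_superpose(x, x, [0, 1])
    line = np.outer(np.arange(5.0), [1.0, 2.0, 0.5])
    with pytest.raises(ValueError, match="collinear"):
        kabsch_superpose(line, line, range(5))


def test_align_trajectory_removes_rigid_motion(rng):
    top = line_topology(6)
    base = _random_points(rng, 6)
    frames = [base]
    for _ in range(4):
        rot = Rotation.random(random_state=rng).as_matrix()
        frames.append(base @ rot.T + rng.normal(size=3))
    traj = Trajectory(top, np.stack(frames), dt=0.1)
    aligned = align_trajectory(traj, range(6))
    for t in range(5):
        assert np.allclose(aligned.coords[t], base, atol=1e-8)


def test_distance_fluctuations_zero_for_rigid_body(rng):
    top = line_topology(5)
    base = _random_points(rng, 5)
    rot = Rotation.random(random_state=rng).as_matrix()
    coords = np.stack([base, base @ rot.T + 3.0])
    ens = Ensemble([Trajectory(top, coords, 0.1)])
    rids, fluct = distance_fluctuation_matrix(ens, atom_name="A1")
    assert rids == [1, 2, 3, 4, 5]
    assert np.allclose(fluct, 0.0, atol=1e-5)


def test_distance_fluctuations_need_two_frames(rng):
    top = line_topology(5)
    ens = Ensemble([Trajectory(top, _random_points(rng, 5)[None], 0.1)])
    with pytest.raises(ValueError, match="2 frames"):
        distance_fluctuation_matrix(ens, atom_name="A1")


def test_stable_core_finds_rigid_cluster(rng):
    # two rigid bodies moving relative to one another; the second body also
    # breathes internally, so the first is the (unique) stable core
    top = line_topology(12)
    base = np.concatenate([
        _random_points(rng, 6), _random_points(rng, 6) + [20, 0, 0]
    ])
    frames = []
    for _ in range(30):
        f = base.copy()
        f[6:] += rng.normal(size=3) * 5.0          # rigid-body drift
        f[6:] += rng.normal(size=(6, 3)) * 0.3     # internal breathing
        frames.append(f)
    ens = Ensemble([Trajectory(top, np.stack(frames), 0.1)])
    core = find_stable_core(ens, atom_name="A1", n_clusters=2)
    assert set(core.residue_ids) == {1, 2, 3, 4, 5, 6}
    # the rigid body is, on average, less mobile than the drifting one
    rigid = np.mean([core.rigidity[r] for r in range(1, 7)])
    drifting = np.mean([core.rigidity[r] for r in range(7, 13)])
    assert rigid < drifting


def test_stable_core_tie_warns(rng):
    # two internally rigid bodies in relative motion: both clusters have
    # exactly zero internal fluctuation
    top = line_topology(4)
    coords = np.zeros((4, 4, 3))
    coords[:, 1, 0] = 1.0
    coords[:, 2:, 0] += 100.0
    coords[:, 3, 0] += 1.0
    coords[:, 2:, 1] += np.array([[-2.0], [0.0], [2.0], [4.0]])  # drift
    ens = Ensemble([Trajectory(top, coords, 0.1)])
    with pytest.warns(UserWarning, match="tie"):
        core = find_stable_core(ens, atom_name="A1", n_clusters=2)
    assert set(core.residue_ids) == {1, 2}  # ties go to the lowest residue


def test_stable_core_too_few_residues(rng):
    top = line_topology(3)
    coords = np.stack([_random_points(rng, 3)] * 3)
    ens = Ensemble([Trajectory(top, coords, 0.1)])
    with pytest.raises(ValueError, match="clusters"):
        find_stable_core(ens, atom_name="A1", n_clusters=5)


def test_average_structure_mean_and_rmsf():
    top = line_topology(1)
    coords = np.zeros((4, 1, 3))
    coords[:, 0, 0] = [0.0, 2.0, 0.0, 2.0]
    avg = average_structure(Trajectory(top, coords, 0.1))
    assert avg.coords[0, 0] == pytest.approx(1.0)
    assert avg.rmsf[0] == pytest.approx(1.0)   # sd around the mean
    assert avg.n_frames == 4
    with pytest.raises(ValueError, match="no frames"):
        average_structure(Trajectory(top, coords, 0.1),
                          np.zeros(4, dtype=bool))


def test_rmsd_between_structures_hand_value():
    top = line_topology(2)
    a = average_structure(Trajectory(top, np.zeros((1, 2, 3)), 0.1))
    shifted = np.zeros((1, 2, 3))
    shifted[0, :, 0] = 3.0
    b = average_structure(Trajectory(top, shifted, 0.1))
    assert rmsd_between_structures(a, b, [0, 1]) == pytest.approx(3.0)
    with pytest.raises(ValueError, match="empty"):
        rmsd_between_structures(a, b, [])


def _backbone_topology(n_res):
    atoms = []
    aid = 0
    for rid in range(1, n_res + 1):
        for name in ("N", "CA", "C", "O"):
            aid += 1
            atoms.append(make_atom(aid, name, rid))
    return Topology(atoms)


def test_per_residue_backbone_rmsd():
    top = _backbone_topology(2)
    x = np.zeros((1, 8, 3))
    y = x.copy()
    y[0, 4:, 2] = 2.0  # displace residue 2 backbone by 2 Å
    a = average_structure(Trajectory(top, x, 0.1))
    b = average_structure(Trajectory(top, y, 0.1))
    out = per_residue_backbone_rmsd(a, b, [1, 2])
    assert out[0] == pytest.approx(0.0)
    assert out[1] == pytest.approx(2.0)


def test_most_populated_structure_picks_dense_bin():
    top = line_topology(4)
    n = 50
    coords = np.zeros((n, 4, 3))
    # 40 frames near distance 10, 10 outlier frames near 30
    coords[:, 1, 0] = 10.0
    coords[40:, 1, 0] = 30.0
    ref = average_structure(Trajectory(top, coords[:40], 0.1))
    frame, dist, rmsd = most_populated_structure(
        coords, (np.array([0]), np.array([1])), ref, np.arange(4))
    assert frame < 40
    assert dist == pytest.approx(10.0)


def test_distance_difference_map_exact():
    top = line_topology(3)
    xa = np.array([[[0, 0, 0], [3, 0, 0], [6, 0, 0]]], dtype=float)
    xb = np.array([[[0, 0, 0], [4, 0, 0], [9, 0, 0]]], dtype=float)
    ens_a = Ensemble([Trajectory(top, xa, 0.1)])
    ens_b = Ensemble([Trajectory(top, xb, 0.1)])
    dd = distance_difference_map(ens_a, ens_b, atom_name="A1",
                                 blocks={"L": [1], "R": [2, 3]})
    assert dd.delta[0, 1] == pytest.approx(3 - 4)
    assert dd.delta[0, 2] == pytest.approx(6 - 9)
    assert dd.delta[1, 2] == pytest.approx(3 - 5)
    assert dd.block_means[("L", "R")] == pytest.approx((-1 - 3) / 2)
    assert dd.block_means[("R", "R")] == pytest.approx(-2.0)


def test_distance_difference_map_residue_mismatch():
    ens_a = Ensemble([Trajectory(line_topology(3), np.zeros((1, 3, 3)), 0.1)])
    ens_b = Ensemble([Trajectory(line_topology(4), np.zeros((1, 4, 3)), 0.1)])
    with pytest.raises(ValueError, match="different residue"):
        distance_difference_map(ens_a, ens_b, atom_name="A1")


def _hinge_pair(rng, n_res=20, angle_deg=12.0):
    """Planar fan of residues around residue 1; the rotated copy displaces
    each residue in exact proportion to its distance from residue 1."""
    top = _backbone_topology(n_res)
    base = np.zeros((n_res * 4, 3))
    for i in range(n_res):
        rho = 2.0 * i
        phi = 0.9 * i
        ca = np.array([rho * np.cos(phi), rho * np.sin(phi), 0.0])
        for k, off in enumerate(([0.3, 0, 0], [0, 0, 0], [0, 0.3, 0],
                                 [0, 0, 0.3])):
            base[4 * i + k] = ca + off
    rot = Rotation.from_euler("z", angle_deg, degrees=True).as_matrix()
    moved = base @ rot.T
    a = average_structure(Trajectory(top, base[None], 0.1))
    b = average_structure(Trajectory(top, moved[None], 0.1))
    return top, a, b


def test_hinge_scan_identifies_pivot(rng):
    top, a, b = _hinge_pair(rng)
    rep = hinge_scan(a, b, candidates=[1, 5, 10, 15], mobile=list(range(5, 20)))
    assert rep.best == 1
    assert rep.ranked[0][1] > 0.99
    assert all(r < rep.ranked[0][1] for _, r in rep.ranked[1:])


def test_hinge_scan_requires_mobile_set(rng):
    top, a, b = _hinge_pair(rng)
    with pytest.raises(ValueError, match="at least 10"):
        hinge_scan(a, b, [1], mobile=[2, 3, 4])


def test_hinge_scan_degenerate_warns(rng):
    top, a, _ = _hinge_pair(rng)
    with pytest.warns(UserWarning, match="identical"):
        rep = hinge_scan(a, a, [1, 2], mobile=list(range(5, 20)))
    assert rep.degenerate
    assert np.isnan(rep.ranked[0][1])


def test_low_rmsd_candidates_keeps_noise_floor_ties(rng):
    # residues 1-12 static (noise-level RMSD), 13-20 clearly displaced;
    # the whole static tie group must survive the quantile cut
    top = _backbone_topology(20)
    x = rng.normal(size=(40, 80, 3)) * 0.02
    y = rng.normal(size=(40, 80, 3)) * 0.02
    y[:, 48:, 0] += 5.0  # residues 13-20
    a = average_structure(Trajectory(top, x, 0.1))
    b = average_structure(Trajectory(top, y, 0.1))
    cands = low_rmsd_candidates(a, b, pool=list(range(1, 21)))
    assert cands == list(range(1, 13))


def test_latch_histograms_normalized_and_summarized(rng):
    top = line_topology(2, atoms_per_residue=1)
    n = 400
    coords = np.zeros((n, 2, 3))
    coords[:, 1, 0] = rng.normal(10.0, 1.5, size=n)
    ens = {"X": Ensemble([Trajectory(top, coords, 0.1)])}
    bins = np.arange(0, 30, 0.5)
    out = latch_distance_histograms(ens, ((1, "A1"), (2, "A1")), bins)
    h = out["X"]
    assert h["hist"].sum() == pytest.approx(1.0)
    assert h["mode"] == pytest.approx(10.0, abs=1.0)
    assert h["sd"] == pytest.approx(1.5, abs=0.25)
    assert 0.0 < h["tail_fraction"] < 0.25


def test_latch_histograms_empty_mask_errors(rng):
    top = line_topology(2)
    ens = {"X": Ensemble([Trajectory(top, np.zeros((4, 2, 3)), 0.1)])}
    with pytest.raises(ValueError, match="empty"):
        latch_distance_histograms(
            ens, ((1, "A1"), (2, "A1")), np.arange(0, 5, 0.5),
            masks={"X": [np.zeros(4, dtype=bool)]})
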