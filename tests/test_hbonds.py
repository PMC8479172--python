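import numpy as np
import pytest

from hingelatch import hbonds
from hingelatch.hbonds import (
    BindingState,
    HBondSpec,
    HBondTrace,
    TerminationMetricSpec,
    classify_binding,
    detect_hbonds,
    equilibration_mask,
    hbond_probability,
    joint_occupancy,
    termination_metric,
)
from hingelatch.trajectory_io import Trajectory

from conftest import hbond_coords, line_topology, static_trajectory


SPEC = HBondSpec(label="b", donor=1, hydrogen=2, acceptors=(3,))
SPEC2 = HBondSpec(label="b", donor=1, hydrogen=2, acceptors=(3, 4))


def _trace_for(coords, hbond_top, spec=SPEC):
    traj = static_trajectory(hbond_top, coords, n_frames=2)
    return detect_hbonds(traj, [spec])


@pytest.mark.parametrize("d,theta,present", [
    (2.8, 170.0, True),    # inside both cutoffs
    (3.6, 170.0, False),   # distance fails
    (2.8, 120.0, False),   # angle fails
    (3.499, 170.0, True),
    (2.8, 130.0, False),   # boundary: strict >
    (2.8, 130.5, True),
])
def test_geometric_criterion_boundaries(hbond_top, d, theta, present):
    trace = _trace_for(hbond_coords(d=d, theta_deg=theta), hbond_top)
    assert bool(trace.occupancy[0, 0]) is present


def test_distance_cutoff_is_strict(hbond_top):
    # D-A distance exactly 3.5 (binary-representable) with a valid angle
    coords = np.array([[0.0, 0.0, 0.0], [0.98, 0.17, 0.0],
                       [3.5, 0.0, 0.0], [30.0, 0.0, 0.0]])
    trace = _trace_for(coords, hbond_top)
    assert trace.distances[0, 0] == 3.5
    assert not trace.occupancy[0, 0]


def test_multi_acceptor_is_logical_or(hbond_top):
    # first acceptor fails distance, second acceptor satisfies the criterion
    coords = hbond_coords(d=3.6, theta_deg=170.0)
    good = hbond_coords(d=2.8, theta_deg=170.0)[2]
    coords[3] = good
    trace = _trace_for(coords, hbond_top, spec=SPEC2)
    assert trace.occupancy[0, 0]
    # recorded distance is the minimum over the acceptor set
    assert trace.distances[0, 0] == pytest.approx(2.8, abs=1e-9)


def test_missing_atom_raises(hbond_top):
    traj = static_trajectory(hbond_top, hbond_coords(), 2)
    bad = HBondSpec(label="x", donor=1, hydrogen=99, acceptors=(3,))
    with pytest.raises(KeyError, match="99"):
        detect_hbonds(traj, [bad])


def test_distant_hydrogen_warns(hbond_top):
    coords = hbond_coords()
    coords[1] = [4.0, 0.0, 0.0]  # hydrogen 4 Å from donor
    traj = static_trajectory(hbond_top, coords, 2)
    with pytest.warns(UserWarning, match="check atom assignment"):
        detect_hbonds(traj, [SPEC])


def _trace(occ, dt=1.0, labels=None, replica="0"):
    occ = np.asarray(occ, dtype=bool)
    labels = labels or tuple(f"b{i}" for i in range(occ.shape[0]))
    return HBondTrace(labels=tuple(labels), occupancy=occ,
                      distances=np.where(occ, 2.8, 9.0), dt=dt,
                      replica_id=replica)


def test_probability_all_on_and_alternating():
    t = _trace(np.ones((1, 10)))
    assert hbond_probability([t])["b0"] == (1.0, 0.0)
    alt = _trace([[True, False] * 5])
    assert hbond_probability([alt])["b0"][0] == pytest.approx(0.5)


def test_probability_across_replicas_hand_value():
    reps = [_trace([[True] * 2 + [False] * 8]),
            _trace([[True] * 5 + [False] * 5]),
            _trace([[True] * 8 + [False] * 2])]
    mean, sd = hbond_probability(reps)["b0"]
    assert mean == pytest.approx(0.5)
    assert sd == pytest.approx(0.3)


def test_probability_empty_mask_errors():
    t = _trace(np.ones((1, 4)))
    with pytest.raises(ValueError, match="empty"):
        hbond_probability([t], np.zeros(4, dtype=bool))


def test_probability_per_replica_masks():
    reps = [_trace(np.ones((1, 4))), _trace(np.zeros((1, 4)))]
    masks = [np.array([True, True, False, False]),
             np.array([False, False, True, True])]
    mean, sd = hbond_probability(reps, masks)["b0"]
    assert mean == pytest.approx(0.5)
    with pytest.raises(ValueError, match="per replica"):
        hbond_probability(reps, [masks[0]])


def test_joint_occupancy_modes_and_reduction():
    occ = np.array([[True, True, False, False],
                    [True, False, True, False]])
    t = _trace(occ)
    assert joint_occupancy([t], ["b0", "b1"]) == pytest.approx(0.25)
    assert joint_occupancy([t], ["b0", "b1"], "all_absent") == pytest.approx(0.25)
    # one-bond subset reduces to the marginal
    assert joint_occupancy([t], ["b0"]) == pytest.approx(0.5)
    # perfectly co-occurring bonds equal the marginal
    co = _trace(np.array([occ[0], occ[0]]))
    assert joint_occupancy([co], ["b0", "b1"]) == pytest.approx(0.5)
    with pytest.raises(ValueError, match="non-empty"):
        joint_occupancy([t], [])
    with pytest.raises(ValueError, match="mode"):
        joint_occupancy([t], ["b0"], "sometimes")


def test_joint_occupancy_independent_bonds_product_law(rng):
    occ = rng.random((2, 20000)) < 0.5
    t = _trace(occ)
    assert joint_occupancy([t], ["b0", "b1"]) == pytest.approx(0.25, abs=0.02)


def _six(a_rows, b_rows):
    return np.array(list(a_rows) + list(b_rows), dtype=bool)


GA = ["b0", "b1", "b2"]
GB = ["b3", "b4", "b5"]


def test_classifier_all_on_fully_bound():
    occ = np.ones((6, 30), dtype=bool)
    bt = classify_binding(_trace(occ), GA, GB, persistence_ns=5, dt=1.0)
    assert (bt.states == int(BindingState.FULLY_BOUND)).all()


def test_classifier_short_a_loss_is_ignored():
    occ = np.ones((6, 30), dtype=bool)
    occ[0:3, 10:15] = False  # A lost for 5 frames = window, not > window
    bt = classify_binding(_trace(occ), GA, GB, persistence_ns=5, dt=1.0)
    assert (bt.states == int(BindingState.FULLY_BOUND)).all()


def test_classifier_hand_computed_transitions():
    n = 60
    occ = np.ones((6, n), dtype=bool)
    occ[0:3, 10:] = False          # A lost from frame 10 onward
    occ[3:6, 30:] = False          # B lost from frame 30 onward
    bt = classify_binding(_trace(occ), GA, GB, persistence_ns=5, dt=1.0)
    # the A-absent run first exceeds window=5 at frame 15 (run of 6)
    assert (bt.states[:15] == int(BindingState.FULLY_BOUND)).all()
    assert (bt.states[15:35] == int(BindingState.PARTIALLY_BOUND)).all()
    # all six absent from frame 30; the run first exceeds 5 at frame 35
    assert (bt.states[35:] == int(BindingState.UNBOUND)).all()


def test_classifier_rebinding_flag():
    n = 40
    occ = np.ones((6, n), dtype=bool)
    occ[0:3, 5:20] = False  # A lost long enough to go partial, then returns
    default = classify_binding(_trace(occ), GA, GB, persistence_ns=5, dt=1.0)
    assert default.states[-1] == int(BindingState.PARTIALLY_BOUND)
    allowed = classify_binding(_trace(occ), GA, GB, persistence_ns=5, dt=1.0,
                               allow_rebinding=True)
    assert allowed.states[-1] == int(BindingState.FULLY_BOUND)


def test_classifier_unbound_is_absorbing():
    occ = np.zeros((6, 30), dtype=bool)
    occ[:, 25:] = True  # everything returns after unbinding
    bt = classify_binding(_trace(occ), GA, GB, persistence_ns=5, dt=1.0,
                          allow_rebinding=True)
    assert (bt.states[6:] == int(BindingState.UNBOUND)).all()


def test_classifier_group_overlap_rejected():
    occ = np.ones((6, 10), dtype=bool)
    with pytest.raises(ValueError, match="disjoint"):
        classify_binding(_trace(occ), GA, ["b2", "b4", "b5"], 5, 1.0)


def test_classifier_short_trace_warns():
    occ = np.ones((6, 3), dtype=bool)
    with pytest.warns(UserWarning, match="shorter"):
        classify_binding(_trace(occ), GA, GB, persistence_ns=5, dt=1.0)


def test_termination_metric_arithmetic():
    top = line_topology(8)
    coords = np.zeros((3, 8, 3))
    for k in range(4):
        coords[:, 2 * k + 1, 0] = 5.0  # each pair 5 Å apart
    traj = Trajectory(top, coords, dt=0.1)
    spec = TerminationMetricSpec(pairs=((1, 2), (3, 4), (5, 6), (7, 8)))
    total, first = termination_metric(traj, spec)
    assert np.allclose(total, 20.0)
    assert first is None
    # exactly at the threshold is not a termination (strict >)
    coords[2, 1, 0] = 65.0  # sum = 80 exactly
    total, first = termination_metric(Trajectory(top, coords, 0.1), spec)
    assert total[2] == pytest.approx(80.0)
    assert first is None
    coords[2, 1, 0] = 65.1
    _, first = termination_metric(Trajectory(top, coords, 0.1), spec)
    assert first == 2


def test_termination_spec_requires_four_pairs():
    with pytest.raises(ValueError, match="four"):
        TerminationMetricSpec(pairs=((1, 2),))


def test_equilibration_mask():
    m = equilibration_mask(10, dt=1.0, exclude_ns=3.0)
    assert m.tolist() == [False] * 3 + [True] * 7
    assert not equilibration_mask(5, dt=1.0, exclude_ns=50.0).any()
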