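"""Hydrogen-bond detection, lifetime merging, and bridge detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memdrug import (
    BindingPairSpec,
    Frame,
    HBPairSpec,
    SiteRef,
    SyntheticConfig,
    SystemMap,
    Trajectory,
    build_system,
    detect_bonds,
    detect_bridges,
    lifetimes,
    minimum_image_distance,
    pair_lifetime_table,
    select_sites,
    simulate_binding,
)
from memdrug.hbonds import BondTimeline, merged_intervals
from memdrug.synthetic import sample_two_state_chain, states_on_grid


def timeline_from_states(states, distances=None, cutoff=2.5):
    states = np.asarray(states, dtype=bool)
    if distances is None:
        distances = np.where(states, 1.7, 8.0)
    return BondTimeline(
        donor=SiteRef(0, "DBD1", "H2"),
        acceptor_label="O13 DOPC#1",
        states=states,
        distances=np.asarray(distances, float),
        cutoff=cutoff,
    )


class TestDetectBonds:
    def test_distance_below_cutoff_is_bound(self, tiny_bilayer):
        system, frame = tiny_bilayer
        pos = frame.positions.copy()
        pos[4] = pos[1] + [0.0, 0.0, 1.7]  # H2 1.7 A above a DOPC O13
        traj = Trajectory(
            system=system,
            frames=[Frame(time=0.0, positions=pos, box=frame.box)],
            dt=0.1,
        )
        tl = detect_bonds(
            traj,
            select_sites(system, "DBD1", "H2"),
            np.array([1]),
            cutoff=2.5,
        )[0]
        assert tl.states[0]
        assert tl.distances[0] == pytest.approx(1.7)

    def test_distance_exactly_at_cutoff_is_bound(self, tiny_bilayer):
        system, frame = tiny_bilayer
        pos = frame.positions.copy()
        pos[4] = pos[1] + [0.0, 0.0, 2.5]
        traj = Trajectory(
            system=system,
            frames=[Frame(time=0.0, positions=pos, box=frame.box)],
            dt=0.1,
        )
        tl = detect_bonds(traj, np.array([4]), np.array([1]), cutoff=2.5)[0]
        assert tl.states[0]

    def test_matches_brute_force_thresholding(self):
        rng = np.random.default_rng(9)
        atoms = [SiteRef(i, "GAS_A", "X") for i in range(3)]
        atoms += [SiteRef(3 + i, "GAS_B", "X") for i in range(6)]
        system = SystemMap(
            atoms=atoms, vocabulary={"GAS_A": ("X",), "GAS_B": ("X",)}
        )
        box = (8.0, 9.0, 10.0)
        frames = [
            Frame(time=0.1 * i, positions=rng.uniform(0, 8, (9, 3)), box=box)
            for i in range(7)
        ]
        traj = Trajectory(system=system, frames=frames, dt=0.1)
        donors = np.arange(3)
        acceptors = np.arange(3, 9)
        cutoff = 3.0
        tls = detect_bonds(traj, donors, acceptors, cutoff)
        k = 0
        for d in donors:
            for a in acceptors:
                for fi, f in enumerate(frames):
                    ref = (
                        minimum_image_distance(f.positions[d], f.positions[a], box)
                        <= cutoff
                    )
                    assert tls[k].states[fi] == ref
                k += 1

    def test_empty_selection_rejected(self, tiny_bilayer):
        system, frame = tiny_bilayer
        traj = Trajectory(system=system, frames=[frame], dt=0.1)
        with pytest.raises(ValueError):
            detect_bonds(traj, np.array([], dtype=int), np.array([1]))


class TestLifetimes:
    def test_fully_bound_single_interval(self):
        s = lifetimes(timeline_from_states(np.ones(1000, bool)), dt=0.01, tolerance=0.0)
        assert s.n_intervals == 1
        assert s.tau == pytest.approx(10.0)

    def test_merge_semantics_across_short_break(self):
        # 10 ns bound, 0.2 ns unbound, 9.8 ns bound at dt = 0.1 ns
        states = np.concatenate(
            [np.ones(100, bool), np.zeros(2, bool), np.ones(98, bool)]
        )
        merged = lifetimes(timeline_from_states(states), dt=0.1, tolerance=0.5)
        assert merged.n_intervals == 1
        assert merged.tau == pytest.approx(20.0)
        split = lifetimes(timeline_from_states(states), dt=0.1, tolerance=0.1)
        assert split.n_intervals == 2
        assert split.tau == pytest.approx(9.9)

    def test_never_bound_is_undefined_not_zero(self):
        s = lifetimes(timeline_from_states(np.zeros(50, bool)), dt=0.1)
        assert s.n_intervals == 0
        assert np.isnan(s.tau)

    def test_edge_interval_exclusion_flag(self):
        states = np.concatenate(
            [np.ones(10, bool), np.zeros(30, bool), np.ones(20, bool),
             np.zeros(30, bool), np.ones(10, bool)]
        )
        incl = lifetimes(timeline_from_states(states), dt=0.1, tolerance=0.0)
        excl = lifetimes(
            timeline_from_states(states), dt=0.1, tolerance=0.0, include_edges=False
        )
        assert incl.n_intervals == 3
        assert excl.n_intervals == 1
        assert excl.tau == pytest.approx(2.0)

    def test_zero_tolerance_durations_sum_to_bound_frames(self):
        rng = np.random.default_rng(4)
        states = rng.random(500) < 0.3
        dt = 0.05
        ivals = merged_intervals(states, dt, tolerance=0.0)
        total = sum((b - a + 1) * dt for a, b in ivals)
        assert total == pytest.approx(states.sum() * dt)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000), p=st.floats(0.05, 0.9))
    def test_tau_nondecreasing_in_tolerance(self, seed, p):
        rng = np.random.default_rng(seed)
        states = rng.random(300) < p
        if not states.any():
            return
        dt = 0.1
        taus = [
            lifetimes(timeline_from_states(states), dt, tol).tau
            for tol in (0.0, 0.1, 0.3, 1.0, 5.0, 30.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(taus, taus[1:]))
        # at tolerance = trajectory length everything merges into one interval
        full = lifetimes(timeline_from_states(states), dt, 300 * dt)
        assert full.n_intervals == 1

    def test_exponential_dwell_recovery_with_discretization(self):
        # k_off = 0.1/ns sampled at dt = 0.01 ns: tau within 3 SE of 10 ns
        rng = np.random.default_rng(17)
        k_on, k_off, dt = 1.0, 0.1, 0.01
        duration = 2400 * (1 / k_on + 1 / k_off)
        ivals = sample_two_state_chain(k_on, k_off, duration, rng)
        times = np.arange(0.0, duration, dt)
        states = states_on_grid(ivals, times)
        s = lifetimes(timeline_from_states(states), dt=dt, tolerance=0.0)
        assert s.n_intervals >= 2000
        sem = s.tau / np.sqrt(s.n_intervals)
        assert abs(s.tau - 10.0) <= 3 * sem


@pytest.fixture(scope="module")
def recovery_run():
    pairs = [
        BindingPairSpec("H2", "DOPC", ("O13", "O14"), k_on=2.0, k_off=1 / 3.0),
        BindingPairSpec("H4", "DOPC", ("O11", "O12"), k_on=2.0, k_off=1.0),
    ]
    cfg = SyntheticConfig(
        seed=23,
        n_lipid_per_leaflet=9,
        box=(30, 30, 95.7),
        dt=0.05,
        n_frames=20_001,
        pairs=pairs,
    )
    system, _ = build_system(cfg)
    traj, truth = simulate_binding(system, cfg)
    specs = [
        HBPairSpec("DBD3", "H2", "DOPC", ("O13", "O14")),
        HBPairSpec("DBD3", "H4", "DOPC", ("O11", "O12")),
    ]
    table = pair_lifetime_table(traj, specs, cutoff=2.5, tolerance=0.0)
    return cfg, truth, table


class TestPairLifetimeTable:
    def test_tau_recovers_mean_bound_dwell(self, recovery_run):
        cfg, truth, table = recovery_run
        s = table[0]
        assert s.n_intervals >= 100
        sem = s.tau / np.sqrt(s.n_intervals)
        assert abs(s.tau - 3.0) <= 3 * sem

    def test_bound_distance_recovered(self, recovery_run):
        cfg, truth, table = recovery_run
        assert table[0].mean_distance_bound == pytest.approx(1.7, abs=0.02)
        assert table[1].mean_distance_bound == pytest.approx(2.05, abs=0.02)

    def test_rank_order_of_lifetimes(self, recovery_run):
        cfg, truth, table = recovery_run
        # ground truth: 1/k_off = 3 ns for H2 channel vs 1 ns for H4 channel
        assert table[0].tau > table[1].tau

    def test_detection_matches_ground_truth_states(self, recovery_run):
        cfg, truth, table = recovery_run
        # detected bound-frame count within 1% of the generator's truth
        s = table[0]
        gt = truth["H2/O13-O14 DOPC"]
        bound_frames_est = s.tau * s.n_intervals / cfg.dt
        assert bound_frames_est == pytest.approx(gt.bound.sum(), rel=0.01)


def bridge_system():
    atoms = [
        SiteRef(0, "DBD4", "H2"),
        SiteRef(0, "DBD4", "H4"),
        SiteRef(1, "DOPC", "O13"),
        SiteRef(1, "DOPC", "O14"),
        SiteRef(2, "CHOL", "OH-O"),
    ]
    return SystemMap(atoms=atoms, leaflet={1: "upper", 2: "lower"})


class TestBridges:
    def make_traj(self, pos):
        system = bridge_system()
        frame = Frame(time=0.0, positions=np.asarray(pos, float), box=(30, 30, 30))
        return system, Trajectory(system=system, frames=[frame], dt=0.1)

    def test_lipid_cholesterol_bridge_detected(self):
        # H2 1.7 A from DOPC O13; H4 2.0 A from cholesterol OH-O
        system, traj = self.make_traj(
            [
                [10.0, 10.0, 10.0],  # H2
                [12.0, 10.0, 10.0],  # H4
                [10.0, 10.0, 11.7],  # O13 (DOPC)
                [20.0, 20.0, 20.0],  # O14 far
                [12.0, 10.0, 12.0],  # OH-O (CHOL)
            ]
        )
        events = detect_bridges(traj, np.array([0, 1]), np.array([2, 3, 4]))
        assert len(events) == 1
        assert events[0].partner_molecules == [1, 2]
        assert set(events[0].drug_sites) == {"H2", "H4"}

    def test_same_partner_molecule_is_not_a_bridge(self):
        system, traj = self.make_traj(
            [
                [10.0, 10.0, 10.0],
                [12.0, 10.0, 10.0],
                [10.0, 10.0, 11.7],  # O13 near H2
                [12.0, 10.0, 11.8],  # O14 (same DOPC) near H4
                [25.0, 25.0, 25.0],  # CHOL far
            ]
        )
        assert detect_bridges(traj, np.array([0, 1]), np.array([2, 3, 4])) == []

    def test_all_far_gives_no_events(self):
        system, traj = self.make_traj(
            [
                [5.0, 5.0, 5.0],
                [7.0, 5.0, 5.0],
                [15.0, 15.0, 15.0],
                [16.0, 15.0, 15.0],
                [20.0, 20.0, 20.0],
            ]
        )
        assert detect_bridges(traj, np.array([0, 1]), np.array([2, 3, 4])) == []

    def test_matches_brute_force_triple_loop(self):
        rng = np.random.default_rng(31)
        system = bridge_system()
        cutoff = 2.5
        n_bridge_frames = 0
        frames = []
        for i in range(40):
            frames.append(
                Frame(time=0.1 * i, positions=rng.uniform(0, 8, (5, 3)), box=(8, 8, 8))
            )
        traj = Trajectory(system=system, frames=frames, dt=0.1)
        events = detect_bridges(traj, np.array([0, 1]), np.array([2, 3, 4]), cutoff)
        got = {e.frame_index for e in events}
        expected = set()
        partners = {2: 1, 3: 1, 4: 2}  # atom -> molecule
        for fi, f in enumerate(frames):
            for s1, s2 in [(0, 1)]:
                for a1 in (2, 3, 4):
                    for a2 in (2, 3, 4):
                        if partners[a1] == partners[a2]:
                            continue
                        d1 = minimum_image_distance(
                            f.positions[s1], f.positions[a1], f.box
                        )
                        d2 = minimum_image_distance(
                            f.positions[s2], f.positions[a2], f.box
                        )
                        if d1 <= cutoff and d2 <= cutoff:
                            expected.add(fi)
        assert got == expected
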