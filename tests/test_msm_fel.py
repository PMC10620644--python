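import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oximescreen.errors import DegeneracyError
from oximescreen.msm_fel import (
    Fel2D,
    GridSpec,
    build_msm,
    count_transitions,
    discretize,
    fel_from_msm,
    find_minima_and_barrier,
)
from oximescreen.pose_geometry import ApicalCriteria


class TestDiscretize:
    def test_lower_edge_bin0(self):
        grid = GridSpec()
        assert discretize([2.0], [0.0], grid)[0] == 0

    def test_upper_edge_last_bin(self):
        grid = GridSpec()
        state = discretize([10.0], [180.0], grid)[0]
        assert state == grid.n_states - 1

    def test_center_round_trip(self):
        grid = GridSpec(d_range=(0.0, 10.0), theta_range=(0.0, 180.0), n_d=5, n_theta=6)
        cd, ct = grid.centers()
        for i, j in itertools.product(range(5), range(6)):
            assert discretize([cd[i]], [ct[j]], grid)[0] == grid.state_index(i, j)

    def test_clipping_warns(self):
        grid = GridSpec()
        with pytest.warns(UserWarning, match="clipped"):
            states = discretize([1.0, 11.0], [90.0, 90.0], grid)
        i_d0 = grid.bin_of_state(int(states[0]))[0]
        i_d1 = grid.bin_of_state(int(states[1]))[0]
        assert i_d0 == 0 and i_d1 == grid.n_d - 1


class TestCountTransitions:
    def test_enumerated_example(self):
        counts = count_transitions([np.array([0, 0, 1, 1])], lag=1, n_states=2)
        assert counts[0, 0] == 1 and counts[0, 1] == 1 and counts[1, 1] == 1
        assert counts.sum() == 3

    def test_lag_longer_than_series(self):
        with pytest.warns(UserWarning, match="shorter"):
            counts = count_transitions([np.array([0, 1])], lag=5, n_states=2)
        assert counts.sum() == 0

    def test_no_counts_across_segments(self):
        counts = count_transitions([np.array([0, 0]), np.array([1, 1])], lag=1, n_states=2)
        assert counts[0, 1] == 0 and counts[1, 0] == 0

    @pytest.mark.filterwarnings("ignore:.*shorter than lag.*")
    @given(
        series=st.lists(
            st.lists(st.integers(0, 4), min_size=2, max_size=30), min_size=1, max_size=4
        ),
        lag=st.integers(1, 5),
    )
    @settings(max_examples=80, deadline=None)
    def test_brute_force_oracle(self, series, lag):
        arrays = [np.array(s) for s in series]
        got = count_transitions(arrays, lag=lag, n_states=5)
        expected = np.zeros((5, 5))
        for s in series:
            for t in range(len(s) - lag):
                expected[s[t], s[t + lag]] += 1
        assert (got == expected).all()


class TestBuildMsm:
    def test_symmetric_counts(self):
        model = build_msm(np.array([[9.0, 1.0], [1.0, 9.0]]))
        assert np.allclose(model.transition_matrix, [[0.9, 0.1], [0.1, 0.9]])
        assert np.allclose(model.stationary, [0.5, 0.5])

    def test_analytic_stationary(self):
        # T = [[0.8, 0.2], [0.4, 0.6]] -> pi = (q, p)/(p+q) = (2/3, 1/3)
        model = build_msm(np.array([[8.0, 2.0], [4.0, 6.0]]))
        assert np.allclose(model.stationary, [2 / 3, 1 / 3], atol=1e-12)

    def test_disconnected_state_excluded(self):
        counts = np.zeros((3, 3))
        counts[:2, :2] = [[5.0, 1.0], [2.0, 4.0]]
        counts[2, 2] = 7.0  # self-loop island, no exchange with the pair
        model = build_msm(counts)
        assert list(model.active) == [0, 1]

    def test_one_way_flow_degenerate(self):
        counts = np.array([[0.0, 3.0], [0.0, 0.0]])
        with pytest.raises(DegeneracyError):
            build_msm(counts)

    def test_rows_sum_to_one_and_fixed_point(self, rng):
        counts = rng.integers(1, 50, size=(12, 12)).astype(float)
        model = build_msm(counts)
        assert np.allclose(model.transition_matrix.sum(axis=1), 1.0, atol=1e-10)
        resid = np.max(np.abs(model.stationary @ model.transition_matrix - model.stationary))
        assert resid < 1e-8

    def test_power_iteration_agrees_with_eig(self, rng):
        """Dual route on a <=50-state model."""
        counts = rng.integers(1, 30, size=(50, 50)).astype(float)
        model = build_msm(counts)
        T = model.transition_matrix
        pi = np.full(len(T), 1.0 / len(T))
        for _ in range(20000):
            nxt = pi @ T
            if np.max(np.abs(nxt - pi)) < 1e-15:
                pi = nxt
                break
            pi = nxt
        assert np.allclose(pi / pi.sum(), model.stationary, atol=1e-10)


class TestFelFromMsm:
    def test_two_thirds_one_third(self):
        model = build_msm(np.array([[8.0, 2.0], [4.0, 6.0]]))
        grid = GridSpec(n_d=2, n_theta=2)
        fel = fel_from_msm(model, grid)
        values = fel.free_energy[np.isfinite(fel.free_energy)]
        assert sorted(values) == pytest.approx([0.0, np.log(2)])

    def test_uniform_is_flat(self):
        k = 4
        counts = np.ones((k, k))
        model = build_msm(counts)
        grid = GridSpec(n_d=2, n_theta=2)
        fel = fel_from_msm(model, grid)
        assert np.allclose(fel.free_energy[np.isfinite(fel.free_energy)], 0.0)

    def test_dominant_state_is_gm(self):
        counts = np.array([[50.0, 1.0], [10.0, 1.0]])
        model = build_msm(counts)
        grid = GridSpec(n_d=2, n_theta=2)
        report = find_minima_and_barrier(fel_from_msm(model, grid))
        assert report.gm.bin == (0, 0)

    def test_fel_recovery_from_iid_boltzmann_chains(self, rng):
        """i.i.d. samples of a known Boltzmann density fed as lag-1 chains
        recover -ln p within 0.3 kT MAE on well-sampled bins."""
        from oximescreen.synthetic_data import make_potential

        pot = make_potential("two_basin_side_GM", 3.0)
        grid = GridSpec(d_range=(2.0, 6.5), n_d=12, n_theta=12)
        sub = 8
        d_edges = np.linspace(*grid.d_range, grid.n_d * sub + 1)
        t_edges = np.linspace(*grid.theta_range, grid.n_theta * sub + 1)
        dc = (d_edges[:-1] + d_edges[1:]) / 2
        tc = (t_edges[:-1] + t_edges[1:]) / 2
        W = np.exp(-pot.energy(dc[:, None], tc[None, :]))
        p = W.reshape(grid.n_d, sub, grid.n_theta, sub).sum(axis=(1, 3)).ravel()
        p /= p.sum()
        draws = rng.choice(grid.n_states, size=300_000, p=p)
        counts = count_transitions([draws], lag=1, n_states=grid.n_states)
        model = build_msm(counts)
        fel = fel_from_msm(model, grid)
        occupancy = np.bincount(draws, minlength=grid.n_states)
        ref = -np.log(p / p.max())
        errs = []
        for state, i in zip(model.active, range(len(model.active))):
            if occupancy[state] >= 200:
                errs.append(abs(fel.free_energy[grid.bin_of_state(int(state))] - ref[state]))
        assert len(errs) > 20
        assert np.mean(errs) < 0.3


def _fel_from_array(F, n_d, n_theta, d_range=(2.0, 10.0)):
    grid = GridSpec(d_range=d_range, n_d=n_d, n_theta=n_theta)
    arr = np.asarray(F, dtype=float).reshape(n_d, n_theta)
    return Fel2D(free_energy=arr - np.nanmin(arr), grid=grid)


class TestMinimaAndBarrier:
    def test_1d_three_bins(self):
        # bins [0, 3, 1] along theta: GM at 0, LM at 2, barrier 3 - 1 = 2
        fel = _fel_from_array([[0.0, 3.0, 1.0], [4.0, 4.0, 4.0]], 2, 3)
        report = find_minima_and_barrier(fel)
        assert report.gm.bin == (0, 0)
        lm_bins = [m.bin for m in report.local_minima]
        assert (0, 2) in lm_bins
        lm = next(m for m in report.local_minima if m.bin == (0, 2))
        assert lm.barrier_to_gm == pytest.approx(2.0)

    def test_single_bowl_has_no_lm(self):
        grid = GridSpec(n_d=9, n_theta=9)
        i, j = np.meshgrid(np.arange(9), np.arange(9), indexing="ij")
        bowl = 0.1 * ((i - 4) ** 2 + (j - 4) ** 2)
        fel = Fel2D(free_energy=bowl.astype(float), grid=grid)
        report = find_minima_and_barrier(fel)
        assert report.gm.bin == (4, 4)
        assert report.local_minima == ()

    def test_min_barrier_filters_noise_dips(self):
        fel = _fel_from_array([[0.0, 1.0, 0.9], [1.0, 1.0, 1.0]], 2, 3)
        unfiltered = find_minima_and_barrier(fel)
        assert any(m.bin == (0, 2) for m in unfiltered.local_minima)
        filtered = find_minima_and_barrier(fel, min_barrier=0.5)
        assert not filtered.local_minima

    def test_apical_flag_uses_bin_center(self):
        grid = GridSpec(d_range=(2.0, 6.0), theta_range=(0.0, 180.0), n_d=4, n_theta=4)
        F = np.full((4, 4), 2.0)
        F[0, 0] = 0.0  # center (2.5, 22.5): not apical
        F[1, 3] = 1.0  # center (3.5, 157.5): apical
        fel = Fel2D(free_energy=F, grid=grid)
        report = find_minima_and_barrier(fel, ApicalCriteria())
        assert not report.gm.apical
        lm = report.local_minima[0]
        assert lm.bin == (1, 3) and lm.apical

    def test_synthetic_saddle_five_kbt(self):
        """Two wells joined through a 5.0 kT saddle built analytically."""
        grid = GridSpec(d_range=(0.0, 1.0), theta_range=(0.0, 1.0), n_d=21, n_theta=21)
        F = np.full((21, 21), 8.0)
        # channel along row 10 whose ceiling sits exactly 5 above the LM
        F[10, :] = 6.0
        F[10, 5] = 0.0  # GM
        F[10, 15] = 1.0  # LM
        fel = Fel2D(free_energy=F, grid=grid)
        report = find_minima_and_barrier(fel)
        lm = next(m for m in report.local_minima if m.bin == (10, 15))
        assert lm.barrier_to_gm == pytest.approx(5.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_minimax_matches_threshold_enumeration(self, seed):
        """Brute-force oracle on a 4x4 grid: the minimax ceiling is the
        smallest F level at which LM and GM become connected in the
        sublevel set {F <= level} (checked by exhaustive BFS)."""
        import networkx as nx

        rng = np.random.default_rng(seed)
        F = rng.uniform(0.0, 6.0, size=(4, 4))
        F[tuple(rng.integers(0, 4, 2))] = 0.0
        F -= F.min()
        fel = _fel_from_array(F, 4, 4)
        report = find_minima_and_barrier(fel)

        def connected_at(level, a, b):
            g = nx.Graph()
            g.add_nodes_from(
                (i, j) for i in range(4) for j in range(4) if F[i, j] <= level
            )
            for i, j in list(g.nodes):
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if (di, dj) != (0, 0) and (i + di, j + dj) in g:
                            g.add_edge((i, j), (i + di, j + dj))
            return a in g and b in g and nx.has_path(g, a, b)

        for lm in report.local_minima:
            ceiling = min(
                level
                for level in sorted(F.ravel())
                if connected_at(level, lm.bin, report.gm.bin)
            )
            assert lm.barrier_to_gm == pytest.approx(
                ceiling - fel.free_energy[lm.bin], abs=1e-9
            )


class TestConvergenceSmoke:
    def test_doubling_trajectory_changes_little(self):
        """Doubling data changes well-sampled FEL bins by < 0.2 kT."""
        from oximescreen.dsmd_engine import DsmdConfig, run_dsmd
        from oximescreen.synthetic_data import langevin_propagator, make_potential

        pot = make_potential("two_basin_side_GM", 2.5)
        prop = langevin_propagator(pot)
        grid = GridSpec(d_range=(2.0, 6.5), n_d=12, n_theta=12)

        def fel_and_counts(n_cycles, seed):
            config = DsmdConfig(n_cycles=n_cycles, steps_per_cycle=2000, n_replicates=2,
                                burn_in_cycles=10, master_seed=seed)
            results = run_dsmd(prop, np.array([4.4, 90.0]), config)
            series = [
                discretize(seg.d, seg.theta, grid)
                for r in results
                for seg in r.segments(10)
            ]
            counts = count_transitions(series, lag=25, n_states=grid.n_states)
            model = build_msm(counts, lag=25)
            visits = counts.sum(axis=1)
            return fel_from_msm(model, grid), visits

        fel_a, visits_a = fel_and_counts(40, seed=31)
        fel_b, visits_b = fel_and_counts(80, seed=31)
        well_sampled = (visits_a >= 2000) & (visits_b >= 2000)
        diffs = []
        for state in np.flatnonzero(well_sampled):
            b = GridSpec(d_range=(2.0, 6.5), n_d=12, n_theta=12).bin_of_state(int(state))
            fa, fb = fel_a.free_energy[b], fel_b.free_energy[b]
            if np.isfinite(fa) and np.isfinite(fb):
                diffs.append(abs(fa - fb))
        assert len(diffs) > 5
        assert np.mean(diffs) < 0.2
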