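import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hs

import stnet as st
from stnet.core import DataError

from conftest import small_instance
import oracle


class TestTwoCityExample:
    def test_progress_after_one_step_is_50_km(self, two_city):
        state = st.initial_state(two_city, "A")
        state = st.propagation_step(state, two_city, 2)
        assert state.P[0, 1] == pytest.approx(50.0)
        assert state.K == {"A"}

    def test_arrival_after_three_steps(self, two_city):
        _, summ = st.run_propagation(two_city, "A")
        b = summ.nodes.index("B")
        assert summ.arrival_step[b] - 1 == 3          # three elapsed timesteps
        assert summ.dist_lambda[b] == pytest.approx(3 * 900.0)
        assert summ.dist_sigma[b] == pytest.approx(150.0)

    def test_unreachable_in_two_step_window(self, two_city):
        _, summ = st.run_propagation(two_city, "A", window=(1, 3))
        b = summ.nodes.index("B")
        assert summ.arrival_step[b] == -1
        assert math.isinf(summ.dist_lambda[b])
        assert math.isinf(summ.dist_sigma[b])


class TestFiveNodeExample:
    """The worked moving-front example: arrivals, resets, and the A->E path."""

    def test_full_trace(self, five_node):
        trace, summ = st.run_propagation(five_node, "A")
        k_by_step = {s.step: s.K for s in trace}
        assert k_by_step[1] == {"A"}
        assert k_by_step[2] == {"A", "B"}
        assert k_by_step[3] == {"A", "B"}          # C only partial
        assert k_by_step[4] == {"A", "B", "C"}
        assert k_by_step[6] == {"A", "B", "C", "E"}

    def test_partial_progress_and_reset(self, five_node):
        trace, _ = st.run_propagation(five_node, "A")
        idx = {v: j for j, v in enumerate(five_node.nodes)}
        P_by_step = {s.step: s.P for s in trace}
        assert P_by_step[3][idx["B"], idx["C"]] == pytest.approx(1.0)  # partial
        assert P_by_step[2][idx["A"], idx["D"]] == pytest.approx(1.0)
        assert P_by_step[3][idx["A"], idx["D"]] == 0.0   # edge gone: reset
        assert P_by_step[5][idx["A"], idx["D"]] == pytest.approx(2.0)
        assert P_by_step[6][idx["A"], idx["D"]] == 0.0   # second failure

    def test_shortest_path_to_E(self, five_node):
        _, summ = st.run_propagation(five_node, "A")
        e = summ.nodes.index("E")
        assert summ.dist_lambda[e] == pytest.approx(5.0)   # seconds
        assert summ.dist_sigma[e] == pytest.approx(4.0)    # metres
        (path,) = summ.paths_to("E")
        assert [v for v, _ in path.sequence] == ["A", "B", "C", "E"]
        assert path.latency == pytest.approx(5.0)
        assert path.spatial_length == pytest.approx(4.0)
        assert path.n == 3

    def test_D_never_reached(self, five_node):
        _, summ = st.run_propagation(five_node, "A")
        d = summ.nodes.index("D")
        assert summ.arrival_step[d] == -1
        assert summ.sigma[d] == 0


class TestStepSemantics:
    def test_infinite_speed_arrives_first_step_edge_present(self):
        win = st.ObservationWindow(0, 4, 1.0)
        snaps = [{}, {}, {("A", "B"): math.inf}, {}]
        net = st.build_network(["A", "B"], {"A": (0, 0), "B": (500.0, 0)},
                               snaps, win)
        _, summ = st.run_propagation(net, "A")
        assert summ.arrival_step[1] == 3
        assert summ.dist_sigma[1] == pytest.approx(500.0)

    def test_window_of_length_one_reaches_only_origin(self, five_node):
        _, summ = st.run_propagation(five_node, "A", window=(3, 3))
        assert summ.arrival_step[summ.nodes.index("A")] == 3
        assert (summ.arrival_step >= 0).sum() == 1

    def test_step_preconditions(self, two_city):
        state = st.initial_state(two_city, "A")
        with pytest.raises(DataError):
            st.propagation_step(state, two_city, 1)
        with pytest.raises(DataError):
            st.propagation_step(state, two_city, 3)   # state is at step 1

    def test_unknown_origin(self, two_city):
        with pytest.raises(DataError, match="unknown node"):
            st.run_propagation(two_city, "Z")


class TestAllPairs:
    def test_one_step_complete_network(self, all_pairs_one_step):
        ap = st.all_pairs(all_pairs_one_step)
        off = ~np.eye(4, dtype=bool)
        assert np.all(ap.dist_lambda[off] == all_pairs_one_step.window.tau)
        assert ap.reachability.all()
        assert np.all(np.diag(ap.dist_lambda) == 0)

    def test_five_node_origin_row(self, five_node):
        ap = st.all_pairs(five_node)
        a = ap.nodes.index("A")
        reach_from_a = {v: bool(ap.reachability[a, ap.nodes.index(v)])
                        for v in "BCDE"}
        assert reach_from_a == {"B": True, "C": True, "D": False, "E": True}

    def test_chunking_is_result_identical(self):
        net = small_instance(21)
        full = st.all_pairs(net)
        chunked = st.all_pairs(net, chunk_size=2)
        assert np.array_equal(full.arrival, chunked.arrival)
        assert np.array_equal(full.dist_sigma, chunked.dist_sigma)
        assert np.array_equal(full.sigma, chunked.sigma)

    def test_matches_single_origin_runs(self):
        net = small_instance(22)
        ap = st.all_pairs(net)
        for v in net.nodes:
            _, summ = st.run_propagation(net, v, record_trace=False)
            b = net.nodes.index(v)
            assert np.array_equal(ap.arrival[b], summ.arrival_step)
            assert np.array_equal(ap.dist_sigma[b], summ.dist_sigma)
            assert np.array_equal(ap.sigma[b], summ.sigma)


@pytest.mark.parametrize("seed", range(40))
def test_engine_matches_exhaustive_oracle(seed):
    """Engine distances, reachability and path counts equal brute force."""
    net = small_instance(seed)
    ap = st.all_pairs(net)
    for v in net.nodes:
        ref = oracle.oracle_summary(net, v)
        b = net.nodes.index(v)
        for w in net.nodes:
            j = net.nodes.index(w)
            r = ref[w]
            assert bool(ap.reachability[b, j]) == r["reachable"], (v, w)
            if r["reachable"]:
                assert ap.dist_lambda[b, j] == pytest.approx(r["lambda"])
                assert ap.dist_sigma[b, j] == pytest.approx(r["sigma_dist"],
                                                            rel=1e-9)
                assert ap.sigma[b, j] == r["count"], (v, w)
            else:
                assert math.isinf(ap.dist_lambda[b, j])
                assert math.isinf(ap.dist_sigma[b, j])


@pytest.mark.parametrize("seed", [2, 9, 17])
def test_latency_optimal_over_all_sequences(seed):
    """No hop-by-hop simulated node sequence beats the engine's latency."""
    rng = np.random.default_rng(seed)
    net = st.random_geometric_stn(
        n=5, T=8, tau=30.0, extent=800.0, radius=600.0,
        p=0.5, inf_prob=0.2, seed=int(rng.integers(2**31)))
    ap = st.all_pairs(net)
    for v in net.nodes:
        best = oracle.min_latency_by_sequence_enumeration(net, v)
        b = net.nodes.index(v)
        for w in net.nodes:
            assert ap.dist_lambda[b, net.nodes.index(w)] == pytest.approx(
                best[w]) or (math.isinf(best[w])
                             and math.isinf(ap.dist_lambda[b, net.nodes.index(w)]))


class TestInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_reachability_set_monotone(self, seed):
        net = small_instance(seed + 100)
        for v in net.nodes:
            trace, _ = st.run_propagation(net, v)
            for prev, cur in zip(trace, trace[1:]):
                assert prev.K <= cur.K

    @pytest.mark.parametrize("seed", range(8))
    def test_paths_temporally_ordered_and_consistent(self, seed):
        net = small_instance(seed + 200)
        ap = st.all_pairs(net)
        for v in net.nodes:
            summ = ap.summary_for(v, net)
            for w in net.nodes:
                if w == v or not summ.reachable(w):
                    continue
                paths = summ.paths_to(w)
                assert len(paths) == summ.sigma[summ.nodes.index(w)]
                for p in paths:
                    steps = [s for _, s in p.sequence]
                    assert all(a < b for a, b in zip(steps, steps[1:]))
                    assert p.latency == summ.dist_lambda[summ.nodes.index(w)]
                    assert p.spatial_length == pytest.approx(
                        summ.dist_sigma[summ.nodes.index(w)], rel=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_spatial_distance_bounded_below_by_straight_line(self, seed):
        net = small_instance(seed + 300)
        ap = st.all_pairs(net)
        D = net.distance_matrix(1)
        finite = np.isfinite(ap.dist_sigma)
        np.fill_diagonal(finite, False)
        assert np.all(ap.dist_sigma[finite] >= D[finite] - 1e-9)

    @given(hs.integers(min_value=0, max_value=10**6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_determinism_bit_identical(self, seed):
        net1 = small_instance(seed)
        net2 = small_instance(seed)
        ap1, ap2 = st.all_pairs(net1), st.all_pairs(net2)
        assert np.array_equal(ap1.dist_lambda, ap2.dist_lambda)
        assert np.array_equal(ap1.dist_sigma, ap2.dist_sigma)
        assert np.array_equal(ap1.sigma, ap2.sigma)


class TestHorizonGrowth:
    def test_single_step_horizon_gives_singletons(self, five_node):
        curve = st.horizon_growth(five_node, [1.0])
        assert curve == [(1.0, 1 / 5)]

    def test_non_decreasing_in_h(self):
        net = st.scheduled_lines_stn(seed=5)
        tau = net.window.tau
        curve = st.horizon_growth(net, [tau * k for k in (1, 5, 10, 20, 40)])
        s_vals = [s for _, s in curve]
        assert all(a <= b for a, b in zip(s_vals, s_vals[1:]))

    def test_plateau_during_service_gap(self):
        # one ring line, service only in the first 5 of every 20 steps
        net = st.scheduled_lines_stn(n_lines=1, stations_per_line=8,
                                     geometry="ring", spacing=600.0,
                                     speed=10.0, tau=60.0, T=40,
                                     period=20, duty=5)
        tau = net.window.tau
        hs_grid = [tau * k for k in (5, 8, 12, 16, 20)]
        curve = dict(st.horizon_growth(net, hs_grid))
        # horizons ending inside the gap (steps 6..20) add no reachability
        assert curve[tau * 8] == curve[tau * 12] == curve[tau * 16]
        assert curve[tau * 5] <= curve[tau * 8]

    def test_empty_horizon_list_rejected(self, five_node):
        with pytest.raises(DataError):
            st.horizon_growth(five_node, [])
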