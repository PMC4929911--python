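import json
import math

import numpy as np
import pytest

import stnet as st
from stnet.core import DataError

from conftest import small_instance


class TestMetricSpace:
    def test_euclidean_3_4_5(self):
        m = st.MetricSpace(units="m")
        assert m.distance(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == 5.0

    def test_two_city_distance_is_150_km(self, two_city):
        assert st.distance_matrix(two_city, 1)[0, 1] == pytest.approx(150.0)

    # expected values frozen from an independent geodesic library
    # (geosphere::distVincentyEllipsoid on WGS-84), metres
    @pytest.mark.parametrize("a,b,expected", [
        ((51.5074, -0.1278), (48.8566, 2.3522), 343923.120090),
        ((40.6413, -73.7781), (33.9416, -118.4085), 3983079.748476),
        ((0.0, 0.0), (0.0, 1.0), 111319.490792),
        ((-5.0, 10.0), (-5.0005, 10.001), 123.917904),
    ])
    def test_geodesic_matches_independent_library(self, a, b, expected):
        assert st.vincenty_distance(*a, *b) == pytest.approx(expected, abs=1.0)

    def test_geodesic_units_and_symmetry(self):
        m = st.MetricSpace(kind="geodesic-ellipsoid", units="km")
        lhr, cdg = np.array([51.5074, -0.1278]), np.array([48.8566, 2.3522])
        assert m.distance(lhr, cdg) == pytest.approx(343.923120, abs=1e-3)
        assert m.distance(lhr, cdg) == pytest.approx(m.distance(cdg, lhr), rel=1e-12)
        assert m.distance(lhr, lhr) == 0.0

    @pytest.mark.parametrize("kind", ["euclidean", "geodesic-ellipsoid"])
    def test_pairwise_symmetric_zero_diagonal(self, kind):
        rng = np.random.default_rng(7)
        coords = (rng.uniform(-50, 50, size=(5, 2)) if kind != "euclidean"
                  else rng.uniform(0, 100, size=(5, 2)))
        D = st.MetricSpace(kind=kind).pairwise(coords)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)
        off = D[~np.eye(5, dtype=bool)]
        assert np.all(off > 0)


class TestObservationWindow:
    def test_snapshot_times(self):
        w = st.ObservationWindow(t1=100.0, T=5, tau=60.0)
        assert w.time_of(1) == 100.0
        assert w.time_of(5) == 340.0
        assert w.duration == 300.0

    @pytest.mark.parametrize("kwargs", [
        dict(t1=0, T=0, tau=1.0), dict(t1=0, T=3, tau=0.0),
        dict(t1=0, T=3, tau=-1.0)])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(DataError):
            st.ObservationWindow(**kwargs)


class TestNetworkContract:
    def test_self_edges_rejected(self):
        win = st.ObservationWindow(0, 1, 1.0)
        with pytest.raises(DataError, match="self-edge"):
            st.build_network(["A", "B"], {"A": (0, 0), "B": (1, 0)},
                             [{("A", "A"): 1.0}], win)

    def test_nonpositive_speed_rejected(self):
        win = st.ObservationWindow(0, 1, 1.0)
        with pytest.raises(DataError, match="speed"):
            st.build_network(["A", "B"], {"A": (0, 0), "B": (1, 0)},
                             [{("A", "B"): 0.0}], win)

    def test_unknown_node_in_edge_rejected(self):
        win = st.ObservationWindow(0, 1, 1.0)
        with pytest.raises(DataError, match="unknown node"):
            st.build_network(["A", "B"], {"A": (0, 0), "B": (1, 0)},
                             [{("A", "Z"): 1.0}], win)

    def test_empty_edges_is_valid(self):
        win = st.ObservationWindow(0, 4, 1.0)
        net = st.build_network(["A", "B", "C"],
                               {"A": (0, 0), "B": (1, 0), "C": (2, 0)},
                               [{}] * 4, win)
        assert all(not s for s in net.snapshots)
        assert st.validate(net).passed


class TestIO:
    def test_round_trip_static(self, tmp_path):
        net = small_instance(11)
        paths = st.save_network(net, tmp_path)
        back = st.load_network(paths["nodes"], paths["edges"], paths["meta"])
        assert net.equals(back)

    def test_round_trip_trajectories(self, tmp_path):
        net = st.contact_stn(n=6, T=8, contact_prob=0.3, seed=4)
        paths = st.save_network(net, tmp_path)
        back = st.load_network(paths["nodes"], paths["edges"], paths["meta"])
        assert net.equals(back)
        assert not back.static_positions

    def test_inf_speed_round_trip(self, tmp_path):
        net = st.contact_stn(n=4, T=3, contact_prob=0.9, seed=1)
        paths = st.save_network(net, tmp_path)
        back = st.load_network(paths["nodes"], paths["edges"], paths["meta"])
        assert any(math.isinf(s) for snap in back.snapshots
                   for s in snap.values())
        assert net.equals(back)

    def test_two_city_loadable_from_files(self, tmp_path, two_city):
        paths = st.save_network(two_city, tmp_path)
        back = st.load_network(paths["nodes"], paths["edges"], paths["meta"])
        assert back.snapshots[0][("A", "B")] == pytest.approx(200 / 3600)
        assert back.metric.units == "km"

    def test_trajectory_gaps_carried_forward(self, tmp_path):
        (tmp_path / "nodes.csv").write_text(
            "t,node_id,x,y\n1,A,0,0\n3,A,5,0\n2,B,1,1\n")
        (tmp_path / "edges.csv").write_text("t,source,target,speed\n")
        meta = {"tau": 1.0, "T": 4, "t1": 0.0}
        net = st.load_network(tmp_path / "nodes.csv", tmp_path / "edges.csv",
                              meta)
        a = net.nodes.index("A")
        b = net.nodes.index("B")
        assert net.positions[:, a, 0].tolist() == [0, 0, 5, 5]  # LOCF
        # leading gap backfilled, then carried forward
        assert net.positions[:, b, 0].tolist() == [1, 1, 1, 1]

    def test_load_errors(self, tmp_path):
        (tmp_path / "nodes.csv").write_text("node_id,x,y\nA,0,0\nB,1,0\n")
        meta = {"tau": 1.0, "T": 2, "t1": 0.0}

        (tmp_path / "bad_t.csv").write_text(
            "t,source,target,speed\n5,A,B,1.0\n")
        with pytest.raises(DataError, match="outside"):
            st.load_network(tmp_path / "nodes.csv", tmp_path / "bad_t.csv",
                            meta)
        (tmp_path / "bad_node.csv").write_text(
            "t,source,target,speed\n1,A,Q,1.0\n")
        with pytest.raises(DataError, match="unknown"):
            st.load_network(tmp_path / "nodes.csv", tmp_path / "bad_node.csv",
                            meta)
        (tmp_path / "dup.csv").write_text(
            "t,source,target,speed\n1,A,B,1.0\n1,A,B,2.0\n")
        with pytest.raises(DataError, match="duplicate"):
            st.load_network(tmp_path / "nodes.csv", tmp_path / "dup.csv",
                            meta)
        (tmp_path / "neg.csv").write_text(
            "t,source,target,speed\n1,A,B,-2\n")
        with pytest.raises(DataError, match="speed"):
            st.load_network(tmp_path / "nodes.csv", tmp_path / "neg.csv",
                            meta)

    def test_undirected_expansion(self, tmp_path):
        (tmp_path / "nodes.csv").write_text("node_id,x,y\nA,0,0\nB,1,0\n")
        (tmp_path / "edges.csv").write_text("t,source,target,speed\n1,A,B,inf\n")
        net = st.load_network(tmp_path / "nodes.csv", tmp_path / "edges.csv",
                              {"tau": 1.0, "T": 1, "t1": 0.0},
                              undirected_edges=True)
        assert net.snapshots[0] == {("A", "B"): math.inf,
                                    ("B", "A"): math.inf}


class TestAggregateGraph:
    def test_union_semantics(self):
        win = st.ObservationWindow(0, 100, 1.0)
        snaps = [{} for _ in range(100)]
        snaps[6] = {("A", "B"): 1.0}  # only snapshot 7
        net = st.build_network(["A", "B", "C"],
                               {"A": (0, 0), "B": (1, 0), "C": (2, 0)},
                               snaps, win)
        g = st.aggregate_graph(net)
        assert g.has_edge("A", "B") and not g.has_edge("B", "A")
        assert g.graph["n_aggregate_edges"] == 1
        assert g.graph["edge_density"] == pytest.approx(1 / 6)

    def test_matches_brute_force_union(self):
        net = small_instance(3)
        g = st.aggregate_graph(net)
        union = set()
        for snap in net.snapshots:
            union |= set(snap)
        assert set(g.edges) == union

    def test_invariant_under_snapshot_permutation(self):
        net = small_instance(5)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(net.window.T))
        shuffled = net.copy_with_snapshots(
            [dict(net.snapshots[i]) for i in perm])
        g1, g2 = st.aggregate_graph(net), st.aggregate_graph(shuffled)
        assert set(g1.edges) == set(g2.edges)


class TestValidate:
    def test_co_located_nodes_fail(self):
        win = st.ObservationWindow(0, 1, 1.0)
        net = st.build_network(["A", "B"], {"A": (1, 2), "B": (1, 2)},
                               [{}], win)
        report = st.validate(net)
        assert not report.passed
        assert any(code == "co-located-nodes" for _, code, _ in report.entries)

    def test_undersampling_warning(self):
        # the edge covers its 1 m distance in tau/2
        win = st.ObservationWindow(0, 2, 1.0)
        net = st.build_network(["A", "B"], {"A": (0, 0), "B": (1, 0)},
                               [{("A", "B"): 2.0}] * 2, win)
        report = st.validate(net)
        assert report.passed  # warning, not error
        assert any(code == "granularity-undersampling"
                   for _, code, _ in report.warnings)

    def test_well_formed_fixture_clean(self, two_city):
        # min direct propagation duration = 3 tau: no warning
        report = st.validate(two_city)
        assert report.passed and not report.entries

    def test_infinite_speeds_do_not_trigger_warning(self):
        win = st.ObservationWindow(0, 2, 1.0)
        net = st.build_network(["A", "B"], {"A": (0, 0), "B": (1000, 0)},
                               [{("A", "B"): math.inf}] * 2, win)
        assert not st.validate(net).warnings


def test_meta_round_trip_json(tmp_path, two_city):
    paths = st.save_network(two_city, tmp_path)
    meta = json.loads(paths["meta"].read_text())
    assert meta["tau"] == 900.0 and meta["T"] == 6
    assert meta["metric"]["units"] == "km"
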