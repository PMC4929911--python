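import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

import stnet as st


def small_instance(seed: int) -> st.SpatioTemporalNetwork:
    """Small seeded random geometric network for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 8))          # 3..7
    T = int(rng.integers(2, 11))         # 2..10
    p = float(rng.uniform(0.3, 0.8))
    inf_prob = float(rng.choice([0.0, 0.3]))
    return st.random_geometric_stn(
        n=n, T=T, tau=30.0, extent=1000.0,
        radius=float(rng.uniform(400.0, 900.0)), p=p,
        speed_mu=np.log(8.0), speed_sigma=0.6, inf_prob=inf_prob,
        seed=int(rng.integers(2**31)))


@pytest.fixture
def two_city():
    return st.two_city_fixture()


@pytest.fixture
def five_node():
    return st.five_node_fixture()


@pytest.fixture
def chain3():
    """Directed chain A->B->C, one timestep per hop, persistent edges."""
    win = st.ObservationWindow(0.0, 4, 1.0)
    return st.build_network(
        ["A", "B", "C"], {"A": (0, 0), "B": (1, 0), "C": (2, 0)},
        [{("A", "B"): 1.0, ("B", "C"): 1.0}] * 4, win)


@pytest.fixture
def all_pairs_one_step():
    """4 nodes, all 12 ordered edges every snapshot, direct arrival in 1 step."""
    pos = {"A": (0.0, 0.0), "B": (1.0, 0.0), "C": (0.0, 1.0), "D": (1.0, 1.0)}
    win = st.ObservationWindow(0.0, 3, 1.0)
    names = list(pos)
    metric = st.MetricSpace(units="m")
    snap = {}
    for v in names:
        for w in names:
            if v != w:
                d = metric.distance(np.array(pos[v]), np.array(pos[w]))
                snap[(v, w)] = d / win.tau
    return st.build_network(names, pos, [dict(snap)] * win.T, win, metric)
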