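"""Deterministic fixtures and seeded random spatio-temporal generators.

The fixtures reproduce small worked systems with known behaviour (a two-city
transit link, a five-node moving-front example, a pair of bridges with equal
path betweenness but different betweenness efficiency).  The random
generators emulate the main empirical network classes the framework targets:
random geometric networks with intermittent edges, scheduled transit lines
with service gaps, connectome-like networks with a static topology and
per-synapse-type signalling delays, and contact networks with instantaneous
(infinite-speed) intermittent links.  Identical parameters and seed always
yield an identical network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (DataError, MetricSpace, ObservationWindow,
                   SpatioTemporalNetwork, build_network)

__all__ = [
    "GeneratorSpec",
    "two_city_fixture",
    "five_node_fixture",
    "equal_pb_diff_be_fixture",
    "random_geometric_stn",
    "scheduled_lines_stn",
    "connectome_like_stn",
    "contact_stn",
    "generate",
    "MODELS",
]


# ---------------------------------------------------------------------------
# Deterministic fixtures
# ---------------------------------------------------------------------------


def two_city_fixture() -> SpatioTemporalNetwork:
    """Two cities 150 km apart joined by a persistent 200 km/h link.

    Kilometre units, tau = 900 s (15 min), T = 6; directed edge A -> B in
    every snapshot.  One propagation step accumulates 50 km, so three
    timesteps must elapse before B is reachable from A.
    """
    window = ObservationWindow(t1=0.0, T=6, tau=900.0)
    metric = MetricSpace(kind="euclidean", dimension=2, units="km")
    speed = 200.0 / 3600.0  # km/s
    snaps = [{("A", "B"): speed} for _ in range(window.T)]
    return build_network(["A", "B"], {"A": (0.0, 0.0), "B": (150.0, 0.0)},
                         snaps, window, metric)


def five_node_fixture() -> SpatioTemporalNetwork:
    """Five nodes at integer planar coordinates, tau = 1 s, all speeds 1 m/s.

    Propagating from A at t1: B arrives at t2; propagation B -> C is partial
    at t3 and completes at t4; the A -> D edge vanishes at t3 (progress
    resets), reappears at t4-t5 and vanishes again at t6, so D is never
    reached; E arrives at t6 via A -> B -> C -> E with latency 5 s and
    spatial path length 4 m.
    """
    window = ObservationWindow(t1=0.0, T=6, tau=1.0)
    metric = MetricSpace(kind="euclidean", dimension=2, units="m")
    pos = {"A": (0.0, 0.0), "B": (0.0, 1.0), "C": (0.0, 3.0),
           "D": (3.0, 0.0), "E": (1.0, 3.0)}
    s = 1.0
    snaps = [
        {("A", "B"): s, ("A", "D"): s},   # t1
        {("A", "B"): s, ("A", "D"): s},   # t2: B arrives; progress to D = 1
        {("B", "C"): s},                  # t3: C partial (1 of 2 m); D resets
        {("B", "C"): s, ("A", "D"): s},   # t4: C arrives; D restarts
        {("A", "D"): s},                  # t5: progress to D = 2 of 3 m
        {("C", "E"): s},                  # t6: E arrives; D resets -> fails
    ]
    return build_network(list(pos), pos, snaps, window, metric)


def equal_pb_diff_be_fixture() -> SpatioTemporalNetwork:
    """Two parallel source-bridge-sink chains with equal PB, different BE.

    Both bridges (X slow, Y fast) carry exactly one source--destination pair,
    so their path betweenness is equal; the Y chain's hops complete in one
    timestep each versus two for X, so the pair routed through Y is twice as
    fast and Y's betweenness efficiency is strictly higher.  A BE-guided
    attack therefore removes Y first.
    """
    window = ObservationWindow(t1=0.0, T=8, tau=1.0)
    metric = MetricSpace(kind="euclidean", dimension=2, units="m")
    pos = {"SA": (0.0, 0.0), "X": (1.0, 0.0), "DA": (2.0, 0.0),
           "SB": (0.0, 3.0), "Y": (1.0, 3.0), "DB": (2.0, 3.0)}
    slow, fast = 0.5, 1.0  # m/s over 1 m hops: 2 steps vs 1 step
    snap = {("SA", "X"): slow, ("X", "DA"): slow,
            ("SB", "Y"): fast, ("Y", "DB"): fast}
    return build_network(list(pos), pos, [dict(snap)] * window.T,
                         window, metric)


# ---------------------------------------------------------------------------
# Random generators
# ---------------------------------------------------------------------------


def random_geometric_stn(n: int = 30, T: int = 20, tau: float = 30.0,
                         extent: float = 1000.0, radius: float = 300.0,
                         p: float = 0.5,
                         speed_mu: float = math.log(5.0),
                         speed_sigma: float = 0.5,
                         inf_prob: float = 0.0,
                         seed: int | None = None) -> SpatioTemporalNetwork:
    """Random geometric network with intermittently active edges.

    ``n`` nodes uniform in an ``extent`` x ``extent`` square (metres);
    every ordered pair within ``radius`` is a candidate directed edge,
    independently active in each snapshot with probability ``p``.  Speeds are
    drawn once per candidate edge from lognormal(speed_mu, speed_sigma) m/s,
    replaced by +inf with probability ``inf_prob``.
    """
    if n < 2 or T < 1:
        raise DataError("need n >= 2 and T >= 1")
    if not 0 <= p <= 1 or not 0 <= inf_prob <= 1:
        raise DataError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, extent, size=(n, 2))
    nodes = [f"n{j:03d}" for j in range(n)]
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    cand = [(v, w) for v in range(n) for w in range(n)
            if v != w and dist[v, w] <= radius]
    speeds = {}
    for e in cand:
        s = float(rng.lognormal(speed_mu, speed_sigma))
        speeds[e] = math.inf if rng.random() < inf_prob else s
    snaps = []
    for _ in range(T):
        active = rng.random(len(cand)) < p
        snaps.append({(nodes[v], nodes[w]): speeds[(v, w)]
                      for (v, w), a in zip(cand, active) if a})
    window = ObservationWindow(t1=0.0, T=T, tau=tau)
    return build_network(nodes, pos, snaps, window,
                         MetricSpace(units="m"))


def scheduled_lines_stn(n_lines: int = 4, stations_per_line: int = 10,
                        geometry: str = "star", spacing: float = 800.0,
                        speed: float = 10.0, tau: float = 60.0, T: int = 40,
                        period: int = 12, duty: int = 9,
                        seed: int | None = None) -> SpatioTemporalNetwork:
    """Scheduled transit lines: periodic finite-speed consecutive-station edges.

    ``geometry="star"`` lays ``n_lines`` radial lines that share a central
    hub (N = n_lines * (stations_per_line - 1) + 1); ``geometry="ring"`` lays
    one circular line of ``stations_per_line`` stations.  Consecutive
    stations are joined by bidirectional edges that are active during the
    first ``duty`` timesteps of every ``period`` timesteps (per-line phase
    offsets), emulating timetabled service with off-hours gaps.  A seed adds
    jitter to line speeds and phase offsets; without one the network is fully
    deterministic.
    """
    if stations_per_line < 2 or n_lines < 1:
        raise DataError("need >= 1 line and >= 2 stations per line")
    if not 1 <= duty <= period:
        raise DataError("need 1 <= duty <= period")
    rng = np.random.default_rng(seed) if seed is not None else None

    lines: list[list[str]] = []
    pos: dict[str, tuple[float, float]] = {}
    if geometry == "star":
        pos["HUB"] = (0.0, 0.0)
        for k in range(n_lines):
            ang = 2 * math.pi * k / n_lines
            names = ["HUB"]
            for j in range(1, stations_per_line):
                v = f"L{k}S{j}"
                pos[v] = (j * spacing * math.cos(ang),
                          j * spacing * math.sin(ang))
                names.append(v)
            lines.append(names)
    elif geometry == "ring":
        m = stations_per_line
        R = spacing * m / (2 * math.pi)
        names = []
        for j in range(m):
            ang = 2 * math.pi * j / m
            v = f"S{j:02d}"
            pos[v] = (R * math.cos(ang), R * math.sin(ang))
            names.append(v)
        lines.append(names + [names[0]])  # close the ring
    else:
        raise DataError(f"unknown geometry {geometry!r}")

    line_speed = []
    line_offset = []
    for k in range(len(lines)):
        jitter = float(rng.uniform(0.85, 1.15)) if rng is not None else 1.0
        line_speed.append(speed * jitter)
        line_offset.append(int(rng.integers(period)) if rng is not None else 0)

    snaps: list[dict[tuple[str, str], float]] = []
    for t in range(1, T + 1):
        snap: dict[tuple[str, str], float] = {}
        for k, names in enumerate(lines):
            if (t - 1 - line_offset[k]) % period >= duty:
                continue  # service gap
            for a, b in zip(names, names[1:]):
                snap[(a, b)] = line_speed[k]
                snap[(b, a)] = line_speed[k]
        snaps.append(snap)
    window = ObservationWindow(t1=0.0, T=T, tau=tau)
    return build_network(list(pos), pos, snaps, window, MetricSpace(units="m"))


def connectome_like_stn(n: int = 60, density: float = 0.08,
                        delay_range: tuple[float, float] = (0.010, 0.030),
                        tau: float = 0.010, T: int = 30,
                        extent: tuple[float, float] = (1.2e-3, 0.2e-3),
                        seed: int | None = None) -> SpatioTemporalNetwork:
    """Connectome-like network: static topology, speed classes by synapse type.

    ``n`` neurons embedded in a 2-D rectangle of size ``extent`` (metres,
    lateral-plane scale of a small nervous system).  Directed connections are
    drawn with probability ``density``; each is labelled electrical, chemical
    or both, and its direct signalling delay is drawn from a type-specific
    sub-range of ``delay_range`` (electrical fastest), with speed = distance
    / delay so every direct propagation delay falls inside ``delay_range``.
    Every snapshot shares the same edge set and speeds (temporal correlation
    exactly 1).  Edge type labels are exposed as ``net.edge_types``.
    """
    if n < 2:
        raise DataError("need n >= 2")
    lo, hi = delay_range
    if not 0 < lo < hi:
        raise DataError("delay_range must satisfy 0 < lo < hi")
    rng = np.random.default_rng(seed)
    pos = rng.uniform((0.0, 0.0), extent, size=(n, 2))
    nodes = [f"neu{j:03d}" for j in range(n)]
    span = hi - lo
    type_ranges = {"electrical": (lo, lo + 0.35 * span),
                   "both": (lo + 0.25 * span, lo + 0.65 * span),
                   "chemical": (lo + 0.55 * span, hi)}
    type_names = ("chemical", "electrical", "both")
    type_probs = (0.6, 0.25, 0.15)

    edge_speeds: dict[tuple[str, str], float] = {}
    edge_types: dict[tuple[str, str], str] = {}
    for v in range(n):
        for w in range(n):
            if v == w or rng.random() >= density:
                continue
            etype = type_names[int(rng.choice(3, p=type_probs))]
            a, b = type_ranges[etype]
            delay = float(rng.uniform(a, b))
            d = float(np.linalg.norm(pos[v] - pos[w]))
            edge_speeds[(nodes[v], nodes[w])] = d / delay
            edge_types[(nodes[v], nodes[w])] = etype
    window = ObservationWindow(t1=0.0, T=T, tau=tau)
    net = build_network(nodes, pos, [dict(edge_speeds)] * T, window,
                        MetricSpace(units="m"))
    net.edge_types = edge_types
    return net


def contact_stn(n: int = 25, T: int = 50, tau: float = 3600.0,
                contact_prob: float = 0.02, step_scale: float = 500.0,
                extent: float = 20000.0,
                seed: int | None = None) -> SpatioTemporalNetwork:
    """Contact network: intermittent bidirectional infinite-speed links.

    Nodes follow independent Gaussian random walks (step scale
    ``step_scale`` metres) inside an ``extent``-sized region; in each
    snapshot every unordered pair is in contact with probability
    ``contact_prob``, adding the two directed edges with infinite speed
    (instantaneous interaction, as in proximity/communication logs).
    """
    if n < 2 or T < 1:
        raise DataError("need n >= 2 and T >= 1")
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, extent, size=(n, 2))
    steps = rng.normal(0.0, step_scale, size=(T, n, 2))
    steps[0] = 0.0
    traj = np.clip(start[None] + np.cumsum(steps, axis=0), 0.0, extent)
    nodes = [f"p{j:02d}" for j in range(n)]
    snaps = []
    for _ in range(T):
        snap: dict[tuple[str, str], float] = {}
        for v in range(n):
            for w in range(v + 1, n):
                if rng.random() < contact_prob:
                    snap[(nodes[v], nodes[w])] = math.inf
                    snap[(nodes[w], nodes[v])] = math.inf
        snaps.append(snap)
    window = ObservationWindow(t1=0.0, T=T, tau=tau)
    return SpatioTemporalNetwork(nodes=nodes, positions=traj,
                                 metric=MetricSpace(units="m"),
                                 snapshots=snaps, window=window)


# ---------------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------------

MODELS = {
    "two_city": two_city_fixture,
    "five_node_demo": five_node_fixture,
    "equal_pb_diff_be": equal_pb_diff_be_fixture,
    "random_geometric": random_geometric_stn,
    "scheduled_lines": scheduled_lines_stn,
    "connectome_like": connectome_like_stn,
    "contact_instantaneous": contact_stn,
}

_SEEDED = {"random_geometric", "scheduled_lines", "connectome_like",
           "contact_instantaneous"}


@dataclass(frozen=True)
class GeneratorSpec:
    """A generator model name, its parameters and a seed.

    Identical spec (model, params, seed) always produces an identical
    network.
    """

    model: str
    params: dict = field(default_factory=dict)
    seed: int | None = None


def generate(spec: GeneratorSpec) -> SpatioTemporalNetwork:
    """Instantiate a network from a :class:`GeneratorSpec`."""
    if spec.model not in MODELS:
        raise DataError(f"unknown generator model {spec.model!r}; "
                        f"choose from {sorted(MODELS)}")
    fn = MODELS[spec.model]
    kwargs = dict(spec.params)
    if spec.model in _SEEDED:
        kwargs.setdefault("seed", spec.seed)
    elif spec.params:
        raise DataError(f"model {spec.model!r} takes no parameters")
    return fn(**kwargs)
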