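"""Descriptive statistics of a spatio-temporal network.

Topological temporal correlation C measures snapshot-to-snapshot persistence
of the topology: per node and consecutive snapshot pair, the cosine overlap
of the node's out-neighbourhoods, averaged over nodes and then over snapshot
transitions (1 for a static topology, 0 for disjoint consecutive edge sets).
Topological reciprocity r is the per-snapshot fraction of directed edges
whose reverse edge coexists; weight reciprocity rho compares speeds on the
two directions of each dyad (sum of dyad minima over sum of dyad maxima).
The radius of gyration is the root-mean-square displacement of a node's
trajectory about its centroid (0 for stationary nodes).  Median propagation
speed is taken over all finite edge-speed records across snapshots and
reported as "inst." when every speed is infinite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .core import DataError, SpatioTemporalNetwork, aggregate_graph

__all__ = [
    "NetworkSummary",
    "temporal_correlation",
    "reciprocity",
    "radius_of_gyration",
    "median_speed",
    "summarize",
]

_EARTH_RADIUS_M = 6371008.8  # mean radius, used only for local projection


def temporal_correlation(net: SpatioTemporalNetwork) -> float:
    """Topological temporal correlation C in [0, 1].

    C_v(i) = sum_w a_vw^[i] a_vw^[i+1] / sqrt(k_v^[i] k_v^[i+1]) on the
    unweighted adjacency; terms where either out-degree is zero are
    undefined and skipped.  Averaged over defined nodes within each
    transition, then over transitions with at least one defined node.
    Returns NaN when no term is defined anywhere.
    """
    if net.window.T < 2:
        raise DataError("temporal correlation requires T >= 2")
    per_transition = []
    A_next = net.speed_matrix(1) > 0
    for i in range(1, net.window.T):
        A, A_next = A_next, net.speed_matrix(i + 1) > 0
        k1 = A.sum(axis=1)
        k2 = A_next.sum(axis=1)
        defined = (k1 > 0) & (k2 > 0)
        if not defined.any():
            continue
        overlap = (A & A_next).sum(axis=1)
        c = overlap[defined] / np.sqrt(k1[defined] * k2[defined])
        per_transition.append(float(c.mean()))
    return float(np.mean(per_transition)) if per_transition else math.nan


def reciprocity(net: SpatioTemporalNetwork) -> tuple[float, float]:
    """(topological reciprocity r, weight reciprocity rho), means over snapshots.

    Per snapshot with >= 1 edge: r is the fraction of directed edges whose
    reverse also exists; rho is sum over dyads (unordered pairs with >= 1
    edge) of min(S_vw, S_wv) divided by the sum of max(S_vw, S_wv), with an
    absent direction contributing speed 0.  Infinite speeds are clamped to
    the snapshot's largest finite speed (1 if none), so an all-instantaneous
    snapshot reduces rho to a topological dyad ratio.  Snapshots with no
    edges are skipped; returns (nan, nan) if every snapshot is empty.
    """
    r_vals, rho_vals = [], []
    for snap in net.snapshots:
        if not snap:
            continue
        r_vals.append(sum((w, v) in snap for (v, w) in snap) / len(snap))

        finite = [s for s in snap.values() if math.isfinite(s)]
        clamp = max(finite) if finite else 1.0
        dyads: dict[tuple[str, str], list[float]] = {}
        for (v, w), s in snap.items():
            key = (v, w) if v < w else (w, v)
            dyads.setdefault(key, [0.0, 0.0])
            dyads[key][0 if v < w else 1] = min(s, clamp)
        num = sum(min(a, b) for a, b in dyads.values())
        den = sum(max(a, b) for a, b in dyads.values())
        rho_vals.append(num / den if den > 0 else 0.0)
    if not r_vals:
        return math.nan, math.nan
    return float(np.mean(r_vals)), float(np.mean(rho_vals))


def radius_of_gyration(net: SpatioTemporalNetwork,
                       ) -> tuple[dict[str, float], float]:
    """Per-node radius of gyration and its mean over nodes (length units).

    RMS metric distance of a node's per-snapshot positions from their
    centroid.  With a static embedding every node scores exactly 0.  For the
    geodesic metric the trajectory is first projected to a local
    equirectangular plane about its mean coordinate (adequate for
    system-scale mobility, not for continental trajectories).
    """
    if net.static_positions:
        vals = {v: 0.0 for v in net.nodes}
        return vals, 0.0
    T = net.window.T
    traj = net.positions  # (T, N, k)
    vals: dict[str, float] = {}
    for j, v in enumerate(net.nodes):
        pts = traj[:, j, :]
        if net.metric.kind == "geodesic-ellipsoid":
            lat0, lon0 = pts[:, 0].mean(), pts[:, 1].mean()
            scale = _EARTH_RADIUS_M / net.metric._UNIT_METRES[net.metric.units]
            x = np.radians(pts[:, 1] - lon0) * math.cos(math.radians(lat0))
            y = np.radians(pts[:, 0] - lat0)
            pts = np.column_stack([x, y]) * scale
        centroid = pts.mean(axis=0)
        vals[v] = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean()))
    return vals, float(np.mean(list(vals.values())))


def median_speed(net: SpatioTemporalNetwork) -> float | str:
    """Median over all finite edge-speed records across snapshots.

    Every (edge, snapshot) occurrence counts as one record.  Returns the
    string ``"inst."`` when all speeds are infinite; raises if the network
    has no edges at all.
    """
    speeds = [s for snap in net.snapshots for s in snap.values()]
    if not speeds:
        raise DataError("network has no edges; median speed undefined")
    finite = [s for s in speeds if math.isfinite(s)]
    if not finite:
        return "inst."
    return float(np.median(finite))


@dataclass
class NetworkSummary:
    """Descriptive record of a spatio-temporal network."""

    N: int
    n_aggregate_edges: int
    edge_density: float
    tau: float
    T: int
    duration: float
    temporal_correlation: float
    reciprocity_topological: float
    reciprocity_weight: float
    mean_radius_of_gyration: float
    median_speed: float | str
    fraction_infinite_speed: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(net: SpatioTemporalNetwork) -> NetworkSummary:
    """Compute the full descriptive summary of a network."""
    agg = aggregate_graph(net)
    r, rho = reciprocity(net)
    _, gyr = radius_of_gyration(net)
    speeds = [s for snap in net.snapshots for s in snap.values()]
    frac_inf = (sum(math.isinf(s) for s in speeds) / len(speeds)
                if speeds else 0.0)
    return NetworkSummary(
        N=net.N,
        n_aggregate_edges=agg.graph["n_aggregate_edges"],
        edge_density=agg.graph["edge_density"],
        tau=net.window.tau,
        T=net.window.T,
        duration=net.window.duration,
        temporal_correlation=(temporal_correlation(net)
                              if net.window.T >= 2 else math.nan),
        reciprocity_topological=r,
        reciprocity_weight=rho,
        mean_radius_of_gyration=gyr,
        median_speed=median_speed(net) if speeds else math.nan,
        fraction_infinite_speed=frac_inf,
    )
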