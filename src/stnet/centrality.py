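"""Node-importance measures over spatio-temporal shortest paths.

Temporal in-closeness (TC) is the reciprocal of a node's mean in-distance:
nodes whose in-reachability set reaches them quickly score high.  Path
betweenness (PB) counts, over all ordered source--destination pairs, the
fraction of spatio-temporally shortest paths passing through a node
(endpoints excluded).  Betweenness efficiency (BE) sums, over the pairs
having at least one shortest path through the node, the reciprocal latency
of that pair (in timestep-reciprocal units), so it rewards bridges that
carry *fast* flows.  PTPB is the purely temporal counterpart of PB: the same
computation on a derived network where every edge's speed is infinite and
all minimum-latency paths are counted.  In-/out-degree (ID/OD) are taken on
the unweighted static aggregate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DataError, SpatioTemporalNetwork, aggregate_graph
from .propagation import AllPairsResult, all_pairs

__all__ = [
    "CentralityScores",
    "temporal_in_closeness",
    "path_betweenness",
    "betweenness_efficiency",
    "pure_temporal_path_betweenness",
    "degree_scores",
    "MEASURES",
]


@dataclass
class CentralityScores:
    """node -> score table tagged with the measure and analysis window."""

    measure: str
    window: tuple[int, int]
    scores: dict[str, float]

    def ranking(self) -> list[str]:
        """Nodes in decreasing score order; ties broken by node identifier."""
        return sorted(self.scores, key=lambda v: (-self.scores[v], v))

    def as_array(self, nodes: list[str]) -> np.ndarray:
        return np.array([self.scores[v] for v in nodes])

    def __getitem__(self, node: str) -> float:
        return self.scores[node]


def _ap(net: SpatioTemporalNetwork, window, ap: AllPairsResult | None,
        **kw) -> AllPairsResult:
    return ap if ap is not None else all_pairs(net, window=window, **kw)


def temporal_in_closeness(net: SpatioTemporalNetwork,
                          window: tuple[int, int] | None = None,
                          ap: AllPairsResult | None = None,
                          ) -> CentralityScores:
    """TC_v = 1 / (mean temporal distance of nodes that reach v), in 1/s.

    The in-component of v is the set of nodes with a path to v plus v itself;
    if it is a singleton the mean in-distance is infinite and the score 0.
    """
    ap = _ap(net, window, ap)
    lam = ap.dist_lambda  # seconds, rows = origins
    scores = {}
    for j, v in enumerate(ap.nodes):
        incoming = np.delete(lam[:, j], j)
        finite = incoming[np.isfinite(incoming)]
        if finite.size == 0:
            scores[v] = 0.0
        else:
            ell = float(finite.mean())
            scores[v] = 1.0 / ell if ell > 0 else math.inf
    return CentralityScores("TC", ap.window, scores)


def path_betweenness(net: SpatioTemporalNetwork,
                     window: tuple[int, int] | None = None,
                     ap: AllPairsResult | None = None) -> CentralityScores:
    """PB_v = sum over ordered pairs (w, u) of |sigma_wu(v)| / |sigma_wu|.

    Brandes-style dependency accumulation on each origin's shortest-path DAG;
    endpoints contribute nothing to their own pairs.
    """
    ap = _ap(net, window, ap)
    return CentralityScores("PB", ap.window,
                            _accumulate_pb(ap).copy())


def _accumulate_pb(ap: AllPairsResult) -> dict[str, float]:
    N = len(ap.nodes)
    pb = np.zeros(N)
    for o in range(N):
        arr = ap.arrival[o]
        sig = ap.sigma[o]
        delta = np.zeros(N)
        order = np.argsort(arr)[::-1]  # latest arrivals first
        for w in order:
            if arr[w] < 0 or w == o:
                continue
            coeff = (1.0 + delta[w]) / sig[w]
            preds = ap.sp_mask[o, :, w]
            delta[preds] += sig[preds] * coeff
        delta[o] = 0.0
        pb += delta
    return {v: float(pb[j]) for j, v in enumerate(ap.nodes)}


def betweenness_efficiency(net: SpatioTemporalNetwork,
                           window: tuple[int, int] | None = None,
                           ap: AllPairsResult | None = None,
                           ) -> CentralityScores:
    """BE_v = sum of 1/dist^lambda_wu over pairs (w, u) routed through v.

    A pair counts once no matter how many of its shortest paths use v;
    reciprocal latency is in timestep-reciprocal units, matching the temporal
    efficiency normalisation.
    """
    ap = _ap(net, window, ap)
    N = len(ap.nodes)
    be = np.zeros(N)
    steps = ap.dist_steps
    for o in range(N):
        arr = ap.arrival[o]
        # anc[v, u]: v lies on >= 1 shortest path from origin o to u
        anc = np.zeros((N, N), dtype=bool)
        for u in np.argsort(arr):
            if arr[u] < 0 or u == o:
                continue
            preds = ap.sp_mask[o, :, u]
            anc[:, u] = anc[:, preds].any(axis=1) | preds
        anc[o, :] = False            # endpoints excluded
        np.fill_diagonal(anc, False)
        with np.errstate(divide="ignore"):
            inv = np.where(arr >= 0, 1.0 / steps[o], 0.0)
        inv[o] = 0.0
        inv[~np.isfinite(inv)] = 0.0
        be += anc @ inv
    return CentralityScores(
        "BE", ap.window, {v: float(be[j]) for j, v in enumerate(ap.nodes)})


def _infinite_speed_copy(net: SpatioTemporalNetwork) -> SpatioTemporalNetwork:
    snaps = [{e: math.inf for e in snap} for snap in net.snapshots]
    return net.copy_with_snapshots(snaps)


def pure_temporal_path_betweenness(net: SpatioTemporalNetwork,
                                   window: tuple[int, int] | None = None,
                                   ) -> CentralityScores:
    """PB on the space-agnostic counterpart of the network.

    Every existing edge's speed is set to infinity, so paths are constrained
    only by edge presence and time-ordering; shortest paths are minimum
    latency only (no spatial tie-break: all minimum-latency paths counted).
    """
    derived = _infinite_speed_copy(net)
    ap = all_pairs(derived, window=window, spatial_tiebreak=False)
    return CentralityScores("PTPB", ap.window, _accumulate_pb(ap))


def degree_scores(net: SpatioTemporalNetwork,
                  direction: str = "in") -> CentralityScores:
    """In-degree (ID) or out-degree (OD) on the unweighted static aggregate."""
    if direction not in ("in", "out"):
        raise DataError(f"direction must be 'in' or 'out', got {direction!r}")
    g = aggregate_graph(net)
    deg = g.in_degree if direction == "in" else g.out_degree
    return CentralityScores("ID" if direction == "in" else "OD",
                            (1, net.window.T),
                            {v: float(d) for v, d in deg})


def compute_measure(net: SpatioTemporalNetwork, measure: str,
                    window: tuple[int, int] | None = None,
                    ap: AllPairsResult | None = None) -> CentralityScores:
    """Dispatch by measure tag: TC, PB, BE, PTPB, ID or OD."""
    m = measure.upper()
    if m == "TC":
        return temporal_in_closeness(net, window, ap)
    if m == "PB":
        return path_betweenness(net, window, ap)
    if m == "BE":
        return betweenness_efficiency(net, window, ap)
    if m == "PTPB":
        return pure_temporal_path_betweenness(net, window)
    if m == "ID":
        return degree_scores(net, "in")
    if m == "OD":
        return degree_scores(net, "out")
    raise DataError(f"unknown centrality measure {measure!r}")


MEASURES = ("TC", "PB", "BE", "PTPB", "ID", "OD")
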