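"""Space--time constrained propagation and spatio-temporal shortest paths.

Propagation from an origin node v0 is a discrete-time process over the
snapshot sequence.  Its state is a reachability set K (nodes reached so far)
and an N x N progress matrix P, where P_vw is the physical distance
accumulated so far while propagating directly from v to w.  Stepping from
timestep i-1 to i, for every reached v and unreached w joined by an edge in
snapshot i, progress grows by min(tau * S_vw, q_vw) where q_vw =
max(0, D_vw - P_vw) is the remaining distance; if the edge is absent the
progress resets to zero.  Node w is reached once P_vw >= D_vw for some
reached v.

A spatio-temporal path is a chain of such completed propagations traced
through the process, so every node on a path is reached at its earliest
arrival from the origin, and arrival times strictly increase along the path.
Among the minimum-latency paths to a destination, the spatio-temporally
shortest ones additionally minimise the summed per-hop propagation distance;
all of them share the same latency and spatial length, so temporal distance
(latency, seconds) and spatial distance (length units) are well defined, and
set to infinity for unreachable destinations.

The per-origin engine mirrors the Brandes approach for counting shortest
paths: arrivals define a predecessor DAG, spatial lengths and path counts
sigma follow by dynamic programming in arrival order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import DataError, SpatioTemporalNetwork

__all__ = [
    "PropagationState",
    "SpatioTemporalPath",
    "ShortestPathSummary",
    "AllPairsResult",
    "initial_state",
    "propagation_step",
    "run_propagation",
    "all_pairs",
    "horizon_growth",
]

# Relative tolerance for recognising equal spatial lengths when grouping
# spatio-temporally shortest paths; genuine ties in constructed fixtures are
# exact, ties between unrelated floating-point sums are vanishingly unlikely.
TIE_RTOL = 1e-9
TIE_ATOL = 1e-12


def _spatial_ties(cand: np.ndarray, best: np.ndarray) -> np.ndarray:
    """Boolean mask of candidates equal (to tolerance) to the minimum."""
    return cand <= best + (TIE_RTOL * np.abs(best) + TIE_ATOL)


def _resolve_window(net: SpatioTemporalNetwork,
                    window: tuple[int, int] | None) -> tuple[int, int]:
    if window is None:
        return 1, net.window.T
    start, end = int(window[0]), int(window[1])
    net.window.check_index(start)
    net.window.check_index(end)
    if end < start:
        raise DataError(f"empty window {start}:{end}")
    return start, end


# ---------------------------------------------------------------------------
# Single-origin state and step (the update rule, one timestep at a time)
# ---------------------------------------------------------------------------


@dataclass
class PropagationState:
    """State of one origin's propagation process at the end of a timestep.

    ``reached`` maps node id -> arrival timestep index; ``P`` is the N x N
    progress matrix in metric length units (row = from, column = to);
    ``predecessors`` maps each reached node (except the origin) to the list
    of ``(predecessor, arrival timestep, hop distance)`` triples that
    completed propagation to it at its arrival step.
    """

    origin: str
    start: int
    step: int
    reached: dict[str, int]
    P: np.ndarray
    predecessors: dict[str, list[tuple[str, int, float]]] = field(
        default_factory=dict)

    @property
    def K(self) -> set[str]:
        return set(self.reached)


def initial_state(net: SpatioTemporalNetwork, origin: str,
                  start: int = 1) -> PropagationState:
    """K = {origin}, P all zero, at the window's start timestep."""
    net.window.check_index(start)
    net.node_index(origin)
    return PropagationState(origin=origin, start=start, step=start,
                            reached={origin: start},
                            P=np.zeros((net.N, net.N)))


def propagation_step(state: PropagationState, net: SpatioTemporalNetwork,
                     i: int) -> PropagationState:
    """Advance the propagation process from timestep i-1 to i.

    Progress accumulates for pairs (v reached, w unreached) joined by an edge
    in snapshot i, resets to zero for unreached targets whose edge vanished,
    and is frozen (kept for audit, never re-read) once the target is reached.
    Newly reached nodes record every predecessor whose progress met the
    distance at this step, with the hop distance equal to that progress.
    """
    if i < 2:
        raise DataError(f"propagation steps start at i=2, got {i}")
    net.window.check_index(i)
    if state.step != i - 1:
        raise DataError(f"state is at step {state.step}, cannot advance to {i}")
    if state.P.shape != (net.N, net.N):
        raise DataError("state/network node-set mismatch")

    S = net.speed_matrix(i)
    D = net.distance_matrix(i)
    tau = net.window.tau

    reached = np.zeros(net.N, dtype=bool)
    for v in state.reached:
        reached[net.node_index(v)] = True
    edge = S > 0
    active = reached[:, None] & ~reached[None, :]
    acc = active & edge

    q = np.maximum(0.0, D - state.P)
    with np.errstate(invalid="ignore"):  # inf * tau on instantaneous edges
        inc = np.minimum(tau * S, q)
    P = np.where(acc, state.P + inc,
                 np.where(active & ~edge, 0.0, state.P))

    arr_cond = acc & (P >= D)
    new_nodes = arr_cond.any(axis=0) & ~reached

    new_reached = dict(state.reached)
    preds = {k: list(v) for k, v in state.predecessors.items()}
    for w_idx in np.flatnonzero(new_nodes):
        w = net.nodes[w_idx]
        new_reached[w] = i
        preds[w] = [(net.nodes[v_idx], i, float(P[v_idx, w_idx]))
                    for v_idx in np.flatnonzero(arr_cond[:, w_idx])]
    return PropagationState(origin=state.origin, start=state.start, step=i,
                            reached=new_reached, P=P, predecessors=preds)


# ---------------------------------------------------------------------------
# Paths and per-origin summaries
# ---------------------------------------------------------------------------


@dataclass
class SpatioTemporalPath:
    """A traced path: (node, arrival timestep) pairs plus per-hop distances."""

    sequence: list[tuple[str, int]]
    hop_distances: list[float]
    tau: float

    def __post_init__(self) -> None:
        steps = [s for _, s in self.sequence]
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise DataError("arrival timesteps must strictly increase")
        names = [v for v, _ in self.sequence]
        if len(set(names)) != len(names):
            raise DataError("nodes along a path must be distinct")
        if len(self.hop_distances) != len(self.sequence) - 1:
            raise DataError("need one hop distance per hop")

    @property
    def n(self) -> int:
        """Topological length (number of hops)."""
        return len(self.sequence) - 1

    @property
    def latency(self) -> float:
        """Elapsed time from the start timestep to the final arrival, seconds."""
        return (self.sequence[-1][1] - self.sequence[0][1]) * self.tau

    @property
    def spatial_length(self) -> float:
        return float(sum(self.hop_distances))


@dataclass
class ShortestPathSummary:
    """Per-destination spatio-temporal distances for one origin.

    ``dist_lambda`` is in seconds and ``dist_steps`` in timestep units
    (both measured from the window start, so waiting at the origin counts);
    ``dist_sigma`` is the spatial distance in metric length units; ``sigma``
    counts spatio-temporally shortest paths; ``sp_predecessors`` maps each
    reached node to its ``(predecessor, hop distance)`` pairs restricted to
    the shortest-path DAG.  Unreachable destinations have both distances
    infinite and sigma 0.
    """

    origin: str
    window: tuple[int, int]
    tau: float
    nodes: list[str]
    arrival_step: np.ndarray     # int, -1 if unreached
    dist_lambda: np.ndarray      # seconds
    dist_sigma: np.ndarray       # length units
    sigma: np.ndarray            # shortest-path counts
    sp_predecessors: dict[str, list[tuple[str, float]]]

    @property
    def dist_steps(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.dist_lambda / self.tau

    def reachable(self, w: str) -> bool:
        return self.arrival_step[self.nodes.index(w)] >= 0

    def paths_to(self, w: str) -> list[SpatioTemporalPath]:
        """Enumerate every spatio-temporally shortest path to ``w``."""
        idx = {v: j for j, v in enumerate(self.nodes)}
        if self.arrival_step[idx[w]] < 0:
            return []

        def walk(node: str) -> list[tuple[list[tuple[str, int]], list[float]]]:
            if node == self.origin:
                return [([(node, self.window[0])], [])]
            out = []
            for pred, hop in self.sp_predecessors.get(node, []):
                for seq, hops in walk(pred):
                    out.append((seq + [(node, int(self.arrival_step[idx[node]]))],
                                hops + [hop]))
            return out

        return [SpatioTemporalPath(seq, hops, self.tau)
                for seq, hops in walk(w)]

    def path_to(self, w: str) -> SpatioTemporalPath | None:
        paths = self.paths_to(w)
        return paths[0] if paths else None


# ---------------------------------------------------------------------------
# Batched engine: all origins simulated simultaneously
# ---------------------------------------------------------------------------


def _engine_inputs(net: SpatioTemporalNetwork, start: int, end: int):
    """Precomputed per-step dense arrays (cached on the network object)."""
    cache = getattr(net, "_engine_cache", None)
    if cache is None:
        cache = net._engine_cache = {}
    key = (start, end)
    if key not in cache:
        edges, tauS, dists = [], [], []
        tau = net.window.tau
        for i in range(start + 1, end + 1):
            S = net.speed_matrix(i)
            edges.append(S > 0)
            tauS.append(tau * S)
            dists.append(net.distance_matrix(i))
        cache[key] = (edges, tauS, dists)
    return cache[key]


def _propagate_batch(net: SpatioTemporalNetwork, origin_idx: np.ndarray,
                     start: int, end: int, alive: np.ndarray | None = None):
    """Run the propagation process for a batch of origins.

    Returns ``(arrival, pred_mask, arrival_P)`` where ``arrival[b, w]`` is the
    arrival timestep (-1 unreached), ``pred_mask[b, v, w]`` marks predecessors
    recorded at w's arrival and ``arrival_P[b, v, w]`` the corresponding hop
    distance.  Identical arithmetic to :func:`propagation_step`, vectorised
    over origins; origins are independent, so results do not depend on batch
    composition or order.  ``alive`` (boolean node mask) suppresses every
    edge incident to a dead node, which is arithmetically identical to
    running on the output of ``robustness.deactivate``.
    """
    B, N = len(origin_idx), net.N
    edges, tauS_list, dists = _engine_inputs(net, start, end)
    alive_pairs = None if alive is None else np.outer(alive, alive)

    reached = np.zeros((B, N), dtype=bool)
    reached[np.arange(B), origin_idx] = True
    arrival = np.full((B, N), -1, dtype=np.int64)
    arrival[np.arange(B), origin_idx] = start
    P = np.zeros((B, N, N))
    pred_mask = np.zeros((B, N, N), dtype=bool)
    arrival_P = np.zeros((B, N, N))

    for k, i in enumerate(range(start + 1, end + 1)):
        edge = edges[k] if alive_pairs is None else edges[k] & alive_pairs
        active = reached[:, :, None] & ~reached[:, None, :]
        if not edge.any():
            P *= ~active                       # every active pair resets
            continue
        D = dists[k]
        acc = active & edge[None, :, :]
        q = D[None, :, :] - P
        np.maximum(q, 0.0, out=q)
        np.minimum(q, tauS_list[k], out=q)     # propagation increment
        np.multiply(q, acc, out=q)
        P += q
        active &= ~edge[None, :, :]
        P *= ~active                           # reset where edge vanished
        arr_cond = acc
        arr_cond &= P >= D[None, :, :]
        new = arr_cond.any(axis=1)
        if new.any():
            sel = new[:, None, :] & arr_cond
            pred_mask |= sel
            arrival_P[sel] = P[sel]
            arrival[new & (arrival < 0)] = i
            reached |= new
    return arrival, pred_mask, arrival_P


def _shortest_path_dp(origin_idx: np.ndarray, arrival: np.ndarray,
                      pred_mask: np.ndarray, arrival_P: np.ndarray,
                      start: int, spatial_tiebreak: bool = True):
    """Spatial distances, sigma counts and shortest-path DAG from arrivals.

    Processes nodes in arrival order; every predecessor arrives strictly
    earlier, so values are final when read.  With ``spatial_tiebreak=False``
    (pure temporal analysis) every minimum-latency predecessor is kept and
    counted regardless of spatial length.
    """
    B, N = arrival.shape
    dist_sigma = np.full((B, N), np.inf)
    dist_sigma[np.arange(B), origin_idx] = 0.0
    sigma = np.zeros((B, N))
    sigma[np.arange(B), origin_idx] = 1.0
    sp_mask = np.zeros_like(pred_mask)

    steps = np.unique(arrival[arrival > start])
    for s in steps:
        M = arrival == s                       # (B, N) nodes arriving at s
        if not M.any():
            continue
        use = pred_mask & M[:, None, :]
        cand = np.where(use, dist_sigma[:, :, None] + arrival_P, np.inf)
        best = cand.min(axis=1)
        if spatial_tiebreak:
            tie = _spatial_ties(cand, best[:, None, :]) & use
        else:
            tie = use
        dist_sigma = np.where(M, best, dist_sigma)
        sig_new = np.where(tie, sigma[:, :, None], 0.0).sum(axis=1)
        sigma = np.where(M, sig_new, sigma)
        sp_mask |= tie
    return dist_sigma, sigma, sp_mask


def _summary_from_batch(net: SpatioTemporalNetwork, b: int, origin: str,
                        window: tuple[int, int], arrival, arrival_P,
                        dist_sigma, sigma, sp_mask) -> ShortestPathSummary:
    start = window[0]
    tau = net.window.tau
    arr = arrival[b]
    lam = np.where(arr >= 0, (arr - start) * tau, np.inf)
    sp_preds: dict[str, list[tuple[str, float]]] = {}
    for w_idx in np.flatnonzero(arr >= 0):
        if net.nodes[w_idx] == origin:
            continue
        vs = np.flatnonzero(sp_mask[b, :, w_idx])
        sp_preds[net.nodes[w_idx]] = [
            (net.nodes[v], float(arrival_P[b, v, w_idx])) for v in vs]
    return ShortestPathSummary(
        origin=origin, window=window, tau=tau, nodes=list(net.nodes),
        arrival_step=arr.copy(), dist_lambda=lam,
        dist_sigma=dist_sigma[b].copy(), sigma=sigma[b].copy(),
        sp_predecessors=sp_preds)


def run_propagation(net: SpatioTemporalNetwork, origin: str,
                    window: tuple[int, int] | None = None,
                    record_trace: bool = True,
                    ) -> tuple[list[PropagationState], ShortestPathSummary]:
    """Propagate from one origin over a window; return the trace and summary.

    The trace is the list of :class:`PropagationState` per timestep (K and P
    at each step, starting with the initial state).  Latency is measured from
    the window's start timestep.
    """
    start, end = _resolve_window(net, window)
    o = net.node_index(origin)

    trace: list[PropagationState] = []
    if record_trace:
        state = initial_state(net, origin, start)
        trace.append(state)
        for i in range(start + 1, end + 1):
            state = propagation_step(state, net, i)
            trace.append(state)

    arrival, pred_mask, arrival_P = _propagate_batch(
        net, np.array([o]), start, end)
    dist_sigma, sigma, sp_mask = _shortest_path_dp(
        np.array([o]), arrival, pred_mask, arrival_P, start)
    summary = _summary_from_batch(net, 0, origin, (start, end),
                                  arrival, arrival_P, dist_sigma, sigma,
                                  sp_mask)
    return trace, summary


@dataclass
class AllPairsResult:
    """System-wide connectivity: distances and reachability for all origins.

    Row v of each matrix corresponds to origin node v.  ``dist_lambda`` is in
    seconds, ``dist_steps`` in timestep units, ``dist_sigma`` in length units;
    the diagonal is 0 / reachable.  Per-origin shortest-path structure
    (``sigma``, predecessor DAG) is retained for centrality computations.
    """

    nodes: list[str]
    window: tuple[int, int]
    tau: float
    arrival: np.ndarray          # (N, N) int
    dist_lambda: np.ndarray      # (N, N) seconds
    dist_sigma: np.ndarray       # (N, N) length units
    sigma: np.ndarray            # (N, N) shortest-path counts
    sp_mask: np.ndarray          # (N, N, N): origin, pred, node
    arrival_P: np.ndarray        # (N, N, N) hop distances at arrival

    @property
    def reachability(self) -> np.ndarray:
        return self.arrival >= 0

    @property
    def dist_steps(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.dist_lambda / self.tau

    def summary_for(self, origin: str,
                    net: SpatioTemporalNetwork) -> ShortestPathSummary:
        b = self.nodes.index(origin)
        return _summary_from_batch(net, b, origin, self.window,
                                   self.arrival, self.arrival_P,
                                   self.dist_sigma, self.sigma, self.sp_mask)


def all_pairs(net: SpatioTemporalNetwork,
              window: tuple[int, int] | None = None,
              spatial_tiebreak: bool = True,
              chunk_size: int | None = None,
              alive: np.ndarray | None = None) -> AllPairsResult:
    """Run propagation from every origin (batched; origins independent).

    ``chunk_size`` bounds the number of origins simulated simultaneously
    (memory is O(chunk * N^2)); results are identical for any chunking.
    ``alive`` is an optional boolean node mask: dead nodes keep their rows
    and columns but lose all incident edges, exactly as if the network had
    been passed through ``robustness.deactivate`` first.
    """
    start, end = _resolve_window(net, window)
    N = net.N
    chunk = N if chunk_size is None else max(1, int(chunk_size))

    arrival = np.full((N, N), -1, dtype=np.int64)
    arrival[np.arange(N), np.arange(N)] = start
    dist_sigma = np.full((N, N), np.inf)
    np.fill_diagonal(dist_sigma, 0.0)
    sigma = np.zeros((N, N))
    np.fill_diagonal(sigma, 1.0)
    sp_mask = np.zeros((N, N, N), dtype=bool)
    arrival_P = np.zeros((N, N, N))
    # a dead origin reaches only itself; simulate live origins only
    origins = np.arange(N) if alive is None else np.flatnonzero(alive)
    for lo in range(0, len(origins), chunk):
        idx = origins[lo:lo + chunk]
        arr, pm, aP = _propagate_batch(net, idx, start, end, alive=alive)
        ds, sg, sp = _shortest_path_dp(idx, arr, pm, aP, start,
                                       spatial_tiebreak=spatial_tiebreak)
        arrival[idx] = arr
        dist_sigma[idx] = ds
        sigma[idx] = sg
        sp_mask[idx] = sp
        arrival_P[idx] = aP

    lam = np.where(arrival >= 0, (arrival - start) * net.window.tau, np.inf)
    return AllPairsResult(nodes=list(net.nodes), window=(start, end),
                          tau=net.window.tau, arrival=arrival,
                          dist_lambda=lam, dist_sigma=dist_sigma,
                          sigma=sigma, sp_mask=sp_mask, arrival_P=arrival_P)


def horizon_growth(net: SpatioTemporalNetwork,
                   horizons: list[float]) -> list[tuple[float, float]]:
    """Giant strong component size S as the temporal horizon h grows.

    Each horizon h truncates the observation window to its first
    floor(h / tau) timesteps (at least one); S is computed on the truncated
    window.  Returns (h, S) pairs; S is non-decreasing in h.
    """
    if not horizons:
        raise DataError("empty horizon list")
    from .robustness import strong_components  # late import avoids a cycle

    out = []
    for h in sorted(horizons):
        if h <= 0 or h > net.window.T * net.window.tau + 1e-9:
            raise DataError(f"horizon {h} outside (0, T*tau]")
        steps = max(1, min(net.window.T, int(math.floor(h / net.window.tau))))
        comp = strong_components(net, window=(1, steps))
        out.append((float(h), comp.giant_fraction))
    return out
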