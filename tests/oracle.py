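"""Brute-force reference implementation used only by the test suite.

Everything here is written independently of the library engine: the
propagation process is re-simulated with plain Python dicts directly from
the update rules (progress accumulates by min(tau*S, remaining distance)
while the edge persists, resets when it disappears, freezes once the target
is reached), and paths are enumerated exhaustively instead of counted by
dynamic programming.  Intended for tiny instances (N <= 7, T <= 10).
"""

from __future__ import annotations

import math
from itertools import permutations

TIE_RTOL = 1e-9
TIE_ATOL = 1e-12


def _dist(net, v, w, i):
    coords = net.coords(i)
    a = coords[net.nodes.index(v)]
    b = coords[net.nodes.index(w)]
    return net.metric.distance(a, b)


def simulate_process(net, origin, start, end):
    """Pure-Python propagation from one origin.

    Returns ``(arrival, links)`` where ``arrival`` maps reached node ->
    arrival timestep and ``links`` maps each reached node (except the origin)
    to the list of ``(predecessor, hop distance)`` pairs recorded at its
    arrival step.
    """
    nodes = list(net.nodes)
    tau = net.window.tau
    arrival = {origin: start}
    P = {(v, w): 0.0 for v in nodes for w in nodes if v != w}
    links: dict[str, list[tuple[str, float]]] = {}

    for i in range(start + 1, end + 1):
        snap = net.snapshots[i - 1]
        newP = {}
        for (v, w), p in P.items():
            if w in arrival:
                newP[(v, w)] = p                      # frozen
            elif (v, w) not in snap:
                newP[(v, w)] = 0.0                    # reset
            elif v in arrival:
                s = snap[(v, w)]
                d = _dist(net, v, w, i)
                q = max(0.0, d - p)
                newP[(v, w)] = p + (q if math.isinf(s) else min(tau * s, q))
            else:
                newP[(v, w)] = p                      # source unreached: 0
        newly = {}
        for w in nodes:
            if w in arrival:
                continue
            preds = [(v, newP[(v, w)]) for v in list(arrival)
                     if v != w and (v, w) in snap
                     and newP[(v, w)] >= _dist(net, v, w, i)]
            if preds:
                newly[w] = preds
        for w, preds in newly.items():
            arrival[w] = i
            links[w] = preds
        P = newP
    return arrival, links


def enumerate_traces(origin, links, dest):
    """All spatio-temporal paths (predecessor chains) origin -> dest.

    Each trace is ``(node sequence, hop distances)``.
    """
    if dest == origin:
        return [((origin,), ())]
    out = []
    for pred, hop in links.get(dest, []):
        for seq, hops in enumerate_traces(origin, links, pred):
            out.append((seq + (dest,), hops + (hop,)))
    return out


def shortest_traces(origin, links, dest, spatial_tiebreak=True):
    """Spatio-temporally shortest traces origin -> dest (may be empty)."""
    traces = enumerate_traces(origin, links, dest)
    if not traces or dest == origin:
        return traces
    lengths = [sum(hops) for _, hops in traces]
    if not spatial_tiebreak:
        return traces
    best = min(lengths)
    keep = [t for t, ln in zip(traces, lengths)
            if ln <= best + TIE_RTOL * abs(best) + TIE_ATOL]
    return keep


def oracle_summary(net, origin, start=None, end=None, spatial_tiebreak=True):
    """Distances, path counts and reachability for one origin, brute force."""
    start = 1 if start is None else start
    end = net.window.T if end is None else end
    arrival, links = simulate_process(net, origin, start, end)
    tau = net.window.tau
    out = {}
    for w in net.nodes:
        if w == origin:
            out[w] = {"lambda": 0.0, "sigma_dist": 0.0, "count": 1,
                      "reachable": True}
        elif w not in arrival:
            out[w] = {"lambda": math.inf, "sigma_dist": math.inf, "count": 0,
                      "reachable": False}
        else:
            keep = shortest_traces(origin, links, w, spatial_tiebreak)
            out[w] = {"lambda": (arrival[w] - start) * tau,
                      "sigma_dist": min(sum(h) for _, h in keep),
                      "count": len(keep), "reachable": True}
    return out


def oracle_centralities(net, start=None, end=None, spatial_tiebreak=True):
    """PB and BE for every node by exhaustive shortest-path enumeration."""
    start = 1 if start is None else start
    end = net.window.T if end is None else end
    tau = net.window.tau
    pb = {v: 0.0 for v in net.nodes}
    be = {v: 0.0 for v in net.nodes}
    for origin in net.nodes:
        arrival, links = simulate_process(net, origin, start, end)
        for u in net.nodes:
            if u == origin or u not in arrival:
                continue
            keep = shortest_traces(origin, links, u, spatial_tiebreak)
            latency_steps = arrival[u] - start
            through = set()
            for seq, _ in keep:
                through.update(seq[1:-1])
            for v in through:
                n_through = sum(v in seq[1:-1] for seq, _ in keep)
                pb[v] += n_through / len(keep)
                be[v] += 1.0 / latency_steps
    return pb, be


def _simulate_sequence(net, seq, start, end):
    """Forward-simulate one candidate node sequence hop by hop.

    Each hop accumulates progress from the sequence's own arrival at the
    previous node, independent of the global process.  Returns the final
    arrival timestep or None if some hop never completes inside the window.
    """
    tau = net.window.tau
    arr = start
    for v, w in zip(seq, seq[1:]):
        P = 0.0
        done = None
        for i in range(arr + 1, end + 1):
            snap = net.snapshots[i - 1]
            if (v, w) in snap:
                d = _dist(net, v, w, i)
                s = snap[(v, w)]
                q = max(0.0, d - P)
                P += q if math.isinf(s) else min(tau * s, q)
                if P >= d:
                    done = i
                    break
            else:
                P = 0.0
        if done is None:
            return None
        arr = done
    return arr


def min_latency_by_sequence_enumeration(net, origin, start=None, end=None):
    """Minimum latency per destination over ALL injective node sequences.

    Independent check of the earliest-arrival property: simulating every
    candidate sequence hop by hop can never beat the propagation process.
    Exponential; use with N <= 6.
    """
    start = 1 if start is None else start
    end = net.window.T if end is None else end
    others = [v for v in net.nodes if v != origin]
    best = {v: math.inf for v in net.nodes}
    best[origin] = 0.0
    for r in range(1, len(others) + 1):
        for middle in permutations(others, r):
            seq = (origin,) + middle
            arr = _simulate_sequence(net, seq, start, end)
            if arr is not None:
                lat = (arr - start) * net.window.tau
                best[seq[-1]] = min(best[seq[-1]], lat)
    return best
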