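"""Vulnerability measures, random error and systematic attack simulation.

Network performance is tracked by three quantities.  The giant strong
component size S is the largest set of mutually spatio-temporally reachable
nodes as a fraction of N (computed on the static reachability digraph --- the
affine-graph reduction of the non-transitive path relation).  Temporal
efficiency E^lambda is the mean reciprocal latency over ordered node pairs
with latency in timestep units, so E^lambda = 1 when every pair completes
direct propagation in one timestep and 0 when nothing propagates.  Spatial
efficiency E^sigma is the mean reciprocal spatial distance (length^-1 units).

Deactivating a node removes every edge to or from it in every snapshot while
keeping the node in V, so denominators stay comparable across deactivation
fractions f.  Robustness curves report S and the relative efficiencies
R^lambda(f) = E^lambda(D)/E^lambda and R^sigma(f) = E^sigma(D)/E^sigma,
either under independent Bernoulli(f) node failure (ERR, averaged over
seeded realisations) or under a systematic attack strategy (TC, PB, BE, ID,
OD, PTPB).  PB and BE re-rank after every removal; the other strategies rank
once on the intact network.  Overall attack aggressiveness is summarised by
the area under a robustness curve (lower = more aggressive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import DataError, SpatioTemporalNetwork
from .propagation import AllPairsResult, all_pairs
from . import centrality as _centrality

__all__ = [
    "DeactivationSet",
    "ComponentSummary",
    "RobustnessCurve",
    "deactivate",
    "strong_components",
    "efficiency",
    "random_error_curve",
    "attack_curve",
    "curve_auc",
    "STRATEGIES",
]

STRATEGIES = ("TC", "PB", "BE", "ID", "OD", "PTPB")
_RECOMPUTED = ("PB", "BE")  # greedy strategies: re-rank after each failure


@dataclass(frozen=True)
class DeactivationSet:
    """An ordered set of failed nodes and the fraction of V it covers."""

    nodes: tuple[str, ...]
    n_total: int

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise DataError("duplicate nodes in deactivation set")

    @property
    def fraction(self) -> float:
        return len(self.nodes) / self.n_total


def deactivate(net: SpatioTemporalNetwork,
               nodes: list[str] | tuple[str, ...] | set[str],
               ) -> SpatioTemporalNetwork:
    """Remove every edge incident to the given nodes from every snapshot.

    The node set (and hence N) is unchanged; positions are retained.
    """
    dead = {str(v) for v in nodes}
    unknown = dead - set(net.nodes)
    if unknown:
        raise DataError(f"unknown nodes in deactivation set: {sorted(unknown)}")
    snaps = [{(v, w): s for (v, w), s in snap.items()
              if v not in dead and w not in dead}
             for snap in net.snapshots]
    return net.copy_with_snapshots(snaps)


@dataclass
class ComponentSummary:
    """Strong/weak components of the spatio-temporal reachability relation."""

    giant_strong: set[str]
    weak: list[set[str]]
    n_total: int

    @property
    def giant_fraction(self) -> float:
        """Giant strong component size S."""
        return len(self.giant_strong) / self.n_total

    @property
    def giant_weak_fraction(self) -> float:
        return max(len(c) for c in self.weak) / self.n_total


def strong_components(net: SpatioTemporalNetwork,
                      window: tuple[int, int] | None = None,
                      ap: AllPairsResult | None = None) -> ComponentSummary:
    """Giant strong and weak components of spatio-temporal reachability.

    A strongly connected set contains a spatio-temporal path between every
    ordered pair of its nodes.  Reachability within a finite window is
    non-transitive, so this cannot be read off digraph SCCs; following the
    affine-graph method, an undirected affine graph joins every mutually
    reachable pair and strongly connected sets are exactly its cliques.  The
    giant strong component is a maximum clique of the affine graph (isolated
    nodes are singleton components, so S >= 1/N).  Weak components are the
    connected components of the undirected reachability graph (edge iff
    reachable in either direction).
    """
    if ap is None:
        ap = all_pairs(net, window=window)
    reach = ap.reachability.copy()
    np.fill_diagonal(reach, False)

    mutual = reach & reach.T
    affine = nx.Graph()
    affine.add_nodes_from(ap.nodes)
    src, dst = np.nonzero(np.triu(mutual))
    affine.add_edges_from((ap.nodes[i], ap.nodes[j])
                          for i, j in zip(src, dst))
    giant = max(nx.find_cliques(affine), key=len)

    und = nx.Graph()
    und.add_nodes_from(ap.nodes)
    src, dst = np.nonzero(reach | reach.T)
    und.add_edges_from((ap.nodes[i], ap.nodes[j]) for i, j in zip(src, dst))
    weak = [set(c) for c in nx.connected_components(und)]
    return ComponentSummary(giant_strong=set(giant), weak=weak,
                            n_total=len(ap.nodes))


def efficiency(net: SpatioTemporalNetwork,
               window: tuple[int, int] | None = None,
               kind: str = "temporal",
               ap: AllPairsResult | None = None) -> float:
    """Mean reciprocal spatio-temporal distance over ordered node pairs.

    ``kind="temporal"``: reciprocal latency in timestep units, in [0, 1].
    ``kind="spatial"``: reciprocal spatial distance, units length^-1.
    Unreachable pairs contribute 0.
    """
    if net.N < 2:
        raise DataError("efficiency requires N >= 2")
    if ap is None:
        ap = all_pairs(net, window=window)
    if kind == "temporal":
        dist = ap.dist_steps
    elif kind == "spatial":
        dist = ap.dist_sigma
    else:
        raise DataError(f"kind must be 'temporal' or 'spatial', got {kind!r}")
    n = len(ap.nodes)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


@dataclass
class RobustnessCurve:
    """Per-fraction response of S, R^lambda and R^sigma to node failures."""

    strategy: str
    fractions: np.ndarray
    S: np.ndarray
    R_lambda: np.ndarray
    R_sigma: np.ndarray
    baseline: dict[str, float]
    sd: dict[str, np.ndarray] | None = None
    se: dict[str, np.ndarray] | None = None
    realizations: int = 1
    deactivation_order: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    _MEASURES = {"S": "S", "R_lambda": "R_lambda", "Rλ": "R_lambda",
                 "R_sigma": "R_sigma", "Rς": "R_sigma"}

    def values(self, measure: str) -> np.ndarray:
        try:
            return getattr(self, self._MEASURES[measure])
        except KeyError:
            raise DataError(f"unknown curve measure {measure!r}") from None


def _metrics_from_ap(net: SpatioTemporalNetwork, ap: AllPairsResult,
                     base_lambda: float, base_sigma: float,
                     ) -> tuple[float, float, float]:
    s = strong_components(net, ap=ap).giant_fraction
    rl = efficiency(net, kind="temporal", ap=ap) / base_lambda
    rs = efficiency(net, kind="spatial", ap=ap) / base_sigma
    return s, rl, rs


def _metrics(net: SpatioTemporalNetwork, window, base_lambda: float,
             base_sigma: float,
             alive: np.ndarray | None = None) -> tuple[float, float, float]:
    ap = all_pairs(net, window=window, alive=alive)
    return _metrics_from_ap(net, ap, base_lambda, base_sigma)


def _baselines(net, window):
    ap = all_pairs(net, window=window)
    base_l = efficiency(net, kind="temporal", ap=ap)
    base_s = efficiency(net, kind="spatial", ap=ap)
    if base_l <= 0 or base_s <= 0:
        raise DataError("intact network has zero efficiency; "
                        "relative robustness is undefined")
    s0 = strong_components(net, ap=ap).giant_fraction
    return base_l, base_s, s0, ap


def random_error_curve(net: SpatioTemporalNetwork,
                       window: tuple[int, int] | None = None,
                       fractions: np.ndarray | list[float] | None = None,
                       realizations: int = 100,
                       seed: int | None = None,
                       exact_count: bool = False) -> RobustnessCurve:
    """Response to uniform random failure with probability f per node.

    Each realisation deactivates every node independently with probability f
    (expected f*N failures); ``exact_count=True`` instead removes exactly
    ceil(f*N) uniformly sampled nodes.  Reports mean, standard deviation and
    standard error over realisations for S, R^lambda and R^sigma.
    """
    if realizations < 1:
        raise DataError("realizations must be >= 1")
    fractions = np.asarray(
        [0.0, 0.2, 0.4, 0.6, 0.8, 1.0] if fractions is None else fractions,
        dtype=float)
    if ((fractions < 0) | (fractions > 1)).any():
        raise DataError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base_l, base_s, _, _ = _baselines(net, window)

    means = {k: [] for k in ("S", "R_lambda", "R_sigma")}
    sds = {k: [] for k in means}
    for f in fractions:
        vals = np.empty((realizations, 3))
        for r in range(realizations):
            if exact_count:
                k = math.ceil(f * net.N)
                dead_idx = rng.choice(net.N, size=k, replace=False)
                alive = np.ones(net.N, dtype=bool)
                alive[dead_idx] = False
            else:
                alive = ~(rng.random(net.N) < f)
            vals[r] = _metrics(net, window, base_l, base_s, alive=alive)
        for j, k in enumerate(("S", "R_lambda", "R_sigma")):
            means[k].append(vals[:, j].mean())
            sds[k].append(vals[:, j].std(ddof=1) if realizations > 1 else 0.0)

    sd = {k: np.asarray(v) for k, v in sds.items()}
    se = {k: v / math.sqrt(realizations) for k, v in sd.items()}
    return RobustnessCurve(
        strategy="ERR", fractions=fractions,
        S=np.asarray(means["S"]), R_lambda=np.asarray(means["R_lambda"]),
        R_sigma=np.asarray(means["R_sigma"]), sd=sd, se=se,
        realizations=realizations,
        baseline={"E_lambda": base_l, "E_sigma": base_s},
        metadata={"failure_model": "bernoulli" if not exact_count
                  else "exact_count", "seed": seed})


def _rank(scores: _centrality.CentralityScores,
          alive: list[str]) -> list[str]:
    s = scores.scores
    return sorted(alive, key=lambda v: (-s[v], v))


def attack_curve(net: SpatioTemporalNetwork,
                 window: tuple[int, int] | None = None,
                 strategy: str = "PB",
                 fractions: np.ndarray | list[float] | None = None,
                 ) -> RobustnessCurve:
    """Systematic attack: deactivate nodes in decreasing centrality order.

    TC, ID, OD and PTPB rank once on the intact network; PB and BE re-rank
    on the damaged network after every failure (greedy).  Ties are broken by
    node identifier, so curves are deterministic.  By default the curve is
    recorded at every f = k/N for k = 0..N; a coarser ``fractions`` grid
    records only the nearest-from-below removal counts.
    """
    strategy = strategy.upper()
    if strategy not in STRATEGIES:
        raise DataError(f"unknown attack strategy {strategy!r}; "
                        f"choose from {STRATEGIES}")
    base_l, base_s, s0, ap0 = _baselines(net, window)
    N = net.N

    if fractions is None:
        record_ks = list(range(N + 1))
    else:
        fr = np.asarray(fractions, dtype=float)
        if ((fr < 0) | (fr > 1)).any():
            raise DataError("fractions must lie in [0, 1]")
        record_ks = sorted({int(math.ceil(f * N)) for f in fr})

    greedy = strategy in _RECOMPUTED
    if not greedy:
        scores = _centrality.compute_measure(net, strategy, window, ap=ap0)
        order = _rank(scores, list(net.nodes))

    dead: list[str] = []
    alive_nodes = list(net.nodes)
    alive = np.ones(net.N, dtype=bool)
    record_set = set(record_ks)
    ks, S_vals, Rl_vals, Rs_vals = [], [], [], []
    if 0 in record_set:
        ks.append(0)
        S_vals.append(s0)
        Rl_vals.append(1.0)
        Rs_vals.append(1.0)
    ap = ap0
    for k in range(1, (max(record_ks) + 1) if record_ks else 1):
        if greedy:
            # `ap` reflects the current damage; rank the survivors on it
            scores = _centrality.compute_measure(net, strategy, window, ap=ap)
            target = _rank(scores, alive_nodes)[0]
        else:
            target = order[k - 1]
        dead.append(target)
        alive_nodes.remove(target)
        alive[net.node_index(target)] = False
        if greedy or k in record_set:
            ap = all_pairs(net, window=window, alive=alive)
        if k in record_set:
            s, rl, rs = _metrics_from_ap(net, ap, base_l, base_s)
            ks.append(k)
            S_vals.append(s)
            Rl_vals.append(rl)
            Rs_vals.append(rs)

    return RobustnessCurve(
        strategy=strategy, fractions=np.array(ks, dtype=float) / N,
        S=np.asarray(S_vals), R_lambda=np.asarray(Rl_vals),
        R_sigma=np.asarray(Rs_vals), deactivation_order=dead,
        baseline={"E_lambda": base_l, "E_sigma": base_s},
        metadata={"ranking": "recomputed" if greedy else "intact",
                  "tie_break": "node id"})


def curve_auc(curve: RobustnessCurve, measure: str = "S") -> float:
    """Trapezoidal area under a robustness curve over f in [0, 1].

    If the computed grid does not span [0, 1], the curve is extended by
    holding the nearest computed value constant (recorded in
    ``curve.metadata['auc_extension']``); a lower area means a more
    aggressive failure process.
    """
    y = np.asarray(curve.values(measure), dtype=float)
    f = np.asarray(curve.fractions, dtype=float)
    if f.size < 2:
        raise DataError("AUC needs a curve with >= 2 grid points")
    order = np.argsort(f)
    f, y = f[order], y[order]
    ext = []
    if f[0] > 0:
        f = np.concatenate([[0.0], f])
        y = np.concatenate([[y[0]], y])
        ext.append("left-constant")
    if f[-1] < 1:
        f = np.concatenate([f, [1.0]])
        y = np.concatenate([y, [y[-1]]])
        ext.append("right-constant")
    curve.metadata["auc_extension"] = ext or ["none"]
    return float(np.trapezoid(y, f))
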