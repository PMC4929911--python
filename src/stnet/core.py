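"""Core domain types for time-varying spatially embedded networks.

A spatio-temporal network is a time-ordered sequence of T directed snapshot
graphs over a fixed node set V, where every node occupies a position in a
metric space (possibly moving between snapshots) and every directed edge
(v, w) active in a snapshot carries a physical propagation speed S_vw (a
positive real, or +inf for instantaneous interaction).  Snapshot i covers the
half-open real-time interval [t1 + (i-1)*tau, t1 + i*tau).

This module houses the container types, the two supported metric spaces
(k-dimensional Euclidean and geodesic on the WGS-84 ellipsoid), CSV/JSON
loading and saving, validation, and the unweighted static aggregate view.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "ObservationWindow",
    "MetricSpace",
    "SpatioTemporalNetwork",
    "ValidationReport",
    "build_network",
    "load_network",
    "save_network",
    "distance_matrix",
    "aggregate_graph",
    "validate",
    "vincenty_distance",
]


class DataError(ValueError):
    """Raised when input data violate the network contract."""


# ---------------------------------------------------------------------------
# Observation window and metric spaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObservationWindow:
    """Discrete observation window: T snapshots of duration tau from t1.

    Parameters
    ----------
    t1 : float
        Start time of the first snapshot (seconds; epoch or 0-origin).
    T : int
        Number of snapshots (>= 1).
    tau : float
        Temporal granularity: duration of one snapshot, in seconds (> 0).
    """

    t1: float
    T: int
    tau: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise DataError(f"tau must be > 0, got {self.tau}")
        if self.T < 1:
            raise DataError(f"T must be >= 1, got {self.T}")

    def time_of(self, i: int) -> float:
        """Real start time of 1-based snapshot index ``i``."""
        self.check_index(i)
        return self.t1 + (i - 1) * self.tau

    def check_index(self, i: int) -> None:
        if not 1 <= i <= self.T:
            raise DataError(f"timestep index {i} outside 1..{self.T}")

    @property
    def duration(self) -> float:
        return self.T * self.tau


# WGS-84 ellipsoid constants
_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)


def vincenty_distance(lat1: float, lon1: float, lat2: float, lon2: float,
                      tol: float = 1e-12, max_iter: int = 200) -> float:
    """Geodesic distance in metres between two WGS-84 coordinates.

    Iterative inverse solution on the ellipsoid (Vincenty).  Coordinates are
    decimal degrees.  Returns 0.0 for identical points.  May lose accuracy for
    nearly antipodal pairs, which do not occur in the intended applications
    (intra-system distances).
    """
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - _WGS84_F) * math.tan(phi1))
    U2 = math.atan((1 - _WGS84_F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(max_iter):
        sinLam, cosLam = math.sin(lam), math.cos(lam)
        sin_sigma = math.sqrt((cosU2 * sinLam) ** 2
                              + (cosU1 * sinU2 - sinU1 * cosU2 * cosLam) ** 2)
        if sin_sigma == 0.0:
            return 0.0  # coincident
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cosLam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sinLam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha ** 2
        if cos2_alpha == 0.0:
            cos_2sigma_m = 0.0  # equatorial line
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = _WGS84_F / 16.0 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * _WGS84_F * sin_alpha * (
            sigma + C * sin_sigma * (
                cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m ** 2)))
        if abs(lam - lam_prev) < tol:
            break

    u2 = cos2_alpha * (_WGS84_A ** 2 - _WGS84_B ** 2) / _WGS84_B ** 2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = B * sin_sigma * (
        cos_2sigma_m + B / 4 * (
            cos_sigma * (-1 + 2 * cos_2sigma_m ** 2)
            - B / 6 * cos_2sigma_m * (-3 + 4 * sin_sigma ** 2)
            * (-3 + 4 * cos_2sigma_m ** 2)))
    return _WGS84_B * A * (sigma - delta_sigma)


@dataclass(frozen=True)
class MetricSpace:
    """Physical embedding space with distance function g.

    kind
        ``"euclidean"`` (coordinates in ``units``) or ``"geodesic-ellipsoid"``
        (coordinates are ``lat, lon`` decimal degrees on WGS-84; distances
        converted from metres to ``units``).
    dimension
        Coordinate dimension k (euclidean only; geodesic is always 2).
    units
        Length unit label, ``"m"`` or ``"km"``.
    """

    kind: str = "euclidean"
    dimension: int = 2
    units: str = "m"

    _UNIT_METRES = {"m": 1.0, "km": 1000.0}

    def __post_init__(self) -> None:
        if self.kind not in ("euclidean", "geodesic-ellipsoid"):
            raise DataError(f"unknown metric kind {self.kind!r}")
        if self.units not in self._UNIT_METRES:
            raise DataError(f"unknown length unit {self.units!r}")
        if self.kind == "geodesic-ellipsoid" and self.dimension != 2:
            raise DataError("geodesic metric requires 2-D (lat, lon) coordinates")
        if self.dimension < 1:
            raise DataError("dimension must be >= 1")

    def distance(self, a: np.ndarray, b: np.ndarray) -> float:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if self.kind == "euclidean":
            return float(np.linalg.norm(a - b))
        metres = vincenty_distance(a[0], a[1], b[0], b[1])
        return metres / self._UNIT_METRES[self.units]

    def pairwise(self, coords: np.ndarray) -> np.ndarray:
        """N x N symmetric distance matrix for an (N, k) coordinate array."""
        coords = np.asarray(coords, dtype=float)
        n = coords.shape[0]
        if self.kind == "euclidean":
            diff = coords[:, None, :] - coords[None, :, :]
            return np.sqrt((diff ** 2).sum(axis=-1))
        out = np.zeros((n, n))
        scale = self._UNIT_METRES[self.units]
        for i in range(n):
            for j in range(i + 1, n):
                d = vincenty_distance(coords[i, 0], coords[i, 1],
                                      coords[j, 0], coords[j, 1]) / scale
                out[i, j] = out[j, i] = d
        return out


# ---------------------------------------------------------------------------
# The network container
# ---------------------------------------------------------------------------


@dataclass
class SpatioTemporalNetwork:
    """A directed time-varying network embedded in a metric space.

    Attributes
    ----------
    nodes
        Ordered list of N node identifiers (strings); identical in every
        snapshot.
    positions
        Either an (N, k) array (static embedding) or a (T, N, k) array of
        per-snapshot trajectories.
    metric
        The :class:`MetricSpace` supplying the distance function g.
    snapshots
        List of length T; element i-1 maps directed edge ``(source, target)``
        (node id strings) to its propagation speed in ``units``/second,
        positive or ``math.inf``.  Absence of a key means no edge (speed 0).
    window
        The :class:`ObservationWindow` (t1, T, tau).
    """

    nodes: list[str]
    positions: np.ndarray
    metric: MetricSpace
    snapshots: list[dict[tuple[str, str], float]]
    window: ObservationWindow

    _node_index: dict[str, int] = field(default=None, repr=False, compare=False)
    _dist_cache: dict = field(default_factory=dict, repr=False, compare=False)
    _speed_cache: list = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = [str(v) for v in self.nodes]
        self.positions = np.asarray(self.positions, dtype=float)
        self._node_index = {v: i for i, v in enumerate(self.nodes)}
        if len(self._node_index) != len(self.nodes):
            raise DataError("duplicate node identifiers")
        if len(self.snapshots) != self.window.T:
            raise DataError(
                f"{len(self.snapshots)} snapshots but window.T={self.window.T}")
        if self.static_positions:
            if self.positions.shape != (self.N, self.metric.dimension):
                raise DataError("static positions must have shape (N, k)")
        elif self.positions.shape != (self.window.T, self.N,
                                      self.metric.dimension):
            raise DataError("trajectories must have shape (T, N, k)")
        self._check_edges()

    def _check_edges(self) -> None:
        for i, snap in enumerate(self.snapshots, start=1):
            for (v, w), s in snap.items():
                if v not in self._node_index or w not in self._node_index:
                    raise DataError(f"unknown node in edge ({v}, {w}) at t={i}")
                if v == w:
                    raise DataError(f"self-edge at node {v}, t={i}")
                if not (s > 0):  # rejects 0, negatives and NaN
                    raise DataError(
                        f"non-positive speed {s} on edge ({v}, {w}) at t={i}")

    # -- basic views --------------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.nodes)

    @property
    def static_positions(self) -> bool:
        return self.positions.ndim == 2

    def node_index(self, node: str) -> int:
        try:
            return self._node_index[node]
        except KeyError:
            raise DataError(f"unknown node {node!r}") from None

    def coords(self, i: int) -> np.ndarray:
        """(N, k) coordinate array during snapshot i (1-based)."""
        self.window.check_index(i)
        return self.positions if self.static_positions else self.positions[i - 1]

    def position(self, node: str, i: int) -> np.ndarray:
        return self.coords(i)[self.node_index(node)]

    def distance_matrix(self, i: int) -> np.ndarray:
        """Pairwise physical distance matrix D^[t_i]; cached per timestep."""
        self.window.check_index(i)
        key = 0 if self.static_positions else i
        if key not in self._dist_cache:
            self._dist_cache[key] = self.metric.pairwise(self.coords(i))
        return self._dist_cache[key]

    def speed_matrix(self, i: int) -> np.ndarray:
        """Dense N x N speed matrix S^[t_i] (0 where no edge); cached."""
        self.window.check_index(i)
        if self._speed_cache is None:
            self._speed_cache = [None] * self.window.T
        if self._speed_cache[i - 1] is None:
            S = np.zeros((self.N, self.N))
            for (v, w), s in self.snapshots[i - 1].items():
                S[self._node_index[v], self._node_index[w]] = s
            self._speed_cache[i - 1] = S
        return self._speed_cache[i - 1]

    def copy_with_snapshots(
            self, snapshots: list[dict[tuple[str, str], float]]
    ) -> "SpatioTemporalNetwork":
        return SpatioTemporalNetwork(
            nodes=list(self.nodes), positions=self.positions.copy(),
            metric=self.metric, snapshots=snapshots, window=self.window)

    def equals(self, other: "SpatioTemporalNetwork") -> bool:
        """Field-by-field equality (used by round-trip checks)."""
        return (self.nodes == other.nodes
                and self.positions.shape == other.positions.shape
                and np.array_equal(self.positions, other.positions)
                and self.metric == other.metric
                and self.window == other.window
                and self.snapshots == other.snapshots)


def build_network(nodes: Sequence[str],
                  positions: Mapping[str, Sequence[float]] | np.ndarray,
                  snapshots: Sequence[Mapping[tuple[str, str], float]],
                  window: ObservationWindow,
                  metric: MetricSpace | None = None) -> SpatioTemporalNetwork:
    """Convenience constructor accepting a node->coordinate mapping."""
    nodes = [str(v) for v in nodes]
    if isinstance(positions, Mapping):
        positions = np.array([positions[v] for v in nodes], dtype=float)
    else:
        positions = np.asarray(positions, dtype=float)
    if metric is None:
        metric = MetricSpace(dimension=positions.shape[-1])
    snaps = [dict(s) for s in snapshots]
    return SpatioTemporalNetwork(nodes=nodes, positions=positions,
                                 metric=metric, snapshots=snaps, window=window)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------
#
# nodes file       CSV  node_id,x,y[,z]              (static embedding)
# trajectory file  CSV  t,node_id,x,y[,z]            (per-snapshot positions;
#                       missing (node, t) rows inherit the node's most recent
#                       position — last observation carried forward)
# edges file       CSV  t,source,target,speed        (speed in unit/s; "inf"
#                       parses to +infinity); t in 1..T
# meta file        JSON {"tau": .., "T": .., "t1": ..,
#                       "metric": {"kind": .., "dimension": .., "units": ..}}
#
# Geodesic coordinates are given as lat,lon decimal degrees (columns x=lat,
# y=lon) on WGS-84.


def _meta_from_dict(meta: Mapping) -> tuple[ObservationWindow, MetricSpace]:
    try:
        window = ObservationWindow(t1=float(meta.get("t1", 0.0)),
                                   T=int(meta["T"]), tau=float(meta["tau"]))
    except KeyError as exc:
        raise DataError(f"meta missing required key {exc}") from None
    m = meta.get("metric", {})
    metric = MetricSpace(kind=m.get("kind", "euclidean"),
                         dimension=int(m.get("dimension", 2)),
                         units=m.get("units", "m"))
    return window, metric


def load_network(nodes_table: str | Path, edges_table: str | Path,
                 meta: str | Path | Mapping,
                 undirected_edges: bool = False) -> SpatioTemporalNetwork:
    """Load a spatio-temporal network from the standard CSV/JSON files.

    ``undirected_edges=True`` expands every edge record into the two directed
    edges (for source data such as phone calls that are inherently
    bidirectional).
    """
    if not isinstance(meta, Mapping):
        with open(meta) as fh:
            meta = json.load(fh)
    window, metric = _meta_from_dict(meta)

    ndf = pd.read_csv(nodes_table, dtype={"node_id": str},
                      float_precision="round_trip")
    coord_cols = [c for c in ("x", "y", "z") if c in ndf.columns]
    if not coord_cols or "node_id" not in ndf.columns:
        raise DataError("nodes table needs node_id and coordinate columns")
    k = len(coord_cols)
    if k != metric.dimension:
        raise DataError(f"{k} coordinate columns but metric dimension "
                        f"{metric.dimension}")

    if "t" in ndf.columns:  # trajectory table
        nodes = sorted(ndf["node_id"].unique())
        idx = {v: j for j, v in enumerate(nodes)}
        pos = np.full((window.T, len(nodes), k), np.nan)
        for row in ndf.itertuples(index=False):
            t = int(row.t)
            window.check_index(t)
            pos[t - 1, idx[row.node_id]] = [getattr(row, c) for c in coord_cols]
        # last observation carried forward; leading gaps backfilled from the
        # first observation (a node with no observation at all is an error)
        for j, v in enumerate(nodes):
            col = pos[:, j, :]
            if np.isnan(col).all():
                raise DataError(f"node {v} has no position at any timestep")
            seen = ~np.isnan(col[:, 0])
            first = int(np.argmax(seen))
            col[:first] = col[first]
            for t in range(first + 1, window.T):
                if np.isnan(col[t, 0]):
                    col[t] = col[t - 1]
        positions = pos
    else:
        if ndf["node_id"].duplicated().any():
            raise DataError("duplicate node_id in nodes table")
        nodes = list(ndf["node_id"])
        positions = ndf[coord_cols].to_numpy(dtype=float)

    node_set = set(nodes)
    edf = pd.read_csv(edges_table, dtype={"source": str, "target": str},
                      float_precision="round_trip")
    snapshots: list[dict[tuple[str, str], float]] = [
        {} for _ in range(window.T)]
    for row in edf.itertuples(index=False):
        t = int(row.t)
        if not 1 <= t <= window.T:
            raise DataError(f"edge timestep {t} outside 1..{window.T}")
        if row.source not in node_set or row.target not in node_set:
            raise DataError(
                f"unknown node id in edge ({row.source}, {row.target})")
        speed = float(row.speed)
        if not speed > 0:
            raise DataError(f"non-positive speed {row.speed} at t={t}")
        pairs = [(row.source, row.target)]
        if undirected_edges:
            pairs.append((row.target, row.source))
        for pair in pairs:
            if pair in snapshots[t - 1] and not undirected_edges:
                raise DataError(f"duplicate directed edge {pair} at t={t}")
            snapshots[t - 1][pair] = speed

    metric = MetricSpace(kind=metric.kind, dimension=k, units=metric.units)
    return SpatioTemporalNetwork(nodes=list(nodes), positions=positions,
                                 metric=metric, snapshots=snapshots,
                                 window=window)


def save_network(net: SpatioTemporalNetwork, out_dir: str | Path) -> dict:
    """Write nodes/edges/meta files; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coord_cols = ["x", "y", "z"][: net.metric.dimension]

    nodes_path = out / "nodes.csv"
    if net.static_positions:
        rows = [[v, *(repr(float(c)) for c in net.positions[j])]
                for j, v in enumerate(net.nodes)]
        pd.DataFrame(rows, columns=["node_id", *coord_cols]).to_csv(
            nodes_path, index=False)
    else:
        rows = [[t, v, *(repr(float(c)) for c in net.positions[t - 1, j])]
                for t in range(1, net.window.T + 1)
                for j, v in enumerate(net.nodes)]
        pd.DataFrame(rows, columns=["t", "node_id", *coord_cols]).to_csv(
            nodes_path, index=False)

    edges_path = out / "edges.csv"
    erows = [[t, v, w, "inf" if math.isinf(s) else repr(float(s))]
             for t in range(1, net.window.T + 1)
             for (v, w), s in sorted(net.snapshots[t - 1].items())]
    pd.DataFrame(erows, columns=["t", "source", "target", "speed"]).to_csv(
        edges_path, index=False)

    meta_path = out / "meta.json"
    meta = {"tau": net.window.tau, "T": net.window.T, "t1": net.window.t1,
            "metric": {"kind": net.metric.kind,
                       "dimension": net.metric.dimension,
                       "units": net.metric.units}}
    meta_path.write_text(json.dumps(meta, indent=1))
    return {"nodes": nodes_path, "edges": edges_path, "meta": meta_path}


# ---------------------------------------------------------------------------
# Aggregate view and validation
# ---------------------------------------------------------------------------


def distance_matrix(net: SpatioTemporalNetwork, i: int) -> np.ndarray:
    """Pairwise physical distance matrix D^[t_i] (module-level alias)."""
    return net.distance_matrix(i)


def aggregate_graph(net: SpatioTemporalNetwork) -> nx.DiGraph:
    """Unweighted static aggregate: (v, w) present iff active in >= 1 snapshot.

    The graph carries ``n_aggregate_edges`` and ``edge_density``
    (|E*| / (N (N-1))) as graph attributes.
    """
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for snap in net.snapshots:
        g.add_edges_from(snap.keys())
    n = net.N
    g.graph["n_aggregate_edges"] = g.number_of_edges()
    g.graph["edge_density"] = (g.number_of_edges() / (n * (n - 1))
                               if n > 1 else 0.0)
    return g


@dataclass
class ValidationReport:
    """Findings from :func:`validate`; fails iff any error-severity entry."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, severity: str, code: str, message: str) -> None:
        self.entries.append((severity, code, message))

    @property
    def passed(self) -> bool:
        return not any(sev == "error" for sev, _, _ in self.entries)

    @property
    def warnings(self) -> list[tuple[str, str, str]]:
        return [e for e in self.entries if e[0] == "warning"]

    def __str__(self) -> str:
        if not self.entries:
            return "OK: no findings"
        return "\n".join(f"[{sev}] {code}: {msg}"
                         for sev, code, msg in self.entries)


def validate(net: SpatioTemporalNetwork) -> ValidationReport:
    """Check network invariants; never raises, findings go in the report.

    Errors: co-located node pairs in any snapshot (nodes are physical
    entities and cannot share a location).  Warnings: temporal granularity
    too coarse — when the minimum direct propagation duration min D/S over
    all finite-speed edge records is smaller than tau, the discrete process
    under-samples the system's dynamics (completed propagations are rounded
    up to a whole timestep).
    """
    report = ValidationReport()

    steps = [1] if net.static_positions else range(1, net.window.T + 1)
    for i in steps:
        coords = net.coords(i)
        _, inverse, counts = np.unique(coords.round(12), axis=0,
                                       return_inverse=True,
                                       return_counts=True)
        if (counts > 1).any():
            dup_groups = np.flatnonzero(counts > 1)
            for gidx in dup_groups:
                names = [net.nodes[j]
                         for j in np.flatnonzero(inverse == gidx)]
                report.add("error", "co-located-nodes",
                           f"nodes {names} share a location at t={i}")

    min_duration = math.inf
    for i in range(1, net.window.T + 1):
        D = net.distance_matrix(i)
        for (v, w), s in net.snapshots[i - 1].items():
            if math.isinf(s):
                continue
            d = D[net.node_index(v), net.node_index(w)]
            if d > 0:
                min_duration = min(min_duration, d / s)
    if min_duration < net.window.tau:
        report.add(
            "warning", "granularity-undersampling",
            f"minimum direct propagation duration min D/S = "
            f"{min_duration:.6g} s is smaller than tau = {net.window.tau} s; "
            "the representation under-samples the temporal dynamics")
    return report
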