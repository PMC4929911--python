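# Methods

This note records the model implemented by `stnet`, the conventions and
numerical choices it makes, what the synthetic generators do and do not
emulate, and known limitations. Symbols follow the README: snapshots
`G[t1..tT]`, granularity `τ`, distance matrices `D[t]`, speed matrices
`S[t]`, reachability set `K[t]`, progress matrix `P[t]`.

## Representation

A network holds a fixed, ordered node set; per-snapshot directed edges with
strictly positive (possibly infinite) speeds; and either one static
coordinate per node or a `(T, N, k)` trajectory array. Snapshot `i`
(1-based) covers real time `[t1 + (i−1)τ, t1 + iτ)`. Two metric spaces are
supported: k-dimensional Euclidean, and geodesic on the WGS-84 ellipsoid
with coordinates as `lat, lon` decimal degrees. Geodesic distances use an
iterative Vincenty inverse solution implemented in `core.py` and verified
against an independent geodesic library to sub-metre agreement; accuracy
degrades only near antipodal pairs, which intra-system distances do not
approach. Speeds are in (length unit)/second; `τ` in seconds; the literal
`inf` in an edges file denotes instantaneous interaction.

Trajectory tables may omit `(node, t)` rows; missing positions inherit the
node's most recent earlier observation (and the first observation is
back-filled to the window start). A node with no position at all is an
error, as are duplicate directed edges within a snapshot, self-edges,
non-positive speeds and unknown node ids. Two nodes may never share a
location (they are physical entities); co-location is a validation error.

### Granularity diagnostics

`validate` warns when the minimum direct propagation duration over all
finite-speed edge records, `min_{t,v,w} D_vw[t] / S_vw[t]`, is smaller than
`τ`: some direct propagation then completes inside a fraction of one window
and the discrete process rounds its duration up to a whole timestep — the
temporal dynamics are under-sampled. (The check is a duration, `D/S`;
a product `D·S` has no time dimension, so the duration form is used.)

## Propagation and path semantics

The update rule is exactly the one given in the README. Three conventions
deserve explicit statement:

- **One hop per timestep, even at infinite speed.** A node reached at step
  `i` can begin forwarding no earlier than step `i+1`, because arrivals at
  step `i` are only granted via nodes already in `K[t_{i−1}]`. Instantaneous
  contact cascades therefore advance one hop per timestep.
- **Progress freezing.** Once `w` enters `K`, all `P_·w` entries stop
  updating. They are retained for inspection but no later computation reads
  them; this avoids undefined semantics for progress toward already-reached
  targets.
- **Paths are traces of the process.** A spatio-temporal path is a chain of
  completed propagations in which every node is reached at its earliest
  arrival from the origin. Hypothetical routes that linger at an
  intermediate node later than its earliest arrival are not paths of this
  model; consequently every prefix of a path is itself a valid trace, the
  predecessor relation is a DAG ordered by arrival step, and Brandes-style
  dynamic programming over that DAG counts exactly the model's shortest
  paths. The test suite's brute-force oracle enumerates predecessor chains
  exhaustively and, separately, simulates raw node sequences hop-by-hop to
  confirm that no sequence can beat the engine's latencies.

Latency is measured from the *window start*, not from the origin's first
outgoing edge: waiting at the origin counts, per the definition of latency
as `t'_arr − t1`. Among minimum-latency paths, spatial length breaks ties;
all spatio-temporally shortest paths to a destination share one latency and
one spatial length, so `dist^λ` and `dist^ς` are well defined. Both are
`inf` for unreachable pairs. The per-hop distance recorded at arrival is
the progress value, which with moving nodes can differ from the
instantaneous separation; with static positions it never exceeds it.

Spatial-length ties are recognised with relative tolerance `1e-9` (absolute
`1e-12`). Constructed fixtures tie exactly; accidental ties between
unrelated floating-point sums are vanishingly rare at these scales.

The engine simulates all origins in one vectorised batch (optionally
chunked; results are bit-identical for any chunking and to the step-by-step
single-origin routine). Node deactivation can be applied either by
materialising a new network (`deactivate`) or by passing a boolean `alive`
mask to `all_pairs`, which suppresses edges incident to dead nodes without
copying; the two are arithmetically identical and tested as such.

## Centralities

- **TC** (temporal in-closeness): `1/ℓ_v`, with `ℓ_v` the mean `dist^λ_wv`
  in seconds over the nodes that reach `v`. The in-component is taken as
  the full in-reachability set of `v` plus `v` itself, which keeps `ℓ_v`
  well defined for every node; a node nobody reaches scores 0.
- **PB** (path betweenness): pair terms `|σ_wu(v)|/|σ_wu|` with endpoints
  excluded (`v ∉ {w, u}`), the standard betweenness convention.
- **BE** (betweenness efficiency): each source–destination pair routed
  through `v` contributes `1/dist^λ_wu` once, however many of its shortest
  paths use `v`; reciprocal latencies are in timestep units so terms match
  the efficiency normalisation (a converter to s⁻¹ is a division by `τ`).
- **PTPB**: PB recomputed on a derived network with every existing edge's
  speed set to `inf`; the spatial tie-break is disabled so all
  minimum-latency paths are counted (space-agnostic temporal betweenness).
- **ID/OD**: degrees on the unweighted static aggregate (union of snapshot
  edge sets).

## Vulnerability and robustness

Reachability within a finite window is non-symmetric and, importantly,
**non-transitive** — a path into `w` arriving late does not compose with a
path out of `w` that must start at the window's beginning. A strongly
connected set therefore cannot be read off digraph SCCs; it is a set with
spatio-temporal paths between all ordered pairs, i.e. a clique of the
undirected *affine graph* joining mutually reachable pairs. The giant
strong component size `S` is the maximum clique of that graph divided by
`N` (Bron–Kerbosch enumeration; mutual-reachability graphs of these systems
are near-clustered, so this is fast in practice). Weak components are
connected components of the undirected either-direction reachability graph.

Temporal efficiency uses latencies in timestep units, so `E^λ ∈ [0, 1]`
with 1 reached exactly when every ordered pair completes direct propagation
in one step, and unreachable pairs contribute 0. Spatial efficiency is the
literal mean reciprocal spatial distance (units length⁻¹); a
straight-line-ratio normalisation (unitless) is deliberately *not* the
default, since the literal form is what the relative measure `R^ς` divides
out.

Deactivating a node removes all its incident edges in every snapshot but
keeps the node, so `N`, and hence the denominators of `S`, `E^λ` and `E^ς`,
stay comparable across deactivation fractions. Under nested deactivation
sets, `E^λ` and `S` are non-increasing (removals only destroy paths or
delay arrivals); `E^ς` is not claimed monotone, because forced re-routing
can change spatial lengths in either direction.

Random error draws independent Bernoulli(`f`) failures per node (expected
`f·N` failures), with an `exact_count` option removing exactly `⌈fN⌉`
sampled nodes; realizations are driven by a single seeded generator and
reported as mean, standard deviation and standard error. Attacks deactivate
in decreasing centrality order: TC, ID, OD and PTPB rank once on the intact
network; PB and BE re-rank on the damaged network after every removal
(greedy), since shortest paths shift as the network degrades. Ties are
broken by node identifier so attack curves are fully deterministic. Attack
curves are recorded at every `f = k/N` by default; a user grid records the
nearest `⌈fN⌉` removal counts.

The area under a robustness curve is computed by the trapezoidal rule over
`f ∈ [0, 1]`; if the computed grid stops short of either endpoint the curve
is extended by holding the nearest computed value constant, and the
extension choice is recorded in the curve metadata.

## Descriptive statistics

- **Temporal correlation** `C`: per node and consecutive snapshot pair, the
  cosine overlap of unweighted out-neighbourhoods,
  `Σ_w a[i] a[i+1] / sqrt(k[i] k[i+1])`; terms with either degree zero are
  undefined and skipped; defined terms are averaged over nodes within a
  transition and then over transitions. A static topology gives exactly 1;
  disjoint consecutive edge sets give 0; independent on/off edges with
  activity `p` give ≈ `p`.
- **Reciprocity**: per snapshot, topological `r` is the fraction of directed
  edges whose reverse coexists; weight reciprocity `ρ` is `Σ min / Σ max`
  of the two directional speeds over dyads with at least one edge (absent
  direction = 0). Infinite speeds are clamped to the snapshot's largest
  finite speed so the sums stay finite; a snapshot with only infinite
  speeds reduces `ρ` to a topological dyad ratio. Means are over non-empty
  snapshots. These are standard-literature definitions, stated here so
  results are auditable; alternatives can be swapped in.
- **Radius of gyration**: RMS metric distance of a node's per-snapshot
  positions from their centroid; exactly 0 for static embeddings. Geodesic
  trajectories are first projected to a local equirectangular plane about
  the trajectory's mean coordinate — adequate for system-scale mobility,
  not for continental-scale trajectories.
- **Median speed**: median over all finite `(edge, snapshot)` speed
  records; reported as `"inst."` when every speed is infinite, alongside
  the fraction of infinite-speed records.

## Synthetic generators

All generators are bit-reproducible under a fixed seed and their outputs
pass validation. They emulate the *structure* of their real counterparts —
schedule periodicity, speed heterogeneity, static wiring, instantaneous
contacts — but not empirically calibrated degree distributions, geography
or demand patterns, so conclusions from passing tests are about the
correctness of the machinery, not about any particular real system.

- `scheduled_lines_stn`: chains radiating from a shared hub (or one ring);
  consecutive stations joined bidirectionally, active during the first
  `duty` of every `period` timesteps with per-line phase offsets (service
  gaps emulate night closures: reachability growth plateaus during a gap).
  Defaults (4 lines × 10 stations + hub, 800 m spacing, 10 m/s, `τ` = 60 s,
  T = 40, duty 9/12) give inter-station transit of 1–2 steps, a metro-like
  scale. A seed jitters speeds (±15%) and offsets across ensemble members.
- `random_geometric_stn`: uniform nodes in a square, candidate directed
  edges within a radius, each active independently per snapshot with
  probability `p`; per-edge lognormal speeds (median 5 m/s by default), an
  `inf_prob` share instantaneous.
- `connectome_like_stn`: static wiring over 2-D positions at small-organism
  scale (1.2 × 0.2 mm); each directed connection is labelled electrical /
  chemical / both and assigned a direct signalling delay from a
  type-specific sub-range of 10–30 ms (electrical fastest), the speed being
  distance/delay; `τ` = 10 ms.
- `contact_stn`: Gaussian random-walk trajectories with intermittent
  bidirectional infinite-speed contacts (communication-log style).
- Deterministic fixtures: the two-city link (150 km, 200 km/h, 15-minute
  windows — progress 50 km per step, arrival after 3 steps), the five-node
  example with a repeatedly failing branch, and the equal-PB/different-BE
  bridge pair.

## Problem sizes in the shipped analyses

The test-suite ensemble study uses 20 scheduled-lines networks of 41
stations and 40 snapshots, random-error curves on a 6-point fraction grid
{0, 0.2, 0.4, 0.6, 0.8, 1} with 200 Bernoulli realizations per point, and
full-resolution (per-removal) PB and BE attack curves; this grid is the
package's default for ensemble studies and reproduces the attack-versus-
error ordering stably. Exhaustive-oracle equivalence is checked on 200
random instances with N ≤ 7 and T ≤ 10, where brute-force path enumeration
is exact and cheap.

## Known limitations

- Continuous-time, event-based semantics are out of scope: everything is
  quantised to `τ`, and a completed propagation is always charged a whole
  number of timesteps (see the granularity warning above).
- Multi-hop cascades within a single timestep do not occur even at infinite
  speed (one hop per step, by the update rule).
- Maximum-clique extraction is exponential in the worst case; it is fast on
  the near-clustered affine graphs these systems produce, but adversarial
  reachability structures could slow it.
- The greedy PB/BE attacks recompute all-pairs propagation after every
  removal: O(N · T · N²) per removal step, practical to a few hundred
  nodes.
- Spatial efficiency is unit-bearing (length⁻¹); comparing `E^ς` across
  networks embedded at different scales requires the relative measure
  `R^ς`, not raw values.
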