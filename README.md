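# stnet — spatio-temporal network analysis

`stnet` analyses **time-varying, spatially embedded networks**: systems such
as metro and rail timetables, flight networks, nervous systems and mobile
contact networks, in which edges switch on and off over time *and*
interaction between nodes is non-instantaneous because it is constrained by
physical distance and a finite propagation speed. It is aimed at researchers
in urban analytics, transport science, network neuroscience and network
science generally who want reachability, centrality and robustness results
that respect both the temporal and the spatial structure of their system.

## The model

A network is a sequence of `T` directed snapshot graphs `G[t]` over a fixed
node set `V` (`N = |V|`), each covering a window of duration `τ` (the
temporal granularity). Every node has a position in a metric space
(k-dimensional Euclidean, or WGS-84 geodesic), giving a distance matrix
`D[t]`; every edge `(v, w)` active in a snapshot carries a propagation speed
`S_vw[t] > 0` (or `inf` for instantaneous interaction, e.g. a phone call).

Connectivity is defined by a **constrained propagation process** from an
origin `v0`, tracked by a reachability set `K[t]` (initially `{v0}`) and a
progress matrix `P[t]` (initially zero). Stepping into timestep `t_i`, for
every reached `v` and unreached `w` joined by an edge,

    P_vw[t_i] = P_vw[t_i-1] + min( τ·S_vw[t_i],  q_vw[t_i] ),
    q_vw[t_i] = max( 0,  D_vw[t_i] − P_vw[t_i-1] ),

while `P_vw` resets to 0 whenever the edge is absent. Node `w` is reached
once `P_vw[t_i] ≥ D_vw[t_i]` for some reached `v`:

    K[t_i] = K[t_i-1] ∪ { w | ∃v : P_vw[t_i] ≥ D_vw[t_i] }.

Tracing the process yields **spatio-temporal paths** with a latency
(arrival time minus window start) and a spatial length (sum of per-hop
propagation distances). A *spatio-temporally shortest* path has minimum
latency, then minimum spatial length; this defines the temporal distance
`dist^λ_vw` and spatial distance `dist^ς_vw` (both `inf` if unreachable).

On top of the paths the package provides:

- **Centralities** — temporal in-closeness `TC_v = 1/ℓ_v` (reciprocal mean
  in-distance); path betweenness `PB_v = Σ_{w≠u} |σ_wu(v)|/|σ_wu|` (Brandes
  counting over shortest-path DAGs); betweenness efficiency
  `BE_v = Σ_{(w,u)∈β_v} 1/dist^λ_wu`, which up-weights bridges carrying
  *fast* flows; the purely temporal PTPB (all speeds set to `inf`); and
  aggregate in/out-degree.
- **Vulnerability measures** — giant strong component size `S` (maximum
  clique of the mutual-reachability "affine" graph), temporal efficiency
  `E^λ = (1/N(N−1)) Σ 1/dist^λ` (timestep units, in [0, 1]) and spatial
  efficiency `E^ς`.
- **Robustness analysis** — random error (independent Bernoulli(f) node
  failure, seeded realizations) and systematic attacks (TC/PB/BE/ID/OD/PTPB
  orderings, with greedy re-ranking for PB and BE), summarised by robustness
  curves `S(f)`, `R^λ(f) = E^λ(D)/E^λ`, `R^ς(f)` and their areas under the
  curve.
- **Descriptive statistics** — temporal correlation, topological and weight
  reciprocity, radius of gyration, median propagation speed.
- **Generators** — seeded synthetic networks emulating scheduled transit
  lines (service gaps included), random geometric systems, connectome-like
  static-topology networks with per-synapse-type delays, and instantaneous
  contact networks, plus small deterministic fixtures.

## Worked example

A five-node fixture (integer coordinates on a plane, `τ = 1 s`, all speeds
1 m/s) in which an edge to `D` keeps vanishing before propagation completes:

```python
import stnet as st

net = st.five_node_fixture()
trace, summary = st.run_propagation(net, "A")
for state in trace:
    print(f"t{state.step}: K = {sorted(state.K)}")
path = summary.path_to("E")
print("path:", " -> ".join(v for v, _ in path.sequence))
print(f"latency = {path.latency:.0f} s, spatial length = {path.spatial_length:.0f} m")
```

prints

```
t1: K = ['A']
t2: K = ['A', 'B']
t3: K = ['A', 'B']
t4: K = ['A', 'B', 'C']
t5: K = ['A', 'B', 'C']
t6: K = ['A', 'B', 'C', 'E']
path: A -> B -> C -> E
latency = 5 s, spatial length = 4 m
```

`B` is one metre from `A` and is reached after one step; `B → C` spans two
metres, so `C` shows partial progress at `t3` and arrives at `t4`; `E`
arrives at `t6` with latency 5 s over a 4 m route. `D` is never reached:
its edge disappears at `t3` and again at `t6`, resetting the accumulated
progress each time. Continuing,

```python
print("PB:", st.path_betweenness(net).scores)
print("E_lambda =", round(st.efficiency(net), 4))
print("S =", st.strong_components(net).giant_fraction)
```

```
PB: {'A': 0.0, 'B': 2.0, 'C': 2.0, 'D': 0.0, 'E': 0.0}
E_lambda = 0.1133
S = 0.2
```

`B` and `C` each sit inside two of the realized shortest paths; reachability
is one-way only, so no two nodes are mutually reachable and the giant strong
component is a single node (`S = 1/N = 0.2`).

The same analyses are available from the shell via the `stn` tool:

```sh
stn generate --model scheduled_lines --seed 11 --out net/
stn attack --nodes net/nodes.csv --edges net/edges.csv --meta net/meta.json \
    --strategy pb --out pb_curve.csv
stn auc pb_curve.csv --measure R_lambda
```

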