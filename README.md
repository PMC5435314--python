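# anna — anatomical network analysis of musculoskeletal systems

`anna` models a musculoskeletal system as an undirected simple graph:
bones, muscles and fibrous (connective-tissue) knots are nodes, and their
physical contacts — joints, ligamentous and monoaxial tendinous junctions —
are edges. On that graph it computes the organizational signatures that
anatomical network analysis (AnNA) relies on, for comparative morphologists
and evo-devo researchers who want topology-driven, observer-independent
delimitation of anatomical modules:

- **Betweenness centrality** (exact, Brandes' algorithm, unnormalized
  unordered-pair convention): which elements sit on the force-transmission
  bridges of the system.
- **Modularity** `Q = (1/2m) Σ_ij (A_ij − P_ij) δ(g_i, g_j)` of any
  partition *g*, where `A` is the adjacency matrix and `P` the expected-edge
  matrix of a degree-preserving null; the standard configuration null
  `p_ij = k_i k_j / 2m` is complemented by a **quasi-bipartite constrained
  null** that assigns zero likelihood to edges inside a designated
  independent set (muscles rarely touch muscles), plus a Barber-style strict
  two-mode null for comparison.
- **Modularity maximization**: an exhaustive oracle for ≤ 12 nodes, and a
  deterministic greedy agglomeration with seeded local-moving refinement and
  exact module bisection for real networks.
- **Fruchterman–Reingold layout** and a module-separation score linking the
  drawing to the partition.
- **Synthetic generators**: limb-like quasi-bipartite networks (connected
  bone scaffold, branching knots, degree-2-dominated muscles),
  planted-partition benchmarks, and degree-preserving rewiring for
  empirical Q null distributions.

The package ships the published 54-node frog hindlimb network
(*Leptodactylus latinasus*; 20 bones, 27 muscles, 7 fibrous knots,
102 contacts) with its published five-module partition (Hip, Thigh, Shank,
Calf, Foot) as `anna.frog_hindlimb_fixture()`.

## Worked example

```python
from anna import (betweenness, best_partition, build_null, compare_partitions,
                  compute_q, count_above_threshold, frog_hindlimb_fixture,
                  frog_published_partition)

net = frog_hindlimb_fixture()          # AnatomicalNetwork(n=54, m=102, ...)
table = betweenness(net)
print(count_above_threshold(table, 100))   # 9
print(net.name_of(table.ranking[0]))       # Femur  (score 478.8)

null = build_null(net, "configuration")
published = frog_published_partition(net)
print(round(compute_q(net, published, null), 6))   # 0.492695  -> prints as 0.49

res = best_partition(net, null, restarts=20, seed=1)
print(res.q, res.partition.n_modules)
# 0.4926951172625913 5
print(compare_partitions(res.partition, published).ari)   # 1.0
```

Nine of the 54 elements exceed betweenness 100 — the long bones (femur,
tibiofibula), the girdle elements (acetabulum, iliac shaft) and the
tibiale among them — marking the skeletal frame as the system's bridging
core. The published five-module partition scores Q = 0.49 under the
configuration null, and the search recovers exactly that partition
(adjusted Rand index 1.0): the hindlimb decomposes into hip, thigh, shank,
calf and foot complexes along the proximal–distal axis.

The same analyses are scriptable from the shell (`anna report --fixture
frog --out-dir results/`, `anna centrality ...`, `anna modules ...`,
`anna simulate limb ...`); see `examples/` for narrative walkthroughs of
each capability, including the quasi-bipartite nulls and the rewiring-based
significance check.

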