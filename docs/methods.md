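# Methods

## The model

A musculoskeletal system is represented as an undirected simple graph
`G = (V, E)` with `n` typed nodes — bones, muscles, and fibrous knots
(connective-tissue hubs from which more than two aligned collagen-fiber
bundles branch) — and `m` unweighted edges encoding physical contacts:
joints between bones, tendinous and ligamentous junctions elsewhere. Edges
carry no direction or weight; the analysis is purely topological.

Input networks arrive either as a node CSV plus an edge CSV
(`source,target`), or as a node CSV with a per-node adjacency-list column in
which every neighbour listing must be mutual. The adjacency form is
deliberately redundant: requiring each contact to be recorded from both
sides catches transcription errors in manually compiled anatomical tables,
and the loader treats any asymmetry as fatal. After loading, the handshake
identity `Σ k_i = 2m` is asserted.

The packaged reference network is the frog hindlimb: 20 bones, 27 muscles,
7 fibrous knots, 102 contacts, node ids 1–54, with the published
Hip/Thigh/Shank/Calf/Foot module labels attached. The fused ilium, ischium
and pubis are represented by the single "Acetabulum" node, following the
source anatomy's treatment of the adult pelvis. One documented
inconsistency in the source material is carried as-is: the prose describing
the shank complex mentions the fibulare, but the node table assigns the
fibulare (id 23) to the foot module; the fixture follows the table.

## Betweenness

For node `v`, betweenness is `Σ_{s<t, s≠v≠t} σ_st(v)/σ_st`, where `σ_st`
counts geodesics between `s` and `t` and `σ_st(v)` those passing through
`v`. The implementation is Brandes' dependency accumulation over BFS trees
(unit edge lengths), with the undirected double-count removed at the end.
Conventions: unnormalized scores, each unordered pair counted once,
endpoints excluded, cross-component pairs contributing zero. The
unnormalized convention is what makes an absolute threshold such as
"score > 100" meaningful on a 54-node network (the top score there is
478.8); with it, exactly nine hindlimb elements exceed 100. Ranking ties
break by ascending node id so reports are bit-reproducible.

A brute-force oracle with the identical contract enumerates all geodesics
explicitly (refusing n > 10) and anchors the property tests; networkx's
implementation is a second, independent cross-check.

## Modularity and its nulls

For a partition `g`, `Q = (1/2m) Σ_ij (A_ij − P_ij) δ(g_i, g_j)`, the sum
over ordered pairs. Three expected-edge matrices `P` are available:

- **configuration** — `p_ij = k_i k_j / 2m`. The formula is applied to all
  ordered pairs *including the diagonal* (`p_ii = k_i²/2m`, while
  `A_ii = 0`). With this convention every row of `B = A − P` sums to zero,
  total expected mass equals total observed mass, and the single-module
  partition scores exactly `Q = 0` — the identity the tests assert on
  random networks.
- **constrained** (quasi-bipartite) — musculoskeletal networks have a
  near-independent muscle set, and a null that spends expected mass on
  anatomically impossible muscle–muscle edges penalizes modules for links
  they could never contain. Here `p_ij = 0` whenever both endpoints carry
  the forbidden type, and `p_ij = c·k_i k_j` on allowed pairs with `c`
  chosen so total expected mass again equals `m`. The functional form is
  this package's explicit interpretation (degree propensity preserved,
  total mass preserved, same diagonal convention as above so `Q(single) = 0`
  still holds); it is one reasonable formalization of a constraint that has
  been posed in the literature only as a requirement, not as a formula.
- **bipartite** — Barber's strict two-mode null, `p_ij = k_i k_j / m`
  across the bipartition only. On a strictly bipartite graph its mass is
  exactly `m`; on quasi-bipartite graphs (which have within-side edges) it
  is approximate. Provided behind the same interface for comparison, and
  likewise labeled an interpretation.

`compute_q` evaluates Q through `B`; the tests verify it against an
independent per-module degree formula (`Σ_c [e_c/m − (d_c/2m)²]`) and
against igraph to 1e−12. Comparisons with the printed value 0.49 use
round-half-up to two decimals, matching printed-table precision.

## Partition search

`exhaustive_best` enumerates every set partition via restricted-growth
strings with the within-module B-sum maintained incrementally; it is exact
and limited to n ≤ 12 (Bell(12) ≈ 4.2 M). Ties break toward fewer
modules, then the lexicographically smallest restricted-growth labeling.

For larger networks `best_partition` combines:

1. **Greedy agglomeration** (CNM style): merge the module pair with the
   largest gain `2·S_ab/2m` while positive; ties go to the pair whose
   smallest member ids are lexicographically least.
2. **Local moving**: seeded sweeps move single nodes to the neighbouring or
   a fresh empty module with the largest gain, until no move improves Q by
   more than 1e−12 (the double-precision floor; prevents cycling). After
   every sweep the incrementally tracked Q is asserted against a
   from-scratch recomputation.
3. **Exact bisection** of each module (enumeration up to 16 members,
   Kernighan–Lin chained flips above): the move that lets the search carve
   a small dense module — such as the three-element calf complex — out of a
   larger one, which single-node steps cannot reach.

Restarts alternate between the greedy solution and singleton starts, each
refined and then polished by merge/split/move rounds until stable; the
best Q wins, with deterministic tie-breaking. All randomness flows from the
single integer seed, so identical inputs give identical `SearchResult`s.
On the hindlimb network, 20 restarts reliably reach Q = 0.492695 with five
modules, which equals the exact optimum found by an independent ILP solver
(igraph's optimal-modularity routine, used only as a development
cross-check) — the search replaces that solver dependency rather than
wrapping it.

Partition agreement uses the adjusted Rand index (scikit-learn) and the
variation of information; the degenerate all-singletons vs all-in-one
comparison is defined as ARI 0, the standard chance-correction convention.

## Layout

Classic Fruchterman–Reingold: attractive force `d²/k` on edges, repulsive
`k²/d` on all pairs, `k = C·√(area/n)`, displacement capped by a
temperature cooling linearly from width/10 to zero, positions clipped to
the frame each step, coincident points separated by seeded jitter.
Defaults (unit frame, 500 iterations, C = 1) are this package's choice —
the method is cited in the field without parameters. Repulsion is computed
over all pairs, O(n²) per iteration, acceptable at anatomical scales
(n ≈ 54); no Barnes–Hut approximation. The `layout_separation_score`
(mean within-module over mean between-module pairwise distance) turns the
qualitative claim "modules appear as proximate subsets" into a number:
random placement scores ≈ 1, the hindlimb layout against the published
partition scores ≈ 0.49.

## Synthetic generators

`generate_limb_like` emulates the *typed degree structure* of limb
networks: a connected bone scaffold (chain or random tree of joints), knots
branching to ≥ 3 bones/earlier knots, muscles drawing degree from
{2: 0.8, 3: 0.15, 4: 0.05} — echoing that 22 of the hindlimb's 27 muscles
have degree 2 — and attaching only to non-muscle elements, so the muscle
set is exactly independent (a flag injects exception edges to mimic the
hindlimb's single muscle–muscle contact). A `locality` parameter (default
0.7) biases attachments toward scaffold neighbourhoods, standing in for the
spatial adjacency of origin and insertion. Defaults reproduce the frog
census (20/27/7). What it does **not** emulate: real geometry, anatomical
nomenclature, correlated attachment patterns along the proximal–distal
axis, or any tissue property — so passing tests show the *pipeline*
handles quasi-bipartite typed networks correctly, not that it would segment
any real limb correctly. Disconnected outcomes are repaired by minimal
logged scaffold edges (raw output available by flag), keeping centrality
comparisons on connected instances.

`generate_planted` is the standard stochastic-block benchmark (`p_in`
within, `p_out` between); the ground-truth partition is returned and
isolated nodes are kept. Equality `p_in = p_out` is allowed for null
calibration; note the planted labeling's Q then has a finite-size offset of
order −(1/2 − same-pair fraction), which vanishes as blocks grow — the
calibration test uses blocks of 25 for this reason.

`degree_preserving_rewire` performs accepted double-edge swaps with
rejection of self-loops, duplicate edges and (optionally) edges inside a
forbidden type; the degree sequence is asserted unchanged.
`q_null_distribution` is an empirical companion to the analytic null —
rewire, re-optimize Q (5 restarts by default), and place the observed
optimum as a percentile. The analytic configuration null needs no such
simulation; the empirical route exists to quantify significance of the
*optimized* Q, which the analytic null does not address.

## Problem sizes and numerical choices

Property suites use 100 random graphs of 4–10 nodes for the
betweenness-oracle and heuristic-vs-exhaustive checks (the exhaustive
enumeration is the binding cost), 20 seeds × 40 nodes for planted-partition
recovery, and 15–20 replicates for rewiring nulls on the 54-node fixture.
Q equalities between code paths are asserted at 1e−12 absolute; heuristic
optimality at 1e−9; the search convergence tolerance is 1e−12 on ΔQ.

## Known limitations

- The constrained and bipartite nulls are interpretations of a constraint
  stated in the literature without a formula; their Q values are labeled as
  such and not compared against any published number.
- Exhaustive search is exact only to n = 12; beyond that optimality is
  empirical (heuristic matches the exhaustive optimum on ≥ 95% of small
  random instances, and the hindlimb optimum is corroborated externally).
- Uniqueness of a network's optimal partition is not guaranteed; ties are
  resolved deterministically but a co-optimal partition different from a
  published one would be a legitimate outcome.
- No weighted or directed edges, no overlapping modules, no resolution
  (multiscale) parameter, no 3-D layout.
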