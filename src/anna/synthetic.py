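"""Synthetic generators of limb-like and benchmark networks.

Two families make every stage of the pipeline testable without external
data:

* **Limb-like quasi-bipartite networks** mimic the typed degree structure of
  musculoskeletal systems: a connected bone scaffold (chain or random tree
  of joints), fibrous knots branching to three or more attachment sites, and
  muscles of low degree (mostly 2, reflecting one origin and one insertion)
  attaching only to non-muscle elements — so the muscle set is an
  independent set, the idealized form of the quasi-bipartite architecture.
  A flag injects a configurable number of exceptional muscle-muscle edges.

* **Planted-partition networks** are standard stochastic-block benchmarks
  (within-module edge probability p_in, between-module p_out) with the
  ground-truth partition returned alongside.

Degree-preserving double-edge-swap rewiring turns any network into an
empirical configuration-model sample, optionally refusing swaps that would
create edges inside a forbidden node type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph import AnatomicalNetwork, NodeRecord, NodeType, Partition
from .modularity import NullModel, build_null
from .search import best_partition

__all__ = [
    "LimbGenParams",
    "PlantedParams",
    "QNullResult",
    "generate_limb_like",
    "generate_planted",
    "degree_preserving_rewire",
    "q_null_distribution",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LimbGenParams:
    """Parameters of the limb-like generator.

    Defaults echo the frog hindlimb census: 20 bones, 27 muscles, 7 knots,
    muscle degree mostly 2 (mass 0.8 on degree 2, 0.15 on 3, 0.05 on 4),
    knots branching to at least 3 attachments.  ``locality`` in [0, 1]
    biases muscle attachments toward scaffold neighbourhoods of their first
    anchor bone, mimicking the anatomical adjacency of origin and insertion.
    """

    n_bones: int = 20
    n_muscles: int = 27
    n_knots: int = 7
    backbone: str = "tree"  # or "chain"
    muscle_degree_dist: dict[int, float] = field(
        default_factory=lambda: {2: 0.8, 3: 0.15, 4: 0.05}
    )
    knot_min_degree: int = 3
    locality: float = 0.7
    n_muscle_exception_edges: int = 0
    repair_connectivity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bones < 2:
            raise ValueError("need at least 2 bones for a scaffold")
        if self.knot_min_degree < 3:
            raise ValueError("a fibrous knot branches to more than two fibre sets")
        if self.backbone not in ("chain", "tree"):
            raise ValueError("backbone must be 'chain' or 'tree'")
        if not 0.0 <= self.locality <= 1.0:
            raise ValueError("locality must lie in [0, 1]")
        if abs(sum(self.muscle_degree_dist.values()) - 1.0) > 1e-9:
            raise ValueError("muscle_degree_dist must sum to 1")
        if self.knot_min_degree > self.n_bones + self.n_knots - 1:
            raise ValueError(
                "infeasible: knots demand more attachment sites than the "
                "scaffold offers"
            )


@dataclass(frozen=True)
class PlantedParams:
    """Stochastic-block benchmark parameters (0 <= p_out <= p_in <= 1)."""

    module_sizes: tuple[int, ...]
    p_in: float
    p_out: float
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_sizes", tuple(self.module_sizes))
        if not self.module_sizes or min(self.module_sizes) < 1:
            raise ValueError("module sizes must be positive")
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out <= p_in <= 1")


def generate_limb_like(params: LimbGenParams) -> AnatomicalNetwork:
    """Generate a typed, simple, connected limb-like network.

    Bones 1..n_bones, knots next, muscles last.  Bones form a chain or
    random labelled tree; each knot attaches to at least ``knot_min_degree``
    distinct bones/earlier knots; each muscle draws its degree and attaches
    to that many distinct non-muscle elements.  If components remain after
    generation they are stitched with minimal scaffold edges (logged),
    unless ``repair_connectivity`` is off.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    bones = list(range(1, p.n_bones + 1))
    knots = list(range(p.n_bones + 1, p.n_bones + p.n_knots + 1))
    muscles = list(
        range(p.n_bones + p.n_knots + 1, p.n_bones + p.n_knots + p.n_muscles + 1)
    )
    edges: set[tuple[int, int]] = set()

    def add(u: int, v: int) -> None:
        edges.add((min(u, v), max(u, v)))

    # bone scaffold
    if p.backbone == "chain":
        for a, b in zip(bones, bones[1:]):
            add(a, b)
    else:  # random labelled tree: attach each bone to a random earlier bone
        for i, b in enumerate(bones[1:], start=1):
            add(b, bones[rng.integers(0, i)])
    scaffold_nbrs = {b: set() for b in bones}
    for u, v in edges:
        scaffold_nbrs[u].add(v)
        scaffold_nbrs[v].add(u)

    # knots branch to >= knot_min_degree distinct bones / earlier knots
    for ki, knot in enumerate(knots):
        pool = bones + knots[:ki]
        if len(pool) < p.knot_min_degree:
            raise ValueError(
                f"infeasible: knot {knot} has only {len(pool)} possible "
                f"attachment sites, needs {p.knot_min_degree}"
            )
        targets = rng.choice(pool, size=p.knot_min_degree, replace=False)
        for t in targets:
            add(knot, int(t))

    # muscles: low degree, non-muscle endpoints only
    degs = sorted(p.muscle_degree_dist)
    probs = np.array([p.muscle_degree_dist[d] for d in degs])
    non_muscle = bones + knots
    for mus in muscles:
        d = int(rng.choice(degs, p=probs))
        anchor = int(rng.choice(bones))
        chosen = {anchor}
        # local pool: scaffold neighbours of the anchor plus all knots
        local = (scaffold_nbrs[anchor] | set(knots)) - chosen
        while len(chosen) < d:
            pool = sorted(local - chosen) if (
                rng.random() < p.locality and local - chosen
            ) else [x for x in non_muscle if x not in chosen]
            chosen.add(int(rng.choice(pool)))
        for t in chosen:
            add(mus, t)

    # optional quasi-bipartite exception edges (e.g. one muscle-muscle link)
    for _ in range(p.n_muscle_exception_edges):
        for _attempt in range(100):
            a, b = rng.choice(muscles, size=2, replace=False)
            key = (min(int(a), int(b)), max(int(a), int(b)))
            if key not in edges:
                edges.add(key)
                break

    records = (
        [NodeRecord(b, f"bone_{b}", NodeType.BONE) for b in bones]
        + [NodeRecord(k, f"knot_{k}", NodeType.CONNECTIVE_KNOT) for k in knots]
        + [NodeRecord(m, f"muscle_{m}", NodeType.MUSCLE) for m in muscles]
    )
    net = AnatomicalNetwork(records, sorted(edges))

    if p.repair_connectivity:
        import networkx as nx

        comps = sorted(nx.connected_components(net.graph), key=min)
        if len(comps) > 1:
            base = comps[0]
            for comp in comps[1:]:
                # stitch with a scaffold edge between non-muscle nodes when
                # possible, falling back to any representative pair
                u = min(x for x in base if net.type_of(x) is not NodeType.MUSCLE)
                nm = [x for x in comp if net.type_of(x) is not NodeType.MUSCLE]
                v = min(nm) if nm else min(comp)
                log.info("connectivity repair: adding edge (%d, %d)", u, v)
                edges.add((min(u, v), max(u, v)))
                base = base | comp
            net = AnatomicalNetwork(records, sorted(edges))
    return net


def generate_planted(
    params: PlantedParams,
) -> tuple[AnatomicalNetwork, Partition]:
    """Planted-partition (stochastic block) network with its ground truth.

    Nodes are typed ``bone`` (the benchmark carries no anatomy); isolated
    nodes may occur at small p and are kept.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = sum(p.module_sizes)
    labels = np.repeat(np.arange(len(p.module_sizes)), p.module_sizes)
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    prob = np.where(same, p.p_in, p.p_out)
    keep = rng.random(len(prob)) < prob
    edges = [(int(iu[e]) + 1, int(ju[e]) + 1) for e in np.flatnonzero(keep)]
    records = [NodeRecord(i + 1, f"node_{i + 1}", NodeType.BONE) for i in range(n)]
    net = AnatomicalNetwork(records, edges)
    truth = Partition({i + 1: f"G{labels[i] + 1}" for i in range(n)})
    return net, truth


def degree_preserving_rewire(
    net: AnatomicalNetwork,
    n_swaps: int,
    seed: int = 0,
    respect_forbidden: NodeType | str | None = None,
) -> AnatomicalNetwork:
    """Randomize a network by accepted double-edge swaps.

    Picks two edges (a, b), (c, d) and proposes (a, d), (c, b); swaps that
    would create self-loops, duplicate edges, or — when
    ``respect_forbidden`` is set — an edge between two nodes of the
    forbidden type, are rejected.  The degree sequence is exactly preserved
    (asserted).  Stops after ``n_swaps`` acceptances or a generous attempt
    budget, logging the acceptance rate.
    """
    if net.m < 2:
        raise ValueError("need at least two edges to swap")
    forbidden = NodeType.coerce(respect_forbidden) if respect_forbidden else None
    rng = np.random.default_rng(seed)
    edges = list(net.edges())
    edge_set = set(edges)
    accepted = attempts = 0
    max_attempts = max(100, 50 * n_swaps)
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if a == d or c == b or new1 == new2:
            continue
        if new1 in edge_set or new2 in edge_set:
            continue
        if forbidden is not None and any(
            net.type_of(u) is forbidden and net.type_of(v) is forbidden
            for u, v in (new1, new2)
        ):
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edges[i], edges[j] = new1, new2
        edge_set.add(new1)
        edge_set.add(new2)
        accepted += 1
    log.debug(
        "rewire: %d/%d swaps accepted (%.1f%% of attempts)",
        accepted, n_swaps, 100.0 * accepted / max(attempts, 1),
    )
    out = AnatomicalNetwork(net.records.values(), edges)
    assert all(out.degree(i) == net.degree(i) for i in net.node_ids)
    return out


@dataclass(frozen=True)
class QNullResult:
    """Empirical null distribution of optimal Q under rewiring.

    ``percentile`` is the fraction (in percent) of replicates whose optimal
    Q falls below the observed network's; ``None`` when no replicates were
    requested.
    """

    q_values: tuple[float, ...]
    observed_q: float
    percentile: float | None


def q_null_distribution(
    net: AnatomicalNetwork,
    n_replicates: int,
    swaps_per_replicate: int,
    seed: int = 0,
    null_kind: str = "configuration",
    forbidden_type: NodeType | str | None = None,
    respect_forbidden: NodeType | str | None = None,
    restarts: int = 5,
) -> QNullResult:
    """Monte-Carlo companion to the analytic null: rewire, re-optimize Q.

    Each replicate rewires the network (degree-preserving) and records the
    best Q found by :func:`~anna.search.best_partition` with ``restarts``
    restarts.  The observed network's own optimal Q is placed as an
    empirical percentile within that distribution.
    """
    rng = np.random.default_rng(seed)
    null = build_null(net, null_kind, forbidden_type)
    observed = best_partition(net, null, restarts=restarts, seed=int(
        rng.integers(0, 2**31 - 1))).q
    qs: list[float] = []
    for _ in range(n_replicates):
        s = int(rng.integers(0, 2**31 - 1))
        rewired = degree_preserving_rewire(
            net, swaps_per_replicate, seed=s, respect_forbidden=respect_forbidden
        )
        rnull = build_null(rewired, null_kind, forbidden_type)
        qs.append(best_partition(rewired, rnull, restarts=restarts, seed=s).q)
    pct = None
    if qs:
        pct = 100.0 * sum(1 for q in qs if q < observed) / len(qs)
    return QNullResult(tuple(qs), observed, pct)
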