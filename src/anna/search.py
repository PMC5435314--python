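"""Modularity maximization: exhaustive oracle and multi-restart heuristics.

Finding the partition that maximizes Q is NP-hard, so this module offers a
ladder of searchers:

* :func:`exhaustive_best` — iterates every set partition (restricted-growth
  enumeration) for networks of at most 12 nodes; the ground-truth oracle.
* :func:`greedy_agglomerative` — deterministic CNM-style merging of the
  module pair with the largest positive Q gain.
* :func:`refine_local_moving` — Louvain-style single-node moves in a seeded
  random sweep order; Q never decreases.
* :func:`best_partition` — greedy agglomeration plus seeded refinement
  restarts from the greedy solution and from random starts; fully
  reproducible given the seed.

All searchers accept any :class:`~anna.modularity.NullModel`, so the same
machinery optimizes Q under the standard configuration null and under the
quasi-bipartite constrained null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics.cluster import contingency_matrix

from .graph import AnatomicalNetwork, Partition
from .modularity import NullModel, compute_q, modularity_matrix

__all__ = [
    "SearchResult",
    "PartitionComparison",
    "exhaustive_best",
    "greedy_agglomerative",
    "refine_local_moving",
    "best_partition",
    "compare_partitions",
]

_TOL = 1e-12
_EXHAUSTIVE_MAX_N = 12


@dataclass(frozen=True)
class SearchResult:
    """Outcome of a modularity search."""

    partition: Partition
    q: float
    method: str
    restarts_used: int = 0
    seed: int | None = None


def _partition_from_codes(net: AnatomicalNetwork, codes) -> Partition:
    """Codes (first-appearance order) -> labels M1, M2, ... ."""
    seen: dict[int, str] = {}
    assignment = {}
    for i, c in zip(net.node_ids, codes):
        assignment[i] = seen.setdefault(int(c), f"M{len(seen) + 1}")
    return Partition(assignment)


def _codes_of(net: AnatomicalNetwork, partition: Partition) -> np.ndarray:
    return np.array(partition.membership(net.node_ids), dtype=int)


def _result(
    net: AnatomicalNetwork,
    null: NullModel,
    codes,
    method: str,
    restarts: int = 0,
    seed: int | None = None,
) -> SearchResult:
    part = _partition_from_codes(net, codes)
    # q recomputed from scratch: no drift between incremental bookkeeping
    # and the reference formula
    q = compute_q(net, part, null)
    return SearchResult(part, q, method, restarts, seed)


# -- exhaustive oracle -----------------------------------------------------

def exhaustive_best(net: AnatomicalNetwork, null: NullModel) -> SearchResult:
    """Globally optimal partition by enumerating all set partitions.

    Enumeration follows restricted-growth strings over nodes in ascending id
    order, with the within-module B-sum maintained incrementally.  Ties are
    broken toward fewer modules, then the lexicographically smallest
    restricted-growth labeling.  Refuses n > 12 (Bell(12) ≈ 4.2 million).
    """
    n = net.n
    if n > _EXHAUSTIVE_MAX_N:
        raise ValueError(
            f"exhaustive search limited to n <= {_EXHAUSTIVE_MAX_N} nodes "
            f"(got n={n}); use best_partition instead"
        )
    B = modularity_matrix(net, null)
    two_m = 2.0 * net.m
    codes = np.zeros(n, dtype=int)
    members: list[list[int]] = [[] for _ in range(n)]
    best = {"q": -np.inf, "k": n + 1, "codes": None}

    def visit(i: int, n_used: int, qsum: float) -> None:
        if i == n:
            q = qsum / two_m
            b = best
            if (
                q > b["q"] + _TOL
                or (abs(q - b["q"]) <= _TOL and n_used < b["k"])
            ):
                b["q"], b["k"], b["codes"] = q, n_used, codes.copy()
            return
        row = B[i]
        for c in range(n_used + 1):
            gain = 2.0 * sum(row[j] for j in members[c]) + B[i, i]
            codes[i] = c
            members[c].append(i)
            visit(i + 1, max(n_used, c + 1), qsum + gain)
            members[c].pop()

    visit(0, 0, 0.0)
    return _result(net, null, best["codes"], "exhaustive")


# -- greedy agglomeration --------------------------------------------------

def greedy_agglomerative(
    net: AnatomicalNetwork,
    null: NullModel,
    start: Partition | None = None,
) -> SearchResult:
    """CNM-style agglomeration: repeatedly merge the module pair with the
    largest Q gain while any gain is positive.

    Starts from singleton modules (or ``start``); the merge gain of modules
    a, b is 2·S_ab/2m where S_ab sums B over cross pairs.  Ties go to the
    pair with the smallest (minimum-member-id) module indices.  Returns the
    best partition along the merge path.
    """
    B = modularity_matrix(net, null)
    two_m = 2.0 * net.m
    n = net.n
    if start is None:
        codes = np.arange(n, dtype=int)
    else:
        start.validate_on(net)
        codes = _codes_of(net, start)
    labels = sorted(set(codes.tolist()))
    M = np.zeros((len(labels), n))
    for r, lab in enumerate(labels):
        M[r, codes == lab] = 1.0
    S = M @ B @ M.T  # module-pair B sums
    # anchor: smallest node id inside each module, for deterministic ties
    anchor = [int(np.flatnonzero(codes == lab)[0]) for lab in labels]
    alive = list(range(len(labels)))

    q = float(np.trace(S)) / two_m
    best_q, best_codes = q, codes.copy()
    module_of = {r: np.flatnonzero(codes == lab).tolist()
                 for r, lab in enumerate(labels)}

    while len(alive) > 1:
        gain, pick = -np.inf, None
        for ai in range(len(alive)):
            a = alive[ai]
            for b in alive[ai + 1:]:
                g = 2.0 * S[a, b] / two_m
                key = tuple(sorted((anchor[a], anchor[b])))
                if g > gain + _TOL or (abs(g - gain) <= _TOL and pick and key < pick[0]):
                    gain, pick = g, (key, a, b)
        if gain <= _TOL:
            break
        _, a, b = pick
        S[a, :] += S[b, :]
        S[:, a] += S[:, b]
        alive.remove(b)
        module_of[a].extend(module_of[b])
        anchor[a] = min(anchor[a], anchor[b])
        q += gain
        if q > best_q + _TOL:
            new_codes = np.empty(n, dtype=int)
            for r in alive:
                new_codes[module_of[r]] = r
            best_q, best_codes = q, new_codes
    return _result(net, null, _canonical(best_codes), "greedy")


def _canonical(codes: np.ndarray) -> np.ndarray:
    """Relabel codes by first appearance."""
    seen: dict[int, int] = {}
    return np.array([seen.setdefault(int(c), len(seen)) for c in codes])


# -- local moving ----------------------------------------------------------

def refine_local_moving(
    net: AnatomicalNetwork,
    null: NullModel,
    start: Partition,
    seed: int = 0,
) -> SearchResult:
    """Seeded single-node move refinement; Q never decreases.

    Each sweep visits all nodes in a seeded random order and moves each to
    the neighbouring (or a fresh empty) module with the largest Q gain,
    while any move improves Q by more than 1e-12.  At the end of every sweep
    the incremental Q is checked against a from-scratch recomputation.
    """
    start.validate_on(net)
    B = modularity_matrix(net, null)
    two_m = 2.0 * net.m
    n = net.n
    codes = _codes_of(net, start)
    rng = np.random.default_rng(seed)
    ids = list(net.node_ids)
    idx = {v: i for i, v in enumerate(ids)}
    nbr = [[idx[w] for w in net.neighbors(v)] for v in ids]

    same = codes[:, None] == codes[None, :]
    q = float(B[same].sum()) / two_m
    sweeps = 0
    improved = True
    while improved:
        improved = False
        order = rng.permutation(n)
        for i in order:
            c_old = codes[i]
            row = B[i]
            stay = row[codes == c_old].sum() - B[i, i]
            # candidate target modules: those of graph neighbours + empty
            cands = {codes[j] for j in nbr[i]} - {c_old}
            free = _first_free_code(codes, c_old)
            if free is not None:
                cands.add(free)
            best_gain, best_c = 0.0, c_old
            for c_new in sorted(cands):
                enter = row[codes == c_new].sum()
                gain = 2.0 * (enter - stay) / two_m
                if gain > best_gain + _TOL:
                    best_gain, best_c = gain, c_new
            if best_c != c_old:
                codes[i] = best_c
                q += best_gain
                improved = True
        sweeps += 1
        # incremental bookkeeping must agree with from-scratch Q
        same = codes[:, None] == codes[None, :]
        q_check = float(B[same].sum()) / two_m
        assert abs(q - q_check) < 1e-9, (q, q_check)
        q = q_check
    return _result(net, null, _canonical(codes), "local_moving", seed=seed)


def _first_free_code(codes: np.ndarray, exclude: int) -> int | None:
    """A code not currently used (a fresh empty module), if the mover is not
    already a singleton."""
    if (codes == exclude).sum() == 1:
        return None
    used = set(codes.tolist())
    c = 0
    while c in used:
        c += 1
    return c


# -- multi-restart driver --------------------------------------------------

def best_partition(
    net: AnatomicalNetwork,
    null: NullModel,
    restarts: int = 20,
    seed: int = 0,
) -> SearchResult:
    """Best-of: greedy agglomeration plus seeded refinement restarts.

    Half the restarts refine the greedy solution, half refine random starts
    (seeded singleton sweeps); every refined partition is further polished
    by alternating merge and move phases until Q stabilizes.  With the same
    (network, null, restarts, seed) the result is identical across runs.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if net.m == 0:
        raise ValueError("modularity search undefined for m = 0")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=restarts)

    greedy = greedy_agglomerative(net, null)
    candidates = [greedy]
    singleton = Partition({i: f"s{i}" for i in net.node_ids})
    for r, s in enumerate(child_seeds):
        start = greedy.partition if r % 2 == 0 else singleton
        res = refine_local_moving(net, null, start, seed=int(s))
        res = _polish(net, null, res, int(s))
        candidates.append(res)

    def rank(res: SearchResult):
        return (-res.q, res.partition.n_modules,
                tuple(res.partition.membership(net.node_ids)))

    best = min(candidates, key=rank)
    return SearchResult(best.partition, best.q, "best_partition",
                        restarts_used=restarts, seed=seed)


def _polish(
    net: AnatomicalNetwork, null: NullModel, res: SearchResult, seed: int
) -> SearchResult:
    """Alternate merge, split and move phases until none improves Q.

    The split phase bisects each module to maximize the within-module B sum
    (exact enumeration up to 16 members, Kernighan-Lin above); it is what
    lets the search carve a small dense module out of a larger one, a move
    unreachable by single-node steps.
    """
    B = modularity_matrix(net, null)
    current = res
    for _ in range(20):
        merged = greedy_agglomerative(net, null, start=current.partition)
        codes = _split_phase(_codes_of(net, merged.partition), B)
        moved = refine_local_moving(
            net, null, _partition_from_codes(net, codes), seed=seed
        )
        if moved.q <= current.q + _TOL:
            break
        current = moved
    return current


def _split_phase(codes: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Bisect every module whose best two-way split increases the
    within-module B sum."""
    codes = codes.copy()
    for c in sorted(set(codes.tolist())):
        mem = np.flatnonzero(codes == c)
        if len(mem) < 2:
            continue
        Bc = B[np.ix_(mem, mem)]
        gain, side = _best_bisection(Bc)
        if gain > _TOL:
            codes[mem[side]] = codes.max() + 1
    return codes


def _best_bisection(Bc: np.ndarray) -> tuple[float, np.ndarray]:
    """Best two-way split of one module.

    Maximizes s^T Bc s over sign vectors s; the gain in the within-module
    B sum is (s^T Bc s - sum Bc)/2.  Exact for up to 16 members (the last
    member's side is fixed to kill the mirror symmetry); Kernighan-Lin
    chained-flip passes from the leading-eigenvector split otherwise.
    """
    k = Bc.shape[0]
    total = Bc.sum()
    if k <= 16:
        bits = (np.arange(2 ** (k - 1))[:, None] >> np.arange(k)) & 1
        S = 1.0 - 2.0 * bits
        vals = np.einsum("ij,jk,ik->i", S, Bc, S)
        best = int(np.argmax(vals))
        side = S[best] < 0
        return (float(vals[best]) - total) / 2.0, side
    # KL: start from the leading eigenvector's signs, then passes of chained
    # single flips (each node flipped once per pass, best-gain first, even if
    # locally negative), keeping the best prefix.
    s = np.where(np.linalg.eigh(Bc)[1][:, -1] >= 0, 1.0, -1.0)
    val = float(s @ Bc @ s)
    for _ in range(k):
        s_pass = s.copy()
        free = np.ones(k, dtype=bool)
        best_val, best_state = val, s.copy()
        v = val
        for _step in range(k):
            flip_gain = -4.0 * s_pass * (Bc @ s_pass - np.diag(Bc) * s_pass)
            flip_gain[~free] = -np.inf
            j = int(np.argmax(flip_gain))
            v += float(flip_gain[j])
            s_pass[j] = -s_pass[j]
            free[j] = False
            if v > best_val + _TOL:
                best_val, best_state = v, s_pass.copy()
        if best_val <= val + _TOL:
            break
        val, s = best_val, best_state
    side = s < 0
    if side.all() or not side.any():
        return 0.0, side
    return (val - total) / 2.0, side


# -- partition comparison --------------------------------------------------

@dataclass(frozen=True)
class PartitionComparison:
    """Similarity of two partitions of the same node set.

    ``ari`` is the adjusted Rand index in [-1, 1] (1 iff identical up to
    relabeling; the degenerate all-singletons vs all-in-one comparison is 0
    by the standard chance-correction convention).  ``vi`` is the variation
    of information in nats (0 iff identical).  ``label_map`` greedily maps
    labels of the first partition onto best-overlapping labels of the
    second.
    """

    ari: float
    vi: float
    label_map: dict[str, str]


def compare_partitions(a: Partition, b: Partition) -> PartitionComparison:
    if set(a.assignment) != set(b.assignment):
        raise ValueError("partitions cover different node sets")
    order = sorted(a.assignment)
    xa = a.membership(order)
    xb = b.membership(order)
    ari = float(adjusted_rand_score(xa, xb))

    C = contingency_matrix(xa, xb).astype(float)
    n = C.sum()
    pa = C.sum(axis=1) / n
    pb = C.sum(axis=0) / n
    ha = -np.sum(pa * np.log(pa))
    hb = -np.sum(pb * np.log(pb))
    pij = C / n
    nz = pij > 0
    mi = float(np.sum(pij[nz] * np.log(pij[nz] / np.outer(pa, pb)[nz])))
    vi = max(0.0, float(ha + hb - 2.0 * mi))

    # best one-to-one label matching by overlap (Hungarian assignment)
    la = sorted({a.assignment[i] for i in order})
    lb = sorted({b.assignment[i] for i in order})
    M = np.zeros((len(la), len(lb)))
    for i in order:
        M[la.index(a.assignment[i]), lb.index(b.assignment[i])] += 1
    rows, cols = linear_sum_assignment(-M)
    label_map = {la[r]: lb[c] for r, c in zip(rows, cols) if M[r, c] > 0}
    if abs(ari - 1.0) < 1e-12:
        vi = 0.0
    return PartitionComparison(ari=ari, vi=vi, label_map=label_map)
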