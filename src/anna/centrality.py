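"""Exact geodesic betweenness centrality.

Betweenness measures the bridging role of a node: for node *v* it sums, over
all unordered pairs {s, t} with s ≠ t ≠ v, the fraction of shortest paths
between s and t that pass through v.  In a musculoskeletal network a high
score marks an element heavily exposed to the propagation of mechanical
force.

Conventions here are the unnormalized, undirected ones (each unordered pair
counted once, unit edge lengths, endpoints excluded), which is what makes
absolute thresholds such as "score > 100" meaningful on a 54-node network.
The main implementation is Brandes' dependency-accumulation algorithm; a
brute-force shortest-path enumeration with the identical contract is
provided as a test oracle for small graphs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .graph import AnatomicalNetwork

__all__ = [
    "CentralityTable",
    "betweenness",
    "brute_force_betweenness",
    "count_above_threshold",
]


@dataclass(frozen=True)
class CentralityTable:
    """Per-node betweenness scores with a deterministic ranking.

    Ranking is by descending score; ties are broken by ascending node id so
    two runs always print the same report.
    """

    scores: dict[int, float]

    @property
    def ranking(self) -> list[int]:
        return sorted(self.scores, key=lambda i: (-self.scores[i], i))

    def top(self, k: int) -> list[int]:
        return self.ranking[:k]

    def __getitem__(self, node_id: int) -> float:
        return self.scores[node_id]


def betweenness(net: AnatomicalNetwork) -> CentralityTable:
    """Brandes' accumulation algorithm on unit-length edges.

    The graph need not be connected: pairs in different components have no
    connecting path and contribute nothing.
    """
    g = net.graph
    score = dict.fromkeys(g, 0.0)
    for s in g:
        # single-source shortest paths by BFS
        stack: list[int] = []
        pred: dict[int, list[int]] = {v: [] for v in g}
        sigma = dict.fromkeys(g, 0.0)
        dist = dict.fromkeys(g, -1)
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in g[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        # dependency accumulation in reverse topological (distance) order
        delta = dict.fromkeys(g, 0.0)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                score[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return CentralityTable({i: score[i] / 2.0 for i in net.node_ids})


def brute_force_betweenness(net: AnatomicalNetwork) -> CentralityTable:
    """Betweenness by explicit enumeration of every shortest path.

    Test oracle only; refuses networks with more than 10 nodes because
    all-geodesic enumeration grows combinatorially.
    """
    if net.n > 10:
        raise ValueError(
            f"brute-force enumeration is limited to n <= 10 nodes, got n={net.n}"
        )
    g = net.graph
    score = dict.fromkeys(g, 0.0)
    for s, t in combinations(net.node_ids, 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    return CentralityTable({i: score[i] for i in net.node_ids})


def count_above_threshold(table: CentralityTable, threshold: float) -> int:
    """Number of nodes scoring strictly above ``threshold``."""
    return sum(1 for v in table.scores.values() if v > threshold)
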