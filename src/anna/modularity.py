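"""Modularity Q under configuration-model and quasi-bipartite nulls.

Newman-Girvan modularity compares the observed within-module edge mass with
its expectation under a degree-preserving random null:

    Q = (1/2m) * sum_ij (A_ij - P_ij) * delta(g_i, g_j)

where A is the adjacency matrix, P the expected-edge matrix of the null,
and the sum runs over ordered node pairs.  Three nulls are provided:

``configuration``
    The standard unimodal null, p_ij = k_i * k_j / (2m).

``constrained``
    A quasi-bipartite interpretation for musculoskeletal networks, where the
    muscle set is (nearly) an independent set: p_ij = 0 whenever both
    endpoints carry the forbidden type, and p_ij = c * k_i * k_j on allowed
    pairs, with c chosen so that total expected edge mass equals m.  Pairs
    that cannot be linked anatomically then carry no modularity penalty.

``bipartite``
    A strict Barber-style two-mode null for comparison: expectation
    k_i * k_j / m across the bipartition only, zero within either side.

Diagonal convention: the configuration formula is applied to all ordered
pairs including i = j (p_ii = k_i^2 / 2m, forbidden-type diagonals zero
under the constrained null), while A_ii = 0 always.  With this convention
total expected mass matches total observed mass exactly, so a single-module
partition scores Q = 0 identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import AnatomicalNetwork, NodeType, Partition

__all__ = [
    "NullModel",
    "build_null",
    "compute_q",
    "modularity_matrix",
    "NULL_KINDS",
]

NULL_KINDS = ("configuration", "constrained", "bipartite")


@dataclass(frozen=True)
class NullModel:
    """Expected-edge-probability matrix P for a network.

    ``P[a, b]`` is indexed by position in ``node_ids`` (sorted node order).
    ``c`` is the normalizing constant of the constrained null (for the
    standard configuration null it equals 1/2m).
    """

    kind: str
    node_ids: tuple[int, ...]
    P: np.ndarray
    forbidden_type: NodeType | None = None
    c: float | None = None

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: int) -> int:
        return self.node_ids.index(node_id)


def _degrees(net: AnatomicalNetwork) -> np.ndarray:
    return np.array([net.degree(i) for i in net.node_ids], dtype=float)


def build_null(
    net: AnatomicalNetwork,
    kind: str = "configuration",
    forbidden_type: NodeType | str | None = None,
) -> NullModel:
    """Build the expected-edge matrix P of a degree-propensity null.

    For ``constrained`` and ``bipartite`` kinds, ``forbidden_type`` names the
    node type forming the (near-)independent set (muscles in limb networks).
    """
    if kind not in NULL_KINDS:
        raise ValueError(f"unknown null kind {kind!r}; expected one of {NULL_KINDS}")
    if net.m == 0:
        raise ValueError("null model undefined for a network with no edges (m = 0)")
    k = _degrees(net)
    two_m = 2.0 * net.m
    ids = net.node_ids

    if kind == "configuration":
        P = np.outer(k, k) / two_m
        return NullModel("configuration", ids, P, None, 1.0 / two_m)

    if forbidden_type is None:
        raise ValueError(f"null kind {kind!r} requires a forbidden_type")
    t = NodeType.coerce(forbidden_type)
    is_forbidden = np.array([net.type_of(i) is t for i in ids])

    if kind == "constrained":
        allowed = ~(np.outer(is_forbidden, is_forbidden))
        mass = float((np.outer(k, k) * allowed).sum())
        if mass <= 0.0:
            raise ValueError(
                "constrained null infeasible: no allowed pair has positive "
                "degree product"
            )
        c = two_m / mass
        P = c * np.outer(k, k) * allowed
        return NullModel("constrained", ids, P, t, c)

    # Barber-style strict two-mode null: expectation only across the
    # bipartition (forbidden type vs. the rest), k_i k_j / m.
    cross = np.outer(is_forbidden, ~is_forbidden)
    cross = cross | cross.T
    P = np.outer(k, k) / float(net.m) * cross
    return NullModel("bipartite", ids, P, t, 1.0 / net.m)


def adjacency_matrix(net: AnatomicalNetwork) -> np.ndarray:
    """Dense adjacency matrix A in sorted node-id order."""
    return nx.to_numpy_array(net.graph, nodelist=list(net.node_ids))


def modularity_matrix(net: AnatomicalNetwork, null: NullModel) -> np.ndarray:
    """The modularity matrix B = A - P, in sorted node-id order."""
    if null.node_ids != net.node_ids:
        raise ValueError("null model was built on a different node set")
    return adjacency_matrix(net) - null.P


def compute_q(
    net: AnatomicalNetwork, partition: Partition, null: NullModel
) -> float:
    """Modularity Q of ``partition`` under ``null``.

    Evaluates (1/2m) * sum over ordered pairs of (A_ij - P_ij) restricted to
    same-module pairs.  Q lies in [-1, 1].
    """
    partition.validate_on(net)
    if null.node_ids != net.node_ids:
        raise ValueError("null model was built on a different node set")
    B = modularity_matrix(net, null)
    codes = np.array(partition.membership(net.node_ids))
    same = codes[:, None] == codes[None, :]
    return float(B[same].sum() / (2.0 * net.m))
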