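"""Graph data model for anatomical networks.

An anatomical network treats discrete anatomical elements — bones, muscles
and fibrous (connective-tissue) knots — as nodes of an undirected simple
graph, and their physical contacts (joints, ligamentous and tendinous
junctions) as edges.  This module provides the typed container
(:class:`AnatomicalNetwork`), validated readers for the two tabular input
conventions (explicit edge list, or a per-node adjacency-list column), module
partitions, and GraphML / CSV export.

Node identifiers are positive integers and are the only keys used in
computation; names, types and module labels are attributes.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "NodeType",
    "NodeRecord",
    "Partition",
    "AnatomicalNetwork",
    "load_network",
    "load_graphml",
    "degree_census",
    "find_within_type_edges",
    "export_graphml",
    "export_edge_csv",
    "export_node_csv",
]


class NodeType(str, enum.Enum):
    """Typology of anatomical elements."""

    BONE = "bone"
    MUSCLE = "muscle"
    CONNECTIVE_KNOT = "connective_knot"

    @classmethod
    def coerce(cls, value: "NodeType | str") -> "NodeType":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown node type {value!r}; expected one of "
                f"{[t.value for t in cls]}"
            ) from None


@dataclass(frozen=True)
class NodeRecord:
    """One anatomical element.

    Parameters
    ----------
    id:
        Positive integer identifier, unique within a network.
    name:
        Human-readable anatomical name.
    type:
        One of :class:`NodeType`.
    published_module:
        Optional module label carried from a published partition.
    synonyms:
        Optional alternative nomenclature; metadata only, never used in
        computation.
    """

    id: int
    name: str
    type: NodeType
    published_module: str | None = None
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if int(self.id) <= 0:
            raise ValueError(f"node id must be a positive integer, got {self.id}")
        object.__setattr__(self, "id", int(self.id))
        object.__setattr__(self, "type", NodeType.coerce(self.type))


@dataclass(frozen=True)
class Partition:
    """Assignment of every node id to a module label.

    The partition is exhaustive and non-overlapping: every node of the host
    network appears exactly once, and every label has at least one member.
    """

    assignment: Mapping[int, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))

    @property
    def labels(self) -> tuple[str, ...]:
        """Distinct module labels, sorted for determinism."""
        return tuple(sorted(set(self.assignment.values())))

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, label: str) -> tuple[int, ...]:
        return tuple(sorted(i for i, g in self.assignment.items() if g == label))

    def sizes(self) -> dict[str, int]:
        return dict(Counter(self.assignment.values()))

    def membership(self, order: Sequence[int]) -> list[int]:
        """Integer membership codes following ``order``; labels coded by
        first appearance along ``order`` (canonical for comparisons)."""
        codes: dict[str, int] = {}
        out = []
        for i in order:
            lab = self.assignment[i]
            out.append(codes.setdefault(lab, len(codes)))
        return out

    def validate_on(self, net: "AnatomicalNetwork") -> None:
        missing = set(net.node_ids) - set(self.assignment)
        extra = set(self.assignment) - set(net.node_ids)
        if missing or extra:
            raise ValueError(
                f"partition does not cover the network: missing={sorted(missing)}, "
                f"extra={sorted(extra)}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return dict(self.assignment) == dict(other.assignment)

    def __hash__(self) -> int:  # content hash, order independent
        return hash(frozenset(self.assignment.items()))


class AnatomicalNetwork:
    """Undirected simple graph over :class:`NodeRecord` elements.

    Invariants enforced at construction: unique ids, no self-loops, no
    duplicate edges, every edge endpoint declared.  The adjacency matrix is
    symmetric by construction (edges are unordered pairs).
    """

    def __init__(
        self,
        records: Iterable[NodeRecord],
        edges: Iterable[tuple[int, int]],
    ) -> None:
        recs = list(records)
        ids = [r.id for r in recs]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise ValueError(f"duplicate node ids: {sorted(dup)}")
        self._records: dict[int, NodeRecord] = {r.id: r for r in recs}

        g = nx.Graph()
        for r in recs:
            g.add_node(
                r.id,
                name=r.name,
                type=r.type.value,
                module=r.published_module or "",
            )
        seen: set[tuple[int, int]] = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                raise ValueError(f"self-loop on node {u} is not allowed")
            for x in (u, v):
                if x not in self._records:
                    raise ValueError(f"edge ({u}, {v}) references unknown node id {x}")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise ValueError(f"duplicate edge ({key[0]}, {key[1]})")
            seen.add(key)
            g.add_edge(*key)
        self._g = g

        # handshake lemma: sum of degrees equals twice the edge count
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()

    # -- basic accessors ---------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        """The underlying :class:`networkx.Graph` (shared, do not mutate)."""
        return self._g

    @property
    def n(self) -> int:
        return self._g.number_of_nodes()

    @property
    def m(self) -> int:
        return self._g.number_of_edges()

    @property
    def node_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self._g.nodes))

    @property
    def records(self) -> dict[int, NodeRecord]:
        return dict(self._records)

    def record(self, node_id: int) -> NodeRecord:
        return self._records[node_id]

    def name_of(self, node_id: int) -> str:
        return self._records[node_id].name

    def type_of(self, node_id: int) -> NodeType:
        return self._records[node_id].type

    def degree(self, node_id: int) -> int:
        return self._g.degree(node_id)

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges, smaller id first, sorted."""
        return sorted((min(u, v), max(u, v)) for u, v in self._g.edges)

    def neighbors(self, node_id: int) -> tuple[int, ...]:
        return tuple(sorted(self._g.neighbors(node_id)))

    def nodes_of_type(self, node_type: NodeType | str) -> tuple[int, ...]:
        t = NodeType.coerce(node_type)
        return tuple(i for i in self.node_ids if self._records[i].type is t)

    def type_census(self) -> dict[str, int]:
        return dict(Counter(self._records[i].type.value for i in self.node_ids))

    def published_partition(self) -> Partition:
        """Partition from the ``published_module`` labels carried by nodes."""
        missing = [i for i in self.node_ids if not self._records[i].published_module]
        if missing:
            raise ValueError(
                f"nodes without a published module label: {missing[:10]}"
            )
        return Partition({i: self._records[i].published_module for i in self.node_ids})

    def subgraph_equals(self, other: "AnatomicalNetwork") -> bool:
        """Attribute-aware equality (same ids, records, edges)."""
        return (
            self.node_ids == other.node_ids
            and self.edges() == other.edges()
            and all(
                (r := self._records[i]).name == other._records[i].name
                and r.type == other._records[i].type
                and (r.published_module or None)
                == (other._records[i].published_module or None)
                for i in self.node_ids
            )
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnatomicalNetwork):
            return NotImplemented
        return self.subgraph_equals(other)

    def __repr__(self) -> str:
        census = self.type_census()
        return f"AnatomicalNetwork(n={self.n}, m={self.m}, types={census})"


# -- readers ---------------------------------------------------------------

def _as_dataframe(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    return pd.read_csv(source, dtype=str, keep_default_na=False)


def _records_from_table(nodes: pd.DataFrame) -> list[NodeRecord]:
    cols = {c.lower(): c for c in nodes.columns}
    for required in ("id", "name", "type"):
        if required not in cols:
            raise ValueError(f"node table lacks required column {required!r}")
    records = []
    for _, row in nodes.iterrows():
        module = str(row[cols["module"]]).strip() if "module" in cols else ""
        syn = ()
        if "synonyms" in cols and str(row[cols["synonyms"]]).strip():
            syn = tuple(
                s.strip() for s in str(row[cols["synonyms"]]).split("|") if s.strip()
            )
        records.append(
            NodeRecord(
                id=int(row[cols["id"]]),
                name=str(row[cols["name"]]).strip(),
                type=NodeType.coerce(row[cols["type"]]),
                published_module=module or None,
                synonyms=syn,
            )
        )
    return records


def _edges_from_adjacency(nodes: pd.DataFrame) -> list[tuple[int, int]]:
    """Collapse a per-node adjacency-list column into undirected edges.

    Every listed neighbour pair (i, j) must also appear as (j, i); an
    asymmetric listing is a transcription error and is fatal.
    """
    cols = {c.lower(): c for c in nodes.columns}
    col = cols["adjacency"]
    listed: dict[int, set[int]] = {}
    for _, row in nodes.iterrows():
        i = int(row[cols["id"]])
        raw = str(row[col]).replace(",", " ").split()
        listed[i] = {int(x) for x in raw}
        if i in listed[i]:
            raise ValueError(f"self-loop on node {i} in adjacency list")
    for i, nbrs in listed.items():
        for j in nbrs:
            if j not in listed:
                raise ValueError(f"adjacency of node {i} references unknown id {j}")
            if i not in listed[j]:
                raise ValueError(
                    f"asymmetric adjacency list: node {i} lists {j} "
                    f"but node {j} does not list {i}"
                )
    return sorted({(min(i, j), max(i, j)) for i, nbrs in listed.items() for j in nbrs})


def load_network(node_table, edge_table=None) -> AnatomicalNetwork:
    """Build a validated :class:`AnatomicalNetwork` from tabular input.

    ``node_table`` needs columns ``id,name,type`` (plus optional ``module``,
    ``synonyms`` and ``adjacency``); it may be a CSV path or a DataFrame.
    Edges come either from ``edge_table`` (columns ``source,target``) or from
    an ``adjacency`` column whose entries list each node's neighbours; the
    adjacency form requires mutual (symmetric) listings.
    """
    nodes = _as_dataframe(node_table)
    records = _records_from_table(nodes)
    cols = {c.lower() for c in nodes.columns}
    if edge_table is not None:
        edges_df = _as_dataframe(edge_table)
        ecols = {c.lower(): c for c in edges_df.columns}
        if not {"source", "target"} <= set(ecols):
            raise ValueError("edge table needs columns 'source' and 'target'")
        edges = [
            (int(r[ecols["source"]]), int(r[ecols["target"]]))
            for _, r in edges_df.iterrows()
        ]
    elif "adjacency" in cols:
        edges = _edges_from_adjacency(nodes)
    else:
        raise ValueError(
            "no edges given: pass an edge table or include an 'adjacency' column"
        )
    return AnatomicalNetwork(records, edges)


# -- summaries -------------------------------------------------------------

def degree_census(
    net: AnatomicalNetwork, type_filter: NodeType | str | None = None
) -> dict[int, int]:
    """Count nodes at each degree, optionally restricted to one node type."""
    if type_filter is None:
        ids = net.node_ids
    else:
        ids = net.nodes_of_type(type_filter)
    return dict(Counter(net.degree(i) for i in ids))


def find_within_type_edges(
    net: AnatomicalNetwork, node_type: NodeType | str
) -> list[tuple[int, int]]:
    """Edges whose two endpoints share ``node_type``.

    For the muscle type this is the quasi-bipartite deviation set: a strictly
    bipartite bone/knot-versus-muscle network would return an empty list.
    """
    t = NodeType.coerce(node_type)
    return [
        (u, v)
        for u, v in net.edges()
        if net.type_of(u) is t and net.type_of(v) is t
    ]


# -- writers ---------------------------------------------------------------

def export_graphml(
    net: AnatomicalNetwork,
    path: str | Path,
    partition: Partition | None = None,
) -> None:
    """Write GraphML with node attributes ``name``, ``type``, ``module``."""
    g = nx.Graph()
    for i in net.node_ids:
        r = net.record(i)
        module = (
            partition.assignment[i] if partition is not None
            else (r.published_module or "")
        )
        g.add_node(i, name=r.name, type=r.type.value, module=module)
    g.add_edges_from(net.edges())
    nx.write_graphml(g, path)


def load_graphml(path: str | Path) -> AnatomicalNetwork:
    g = nx.read_graphml(path)
    records = [
        NodeRecord(
            id=int(i),
            name=data.get("name", str(i)),
            type=NodeType.coerce(data["type"]),
            published_module=data.get("module") or None,
        )
        for i, data in g.nodes(data=True)
    ]
    edges = [(int(u), int(v)) for u, v in g.edges]
    return AnatomicalNetwork(records, edges)


def export_edge_csv(net: AnatomicalNetwork, path: str | Path) -> None:
    """Two-column CSV, one row per undirected edge, smaller id first."""
    pd.DataFrame(net.edges(), columns=["source", "target"]).to_csv(path, index=False)


def export_node_csv(net: AnatomicalNetwork, path: str | Path) -> None:
    rows = [
        {
            "id": i,
            "name": net.record(i).name,
            "type": net.record(i).type.value,
            "module": net.record(i).published_module or "",
        }
        for i in net.node_ids
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
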