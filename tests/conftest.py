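import numpy as np
import pytest

from anna import (
    AnatomicalNetwork,
    NodeRecord,
    NodeType,
    build_null,
    frog_hindlimb_fixture,
    frog_published_partition,
)


@pytest.fixture(scope="session")
def frog():
    return frog_hindlimb_fixture()


@pytest.fixture(scope="session")
def published(frog):
    return frog_published_partition(frog)


@pytest.fixture(scope="session")
def frog_null(frog):
    return build_null(frog, "configuration")


def make_network(edges, n=None, types=None):
    """Small typed network from an edge list (ids 1-based)."""
    ids = sorted({i for e in edges for i in e} | set(range(1, (n or 0) + 1)))
    types = types or {}
    records = [
        NodeRecord(i, f"v{i}", types.get(i, NodeType.BONE)) for i in ids
    ]
    return AnatomicalNetwork(records, edges)


def random_network(rng, n, p=0.4, require_connected=False, require_edges=True):
    """Erdos-Renyi test network; optionally resampled until connected."""
    import networkx as nx

    for _ in range(200):
        edges = [
            (i, j)
            for i in range(1, n + 1)
            for j in range(i + 1, n + 1)
            if rng.random() < p
        ]
        if require_edges and not edges:
            continue
        net = make_network(edges, n=n)
        if not require_connected or nx.is_connected(net.graph):
            return net
    raise RuntimeError("could not sample a suitable random network")


PATH3 = [(1, 2), (2, 3)]
TRIANGLE_PAIR = [(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)]
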