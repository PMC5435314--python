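"""Modularity Q and the three null models."""

import numpy as np
import pytest

from anna import (
    NodeType,
    Partition,
    build_null,
    compute_q,
    find_within_type_edges,
    modularity_matrix,
)

from conftest import TRIANGLE_PAIR, make_network, random_network


def single_module(net):
    return Partition({i: "all" for i in net.node_ids})


def q_by_degree_formula(net, partition):
    """Independent route: Q = sum_c [e_c/m - (d_c/2m)^2] (standard null)."""
    m = net.m
    q = 0.0
    for label in partition.labels:
        members = set(partition.members(label))
        e_c = sum(1 for u, v in net.edges() if u in members and v in members)
        d_c = sum(net.degree(i) for i in members)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


class TestConfigurationNull:
    def test_k2_expected_edge(self):
        net = make_network([(1, 2)])
        null = build_null(net)
        assert null.P[0, 1] == pytest.approx(0.5)

    def test_fixture_femur_tibiofibula_expectation(self, frog, frog_null):
        a = frog.node_ids.index(22)
        b = frog.node_ids.index(53)
        assert frog_null.P[a, b] == pytest.approx(17 * 15 / 204)

    def test_null_requires_edges(self):
        with pytest.raises(ValueError, match="m = 0"):
            build_null(make_network([], n=3))

    def test_modularity_matrix_k2(self):
        net = make_network([(1, 2)])
        B = modularity_matrix(net, build_null(net))
        assert B == pytest.approx(np.array([[-0.5, 0.5], [0.5, -0.5]]))

    def test_row_sums_vanish_with_diagonal_convention(self, frog, frog_null):
        B = modularity_matrix(frog, frog_null)
        assert np.allclose(B.sum(axis=1), 0.0, atol=1e-12)

    def test_expected_edge_mass_equals_m(self, frog, frog_null):
        assert frog_null.P.sum() / 2.0 == pytest.approx(frog.m)


class TestComputeQ:
    def test_single_module_is_zero_everywhere(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            net = random_network(rng, int(rng.integers(4, 13)), p=0.35)
            q = compute_q(net, single_module(net), build_null(net))
            assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles(self):
        net = make_network(TRIANGLE_PAIR)
        part = Partition({i: ("a" if i <= 3 else "b") for i in net.node_ids})
        assert compute_q(net, part, build_null(net)) == pytest.approx(0.5)

    def test_k2_singletons(self):
        net = make_network([(1, 2)])
        part = Partition({1: "a", 2: "b"})
        assert compute_q(net, part, build_null(net)) == pytest.approx(-0.5)

    def test_published_partition_rounds_to_049(self, frog, published, frog_null):
        from anna.report import _round_half_up

        q = compute_q(frog, published, frog_null)
        assert _round_half_up(q, 2) == 0.49

    def test_matrix_route_agrees_with_degree_formula(self, frog, published, frog_null):
        q = compute_q(frog, published, frog_null)
        assert q == pytest.approx(q_by_degree_formula(frog, published), abs=1e-12)

    def test_agrees_with_igraph(self, frog, published):
        igraph = pytest.importorskip("igraph")
        g = igraph.Graph(n=54, edges=[(u - 1, v - 1) for u, v in frog.edges()])
        labels = published.labels
        memb = [labels.index(published.assignment[i]) for i in frog.node_ids]
        q = compute_q(frog, published, build_null(frog))
        assert q == pytest.approx(g.modularity(memb), abs=1e-12)

    def test_invariant_under_relabeling_and_permutation(self, frog, published, frog_null):
        rng = np.random.default_rng(0)
        labels = list(published.labels)
        for _ in range(5):
            perm = {lab: f"x{rng.integers(1000)}_{k}" for k, lab in enumerate(labels)}
            relabeled = Partition(
                {i: perm[published.assignment[i]] for i in frog.node_ids}
            )
            assert compute_q(frog, relabeled, frog_null) == pytest.approx(
                compute_q(frog, published, frog_null), abs=1e-12
            )

    def test_missing_node_is_fatal(self, frog, frog_null):
        part = Partition({i: "all" for i in frog.node_ids[:-1]})
        with pytest.raises(ValueError, match="does not cover"):
            compute_q(frog, part, frog_null)


class TestConstrainedNull:
    def test_muscle_pairs_forbidden(self, frog):
        null = build_null(frog, "constrained", NodeType.MUSCLE)
        ids = list(frog.node_ids)
        muscles = [ids.index(i) for i in frog.nodes_of_type(NodeType.MUSCLE)]
        assert np.all(null.P[np.ix_(muscles, muscles)] == 0.0)
        # including the one realized muscle-muscle contact
        assert null.P[ids.index(8), ids.index(20)] == 0.0

    def test_total_mass_preserved(self, frog):
        null = build_null(frog, "constrained", NodeType.MUSCLE)
        assert null.P.sum() / 2.0 == pytest.approx(frog.m)
        assert null.c is not None and null.c > 0

    def test_single_module_still_zero(self, frog):
        null = build_null(frog, "constrained", NodeType.MUSCLE)
        q = compute_q(frog, single_module(frog), null)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_distinguishable_from_standard_null(self, frog, published, frog_null):
        constrained = build_null(frog, "constrained", NodeType.MUSCLE)
        q_std = compute_q(frog, published, frog_null)
        q_con = compute_q(frog, published, constrained)
        assert q_con != pytest.approx(q_std, abs=1e-6)

    def test_requires_forbidden_type(self, frog):
        with pytest.raises(ValueError, match="forbidden_type"):
            build_null(frog, "constrained")

    def test_all_pairs_forbidden_is_fatal(self):
        net = make_network(
            [(1, 2)], types={1: NodeType.MUSCLE, 2: NodeType.MUSCLE}
        )
        with pytest.raises(ValueError, match="infeasible"):
            build_null(net, "constrained", NodeType.MUSCLE)


class TestBipartiteNull:
    def test_zero_within_both_sides(self, frog):
        null = build_null(frog, "bipartite", NodeType.MUSCLE)
        ids = list(frog.node_ids)
        muscles = [ids.index(i) for i in frog.nodes_of_type(NodeType.MUSCLE)]
        others = [j for j in range(frog.n) if j not in muscles]
        assert np.all(null.P[np.ix_(muscles, muscles)] == 0.0)
        assert np.all(null.P[np.ix_(others, others)] == 0.0)

    def test_exact_mass_on_strictly_bipartite_graph(self):
        # muscles attach only to bones: expectation sums to m exactly
        net = make_network(
            [(1, 3), (1, 4), (2, 3), (2, 4)],
            types={3: NodeType.MUSCLE, 4: NodeType.MUSCLE},
        )
        assert find_within_type_edges(net, NodeType.MUSCLE) == []
        null = build_null(net, "bipartite", NodeType.MUSCLE)
        assert null.P.sum() / 2.0 == pytest.approx(net.m)
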