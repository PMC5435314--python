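"""Data model, validation, fixture integrity and round-trip I/O."""

import pandas as pd
import pytest

from anna import (
    NodeType,
    degree_census,
    export_edge_csv,
    export_graphml,
    export_node_csv,
    find_within_type_edges,
    frog_hindlimb_fixture,
    load_graphml,
    load_network,
)
from anna.synthetic import LimbGenParams, PlantedParams, generate_limb_like, generate_planted

from conftest import make_network


def nodes_df(rows):
    return pd.DataFrame(rows)


class TestLoading:
    def test_minimal_network(self):
        net = load_network(
            nodes_df(
                [
                    {"id": 1, "name": "a", "type": "bone"},
                    {"id": 2, "name": "b", "type": "muscle"},
                ]
            ),
            pd.DataFrame([{"source": 1, "target": 2}]),
        )
        assert (net.n, net.m) == (2, 1)
        assert net.type_of(2) is NodeType.MUSCLE

    def test_adjacency_list_form_collapses_mutual_listings(self):
        net = load_network(
            nodes_df(
                [
                    {"id": 1, "name": "a", "type": "bone", "adjacency": "2 3"},
                    {"id": 2, "name": "b", "type": "bone", "adjacency": "1"},
                    {"id": 3, "name": "c", "type": "muscle", "adjacency": "1"},
                ]
            )
        )
        assert net.edges() == [(1, 2), (1, 3)]

    def test_asymmetric_adjacency_is_fatal_naming_both_ids(self):
        rows = [
            {"id": 48, "name": "a", "type": "bone", "adjacency": "49"},
            {"id": 49, "name": "b", "type": "bone", "adjacency": ""},
        ]
        with pytest.raises(ValueError, match="48.*49"):
            load_network(nodes_df(rows))

    @pytest.mark.parametrize(
        "edges,msg",
        [
            ([(1, 3)], "unknown node id"),
            ([(1, 1)], "self-loop"),
            ([(1, 2), (2, 1)], "duplicate edge"),
        ],
    )
    def test_edge_validation(self, edges, msg):
        rows = [
            {"id": 1, "name": "a", "type": "bone"},
            {"id": 2, "name": "b", "type": "bone"},
        ]
        with pytest.raises(ValueError, match=msg):
            load_network(nodes_df(rows), pd.DataFrame(edges, columns=["source", "target"]))

    def test_unknown_type_is_fatal(self):
        with pytest.raises(ValueError, match="unknown node type"):
            load_network(
                nodes_df([{"id": 1, "name": "a", "type": "tendon", "adjacency": ""}])
            )

    def test_handshake_lemma_on_random_networks(self):
        import numpy as np

        from conftest import random_network

        rng = np.random.default_rng(11)
        for _ in range(30):
            net = random_network(rng, int(rng.integers(3, 12)), require_edges=False)
            assert sum(net.degree(i) for i in net.node_ids) == 2 * net.m


class TestFrogFixture:
    """Integrity of the packaged 54-node hindlimb network."""

    def test_census(self, frog):
        assert frog.n == 54
        assert frog.m == 102
        assert frog.type_census() == {
            "muscle": 27,
            "bone": 20,
            "connective_knot": 7,
        }

    def test_femur_degree(self, frog):
        femur = next(i for i in frog.node_ids if frog.name_of(i) == "Femur")
        assert femur == 22
        assert frog.degree(22) == 17

    def test_published_module_sizes(self, published):
        assert published.sizes() == {
            "Hip": 9,
            "Thigh": 14,
            "Shank": 12,
            "Calf": 3,
            "Foot": 16,
        }

    def test_every_adjacency_listing_is_mutual(self):
        # the loader revalidates symmetry on every load; a transcription
        # error would raise here
        frog_hindlimb_fixture()


class TestCensusAndTypeEdges:
    def test_muscle_degree_census(self, frog):
        census = degree_census(frog, NodeType.MUSCLE)
        assert census[2] == 22
        assert sum(census.values()) == 27

    def test_star_census(self):
        star = make_network([(1, 2), (1, 3), (1, 4), (1, 5)])
        assert degree_census(star) == {1: 4, 4: 1}

    def test_isolated_nodes_census(self):
        net = make_network([], n=3)
        assert degree_census(net) == {0: 3}

    def test_single_muscle_muscle_edge(self, frog):
        assert find_within_type_edges(frog, NodeType.MUSCLE) == [(8, 20)]
        assert frog.name_of(8) == "Cruralis"
        assert frog.name_of(20) == "Extensor iliotibialis B"

    def test_removing_the_exception_gives_strict_bipartition(self, frog):
        edges = [e for e in frog.edges() if e != (8, 20)]
        net = type(frog)(frog.records.values(), edges)
        assert find_within_type_edges(net, NodeType.MUSCLE) == []

    def test_bone_bone_joints_nonempty(self, frog):
        joints = find_within_type_edges(frog, NodeType.BONE)
        assert (1, 22) in joints  # acetabulum-femur hip joint


class TestRoundTrips:
    def test_frog_graphml_round_trip(self, frog, tmp_path):
        path = tmp_path / "frog.graphml"
        export_graphml(frog, path)
        again = load_graphml(path)
        assert again == frog

    def test_graphml_counts(self, frog, tmp_path):
        path = tmp_path / "frog.graphml"
        export_graphml(frog, path)
        text = path.read_text()
        assert text.count("<node ") == 54
        assert text.count("<edge ") == 102

    def test_k2_edge_csv(self, tmp_path):
        net = make_network([(1, 2)])
        path = tmp_path / "k2.csv"
        export_edge_csv(net, path)
        assert path.read_text().strip().splitlines() == ["source,target", "1,2"]

    def test_csv_round_trip_on_random_synthetics(self, tmp_path):
        for seed in range(50):
            if seed % 2:
                net = generate_limb_like(
                    LimbGenParams(n_bones=5, n_muscles=6, n_knots=3, seed=seed)
                )
            else:
                net, _ = generate_planted(PlantedParams((4, 4), 0.9, 0.2, seed=seed))
            npath, epath = tmp_path / "n.csv", tmp_path / "e.csv"
            export_node_csv(net, npath)
            export_edge_csv(net, epath)
            assert load_network(npath, epath) == net

    def test_graphml_round_trip_on_random_synthetics(self, tmp_path):
        for seed in range(50):
            net = generate_limb_like(
                LimbGenParams(n_bones=4, n_muscles=5, n_knots=3, seed=seed)
            )
            path = tmp_path / "g.graphml"
            export_graphml(net, path)
            assert load_graphml(path) == net
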