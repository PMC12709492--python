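"""Network container, graph matrices, spectral embeddings, fixture, I/O."""

import networkx as nx
import numpy as np
import pytest

from hmlm.network import (
    MODULES,
    Edge,
    NetworkValidationError,
    Node,
    SignalingNetwork,
    adjacency_matrix,
    generate_fixture_network,
    path_length_matrix,
    read_network,
    spectral_positional_embedding,
    weighted_adjacency,
    write_network,
)


class TestContainer:
    def test_duplicate_node_ids_rejected(self):
        with pytest.raises(NetworkValidationError, match="duplicate node ids"):
            SignalingNetwork([Node("a", "inputs"), Node("a", "inputs")], [])

    def test_duplicate_edges_rejected_not_merged(self):
        nodes = [Node("a", "inputs"), Node("b", "receptors", "receptor")]
        with pytest.raises(NetworkValidationError, match="duplicate edge"):
            SignalingNetwork(nodes, [Edge("a", "b"), Edge("a", "b", 1, 0.5)])

    def test_edge_to_unknown_node_rejected(self):
        with pytest.raises(NetworkValidationError, match="unknown node"):
            SignalingNetwork([Node("a", "inputs")], [Edge("a", "zz")])

    def test_module_map_partitions_nodes(self, net):
        all_ids = set()
        for members in net.module_map.values():
            assert not (all_ids & members)
            all_ids |= members
        assert all_ids == set(net.species)


class TestMatrices:
    def test_adjacency_chain(self, chain_net):
        a = adjacency_matrix(chain_net)
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 2] = 1
        np.testing.assert_array_equal(a, expected)

    def test_adjacency_empty_edges(self):
        netx = SignalingNetwork([Node("a", "inputs"), Node("b", "inputs")], [])
        assert adjacency_matrix(netx).sum() == 0

    def test_adjacency_row_sums_are_out_degrees(self, net):
        a = adjacency_matrix(net)
        out_deg = {s: 0 for s in net.species}
        for e in net.edges:
            out_deg[e.source] += 1
        np.testing.assert_array_equal(
            a.sum(axis=1), [out_deg[s] for s in net.species]
        )

    def test_weighted_inhibitory_entry(self):
        nodes = [Node("a", "feedback"), Node("b", "receptors", "receptor")]
        w = weighted_adjacency(SignalingNetwork(nodes, [Edge("a", "b", -1, 0.5)]))
        assert w[0, 1] == -0.5

    def test_weighted_reduces_to_adjacency_for_unit_weights(self, chain_net):
        np.testing.assert_array_equal(
            weighted_adjacency(chain_net), adjacency_matrix(chain_net)
        )

    def test_sparsity_patterns_coincide(self, net):
        np.testing.assert_array_equal(
            adjacency_matrix(net) != 0, weighted_adjacency(net) != 0
        )


class TestPathLengths:
    def test_chain_two_hops(self, chain_net):
        d = path_length_matrix(chain_net, max_len=3)
        assert d[0, 2] == 2

    def test_disconnected_pair_sentinel(self):
        netx = SignalingNetwork([Node("a", "inputs"), Node("b", "inputs")], [])
        d = path_length_matrix(netx, max_len=3)
        assert d[0, 1] == 4  # sentinel = max_len + 1

    def test_agrees_with_bfs_oracle_on_fixture(self, net):
        d = path_length_matrix(net, max_len=3)
        g = net.to_networkx()
        rng = np.random.default_rng(0)
        for _ in range(20):
            i, j = rng.integers(0, net.n_nodes, size=2)
            src, tgt = net.species[i], net.species[j]
            try:
                true = nx.shortest_path_length(g, src, tgt)
            except nx.NetworkXNoPath:
                true = np.inf
            expected = true if true <= 3 else 4
            assert d[i, j] == expected

    def test_full_agreement_on_small_network(self):
        rng = np.random.default_rng(3)
        nodes = [Node(f"n{i}", "inputs") for i in range(20)]
        edges = []
        seen = set()
        for _ in range(40):
            i, j = rng.integers(0, 20, size=2)
            if i != j and (i, j) not in seen:
                seen.add((i, j))
                edges.append(Edge(f"n{i}", f"n{j}"))
        small = SignalingNetwork(nodes, edges)
        d = path_length_matrix(small, max_len=5)
        g = small.to_networkx()
        lengths = dict(nx.all_pairs_shortest_path_length(g))
        for i in range(20):
            for j in range(20):
                true = lengths.get(f"n{i}", {}).get(f"n{j}", np.inf)
                assert d[i, j] == (true if true <= 5 else 6)


class TestSpectralEmbedding:
    def test_complete_graph_eigenvalue(self):
        nodes = [Node(c, "inputs") for c in "abc"]
        edges = [
            Edge(a, b)
            for a in "abc"
            for b in "abc"
            if a != b
        ]
        k3 = SignalingNetwork(nodes, edges)
        emb = spectral_positional_embedding(k3, k=1)
        # normalized Laplacian of K3 has spectrum {0, 1.5, 1.5}
        assert emb.eigenvalues[0] == pytest.approx(1.5)

    def test_zero_eigenvalues_excluded_for_disconnected_graph(self):
        nodes = [Node(c, "inputs") for c in "abcd"]
        edges = [Edge("a", "b"), Edge("c", "d")]  # two components
        emb = spectral_positional_embedding(SignalingNetwork(nodes, edges), k=2)
        assert np.all(emb.eigenvalues > 1e-10)

    def test_columns_orthogonal(self, net):
        emb = spectral_positional_embedding(net, k=4)
        gram = emb.positional_block.T @ emb.positional_block
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=1e-8)
        np.testing.assert_allclose(np.diag(gram), 1.0, atol=1e-8)

    def test_eigenvalues_in_normalized_laplacian_range(self, net):
        emb = spectral_positional_embedding(net, k=6)
        assert np.all(emb.eigenvalues >= 0) and np.all(emb.eigenvalues <= 2 + 1e-12)
        assert np.all(np.diff(emb.eigenvalues) >= -1e-12)

    def test_error_when_k_exceeds_available(self):
        # 3 nodes, 2 components -> two zero eigenvalues, only 1 usable
        nodes = [Node(c, "inputs") for c in "abc"]
        with pytest.raises(ValueError, match="1 are available"):
            spectral_positional_embedding(
                SignalingNetwork(nodes, [Edge("a", "b")]), k=2
            )


class TestFixtureNetwork:
    def test_deterministic_given_seed(self):
        assert generate_fixture_network(seed=1) == generate_fixture_network(seed=1)

    def test_seed_changes_network(self):
        assert generate_fixture_network(seed=1) != generate_fixture_network(seed=2)

    def test_scale_and_modules(self, net):
        assert net.n_nodes == 132
        assert len(net.edges) >= 200
        assert set(net.module_map) == set(MODULES)
        assert all(net.module_map[m] for m in MODULES)

    def test_anchor_chain_present(self, net):
        for src, tgt in [
            ("TGFB", "TGFBR"),
            ("TGFBR", "SMAD3"),
            ("PDGF", "PDGFR"),
            ("PDGFR", "PI3K"),
            ("integrins", "FAK"),
            ("SMAD3", "YAP"),
            ("YAP", "aSMA"),
        ]:
            assert net.has_edge(src, tgt), f"missing anchor edge {src}->{tgt}"
        assert net.node("p38").module == "mapk"
        assert net.node("contractility").entity_type == "readout"

    def test_tgfb_reaches_collagen_within_three_hops(self, net):
        d = path_length_matrix(net, max_len=3)
        assert d[net.index("TGFB"), net.index("proCI")] <= 3


class TestIO:
    @pytest.mark.parametrize("fmt", ["graphml", "sif", "json"])
    def test_round_trip(self, net, tmp_path, fmt):
        path = tmp_path / f"net.{fmt}"
        write_network(net, path)
        again = read_network(path)
        assert again == net

    def test_sif_activates_line(self, tmp_path):
        path = tmp_path / "mini.sif"
        path.write_text("TGFBR\tactivates\tSMAD3\n")
        netx = read_network(path)
        (edge,) = netx.edges
        assert (edge.sign, edge.weight) == (1, 1.0)

    def test_sif_unknown_relation_reports_line(self, tmp_path):
        path = tmp_path / "bad.sif"
        path.write_text("A\tpokes\tB\n")
        with pytest.raises(NetworkValidationError, match="bad.sif:1"):
            read_network(path)

    def test_json_missing_module_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"nodes": [{"id": "a"}], "edges": []}')
        with pytest.raises(NetworkValidationError, match="missing 'module'"):
            read_network(path)
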