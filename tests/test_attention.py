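"""Attention: initialization, lagged correlation, refinement, aggregation, nulls."""

import numpy as np
import pytest

from hmlm.attention import (
    INIT_LEVELS,
    attention_graph,
    attention_null_test,
    init_attention,
    lagged_correlation_matrices,
    lagged_pearson,
    pathway_attention,
    refine_attention,
)
from hmlm.network import Edge, Node, SignalingNetwork
from hmlm.simulate import SimulationConfig, TimeSeriesDataset, generate_dataset


class TestInitAttention:
    def test_chain_values(self, chain_net):
        a0 = init_attention(chain_net).initial
        assert a0[0, 0] == 1.0  # self
        assert a0[0, 1] == 0.8  # direct edge
        assert a0[0, 2] == 0.4  # path length 2
        assert a0[2, 0] == 0.0  # unreachable

    def test_path_length_three_value(self):
        nodes = [Node(c, "inputs") for c in "abcd"]
        edges = [Edge("a", "b"), Edge("b", "c"), Edge("c", "d")]
        a0 = init_attention(SignalingNetwork(nodes, edges)).initial
        assert a0[0, 3] == 0.2

    def test_values_form_the_five_level_set(self, net):
        a0 = init_attention(net).initial
        assert set(np.unique(a0)) <= set(INIT_LEVELS.values()) | {0.0}

    def test_diagonal_all_ones(self, net):
        np.testing.assert_array_equal(np.diag(init_attention(net).initial), 1.0)


class TestLaggedPearson:
    def test_identical_series_lag_zero(self):
        x = np.array([0.1, 0.5, 0.2, 0.9, 0.4])
        assert lagged_pearson(x, x, 0) == pytest.approx(1.0)

    def test_perfect_lag_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.random(50)
        y = np.roll(x, 2)  # y(t+2) == x(t) on the overlap
        assert lagged_pearson(x, y, 2) == pytest.approx(1.0)

    def test_anticorrelated_hand_example(self):
        assert lagged_pearson(
            np.array([1.0, 2, 3, 4]), np.array([4.0, 3, 2, 1]), 0
        ) == pytest.approx(-1.0)

    def test_zero_variance_convention(self):
        assert lagged_pearson(np.ones(10), np.arange(10.0), 0) == 0.0

    def test_short_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            lagged_pearson(np.arange(4.0), np.arange(4.0), 2)

    def test_matrix_form_matches_scalar_oracle(self):
        rng = np.random.default_rng(1)
        data = rng.random((30, 4))
        mats = lagged_correlation_matrices(data, (0, 1, 2))
        for tau in (0, 1, 2):
            for i in range(4):
                for j in range(4):
                    assert mats[tau][i, j] == pytest.approx(
                        lagged_pearson(data[:, i], data[:, j], tau), abs=1e-12
                    )


class TestRefineAttention:
    def test_self_attention_stays_one(self, net, dataset):
        refined = refine_attention(init_attention(net), dataset).refined
        np.testing.assert_allclose(np.diag(refined), 1.0)

    def test_blend_formula_against_brute_force(self):
        """0.3*A0 + 0.7*max_tau(mean-over-conditions R), clamped to [0,1]."""
        rng = np.random.default_rng(2)
        nodes = [Node(f"s{i}", "inputs") for i in range(5)]
        netx = SignalingNetwork(nodes, [Edge("s0", "s1"), Edge("s1", "s2")])
        cube = rng.random((3, 25, 5))
        ds = TimeSeriesDataset(["c1", "c2", "c3"], cube, [n.id for n in nodes])
        a0 = init_attention(netx)
        refined = refine_attention(a0, ds).refined
        for i in range(5):
            for j in range(5):
                rs = []
                for tau in (0, 1, 2):
                    per_cond = [
                        lagged_pearson(cube[c, :, i], cube[c, :, j], tau)
                        for c in range(3)
                    ]
                    rs.append(np.mean(per_cond))
                expected = np.clip(0.3 * a0.initial[i, j] + 0.7 * max(rs), 0, 1)
                assert refined[i, j] == pytest.approx(expected, abs=1e-12)

    def test_anticorrelated_nonadjacent_pair_clamps_to_zero(self):
        nodes = [Node("x", "inputs"), Node("y", "inputs")]
        netx = SignalingNetwork(nodes, [])
        t = np.linspace(0, 1, 30)
        cube = np.stack([0.2 + 0.5 * t, 0.8 - 0.5 * t], axis=1)[None, ...]
        ds = TimeSeriesDataset(["c"], cube, ["x", "y"])
        refined = refine_attention(init_attention(netx), ds).refined
        assert refined[0, 1] == 0.0

    def test_noise_dataset_shrinks_toward_structural_prior(self, chain_net):
        """With pure noise, refinement adds only the small max-of-lags bias."""
        excess = []
        for t_len in (20, 200):
            rng = np.random.default_rng(0)
            cube = rng.random((4, t_len, 3))
            ds = TimeSeriesDataset(list("wxyz"), cube, ["a", "b", "c"])
            a0 = init_attention(chain_net)
            refined = refine_attention(a0, ds).refined
            off = ~np.eye(3, dtype=bool)
            excess.append((refined - 0.3 * a0.initial)[off].mean())
        assert excess[0] > 0  # max over lags has positive expectation
        assert excess[1] < excess[0]  # shrinks as series grow


class TestPathwayAttention:
    def test_singleton_modules_reduce_to_entry(self, chain_net):
        a0 = init_attention(chain_net)
        pa = pathway_attention(a0, {"ma": ["a"], "mb": ["b"]})
        assert pa.get("ma", "mb") == pytest.approx(0.8)

    def test_uniform_matrix_is_mean_preserving(self):
        mat = np.full((4, 4), 0.37)
        pa = pathway_attention(
            mat, {"g1": ["a", "b"], "g2": ["c", "d"]}, species=list("abcd")
        )
        np.testing.assert_allclose(pa.matrix, 0.37)

    def test_block_mean_hand_example(self):
        mat = np.array([[0.2, 0.4], [0.6, 0.8]])
        pa = pathway_attention(mat, {"g": ["a", "b"]}, species=["a", "b"])
        assert pa.get("g", "g") == pytest.approx(0.5)

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            pathway_attention(np.eye(2), {"g": []}, species=["a", "b"])


class TestAttentionGraph:
    def test_all_below_threshold_gives_empty_graph(self):
        g = attention_graph(np.full((3, 3), 0.1), 0.3, species=list("abc"))
        assert g.number_of_edges() == 0

    def test_zero_threshold_keeps_all_offdiagonal(self):
        g = attention_graph(np.full((3, 3), 0.5), 0.0, species=list("abc"))
        assert g.number_of_edges() == 6

    def test_retained_weights_exceed_threshold(self, net, dataset):
        refined = refine_attention(init_attention(net), dataset)
        g = attention_graph(refined, threshold=0.3)
        assert g.number_of_edges() > 0
        assert all(d["attention"] > 0.3 for _, _, d in g.edges(data=True))
        assert all("degree_centrality" in g.nodes[n] for n in g.nodes)


@pytest.fixture(scope="module")
def small_case():
    nodes = [
        Node("in", "inputs"),
        Node("r", "receptors", "receptor"),
        Node("k", "kinases"),
        Node("tf", "transcription_factors", "transcription-factor"),
        Node("o1", "ecm_fibrosis"),
        Node("o2", "ecm_fibrosis"),
    ]
    edges = [
        Edge("in", "r", 1, 0.15),
        Edge("r", "k", 1, 0.25),
        Edge("k", "tf", 1, 0.3),
        Edge("tf", "o1", 1, 0.25),
        Edge("tf", "o2", 1, 0.25),
        Edge("o2", "k", -1, 0.05),
    ]
    netx = SignalingNetwork(nodes, edges)
    cfg = SimulationConfig(seed=4, n_timepoints=60)
    conds = [{"in": 0.05}, {"in": 1.0}]
    from hmlm.simulate import Condition, simulate

    cube = np.stack(
        [simulate(netx, cfg, Condition(n, c)) for n, c in zip(["lo", "hi"], conds)]
    )
    ds = TimeSeriesDataset(["lo", "hi"], cube, [n.id for n in nodes])
    refined = refine_attention(init_attention(netx), ds)
    return netx, ds, refined


class TestNullTest:
    def test_pvalues_respect_add_one_convention(self, small_case):
        netx, ds, refined = small_case
        out = attention_null_test(refined, netx, ds, n_boot=100, seed=0)
        assert (out["p"] >= 1 / 101 - 1e-12).all()
        assert (out["p"] <= 1.0).all()

    def test_reproducible_given_seed(self, small_case):
        netx, ds, refined = small_case
        a = attention_null_test(refined, netx, ds, n_boot=100, seed=3)
        b = attention_null_test(refined, netx, ds, n_boot=100, seed=3)
        np.testing.assert_array_equal(a["p"], b["p"])

    def test_strong_direct_edge_ranks_best_against_null(self, small_case):
        """On a toy net the rewiring space is tiny, so check the ordering:
        the strong direct edge gets the smallest p-value of all pairs."""
        netx, ds, refined = small_case
        out = attention_null_test(refined, netx, ds, n_boot=199, seed=1)
        off = out[out.source != out.target]
        best = off.sort_values("p").iloc[0]
        assert (best.source, best.target) == ("r", "k")
        assert best.p < 0.1

    def test_small_n_boot_rejected(self, small_case):
        netx, ds, refined = small_case
        with pytest.raises(ValueError, match="n_boot"):
            attention_null_test(refined, netx, ds, n_boot=10)
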