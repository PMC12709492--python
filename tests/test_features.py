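"""Temporal feature engineering: derivatives, memory, correlations, tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmlm.attention import init_attention, refine_attention
from hmlm.features import (
    ALL_FEATURES,
    FeatureTable,
    build_feature_table,
    build_targets,
    max_lag_correlation,
    memory_state,
    temporal_derivative,
)
from hmlm.network import Edge, Node, SignalingNetwork, spectral_positional_embedding
from hmlm.simulate import TimeSeriesDataset


class TestTemporalDerivative:
    def test_linear_series_constant_slope(self):
        series = 0.3 * np.arange(10.0)
        np.testing.assert_allclose(temporal_derivative(series, dt=1.0), 0.3)

    def test_constant_series_zero(self):
        np.testing.assert_allclose(temporal_derivative(np.full(6, 0.4)), 0.0)

    def test_central_difference_hand_example(self):
        d = temporal_derivative(np.array([0.0, 1.0, 4.0, 9.0]), dt=1.0)
        np.testing.assert_allclose(d[1:3], [2.0, 4.0])  # (4-0)/2, (9-1)/2
        np.testing.assert_allclose(d[0], 1.0)  # forward difference
        np.testing.assert_allclose(d[3], 5.0)  # backward difference

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            temporal_derivative(np.array([1.0, 2.0]))

    def test_derivative_of_cumulative_integral_recovers_series(self):
        dt = 0.05
        t = np.arange(0, 3, dt)
        series = np.sin(t)
        integral = np.cumsum(series) * dt
        recovered = temporal_derivative(integral, dt=dt)
        # the rectangle-rule integral carries a half-step phase: the central
        # difference recovers the series at midpoints within O(dt^2)
        midpoint = np.sin(t + dt / 2)
        np.testing.assert_allclose(recovered[1:-1], midpoint[1:-1], atol=5 * dt**2)


class TestMemoryState:
    def test_hand_recursion(self):
        np.testing.assert_allclose(
            memory_state(np.array([1.0, 0.0, 0.0]), alpha=0.3), [1.0, 0.7, 0.49]
        )

    def test_constant_series_fixed_point(self):
        np.testing.assert_allclose(memory_state(np.full(8, 0.42)), 0.42)

    def test_alpha_one_is_identity(self):
        x = np.random.default_rng(0).random(20)
        np.testing.assert_allclose(memory_state(x, alpha=1.0), x)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            memory_state(np.ones(3), alpha=0.0)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_convex_combination_bounds(self, xs):
        m = memory_state(np.array(xs))
        assert m.min() >= min(xs) - 1e-12
        assert m.max() <= max(xs) + 1e-12


class TestMaxLagCorrelation:
    @pytest.fixture()
    def tiny(self):
        nodes = [Node("a", "inputs"), Node("b", "receptors", "receptor"), Node("c", "kinases")]
        netx = SignalingNetwork(nodes, [Edge("a", "b"), Edge("b", "c")])
        rng = np.random.default_rng(0)
        base = rng.random(30)
        cube = np.stack([base, np.roll(base, 1), rng.random(30)], axis=1)[None, ...]
        return netx, TimeSeriesDataset(["c1"], np.clip(cube, 0, 1), ["a", "b", "c"])

    def test_perfect_lag_one_neighbor(self, tiny):
        netx, ds = tiny
        out = max_lag_correlation(ds, netx)
        val = out[(out.species == "a")]["max_lag_corr"].iloc[0]
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_isolated_node_convention(self):
        nodes = [Node("a", "inputs"), Node("b", "inputs")]
        netx = SignalingNetwork(nodes, [])
        cube = np.random.default_rng(1).random((1, 20, 2))
        ds = TimeSeriesDataset(["c"], cube, ["a", "b"])
        out = max_lag_correlation(ds, netx)
        assert (out["max_lag_corr"] == 0.0).all()

    def test_matches_brute_force_scan(self, tiny):
        from hmlm.attention import lagged_pearson

        netx, ds = tiny
        out = max_lag_correlation(ds, netx)
        neighbors = {"a": ["b"], "b": ["a", "c"], "c": ["b"]}
        for sp, nbrs in neighbors.items():
            best = max(
                lagged_pearson(ds.series("c1", sp), ds.series("c1", j), tau)
                for j in nbrs
                for tau in (0, 1, 2, 3)
            )
            got = out[out.species == sp]["max_lag_corr"].iloc[0]
            assert got == pytest.approx(best, abs=1e-12)


@pytest.fixture(scope="module")
def table_inputs(net, dataset):
    emb = spectral_positional_embedding(net, k=4)
    att = refine_attention(init_attention(net), dataset)
    return net, dataset, att, emb


class TestBuildFeatureTable:
    def test_row_count_and_no_missing(self, table_inputs):
        net, dataset, att, emb = table_inputs
        table = build_feature_table(dataset, net, att, emb)
        assert len(table.frame) == 4 * 100 * 132
        assert not table.frame[list(ALL_FEATURES)].isna().any().any()

    def test_cellular_mean_equals_grand_mean(self, table_inputs):
        net, dataset, att, emb = table_inputs
        table = build_feature_table(dataset, net, att, emb, times=np.array([7]))
        for c in dataset.conditions:
            sub = table.frame[table.frame.condition == c]
            assert sub["global_mean"].iloc[0] == pytest.approx(
                dataset.get(c)[7].mean()
            )
            assert sub["fibrosis_index"].iloc[0] == pytest.approx(
                dataset.get(c)[7][
                    [i for i, s in enumerate(dataset.species) if net.node(s).module == "ecm_fibrosis"]
                ].mean()
            )

    def test_uniform_activities_give_uniform_attention_feature(self, chain_net):
        cube = np.full((1, 20, 3), 0.6)
        ds = TimeSeriesDataset(["c"], cube, ["a", "b", "c"])
        att = refine_attention(init_attention(chain_net), ds)
        # constant series -> correlations 0 -> refined = 0.3*A0; direct edges
        # survive the significance cut only if above threshold, so force the
        # initial matrix as refined for this check
        att.refined = att.initial
        emb = spectral_positional_embedding(chain_net, k=1)
        table = build_feature_table(ds, chain_net, att, emb)
        attended = table.frame[table.frame.species.isin(["b", "c"])]["attn_neighbor"]
        np.testing.assert_allclose(attended, 0.6)

    def test_single_species_pathway_block_equals_activity(self):
        netx = SignalingNetwork([Node("x", "kinases")], [])
        rng = np.random.default_rng(0)
        ds = TimeSeriesDataset(["c"], rng.random((1, 15, 1)), ["x"])
        att = refine_attention(init_attention(netx), ds)
        emb_dummy = spectral_positional_embedding  # no eigenvectors for n=1
        from hmlm.network import EmbeddingTable

        emb = EmbeddingTable(["x"], np.zeros((1, 5)), np.zeros((1, 0)), np.zeros((1, 4)))
        table = build_feature_table(ds, netx, att, emb)
        np.testing.assert_allclose(
            table.frame["module_mean_activity"], table.frame["activity"]
        )

    def test_species_mismatch_reported(self, table_inputs, chain_net):
        net, dataset, att, emb = table_inputs
        cube = np.zeros((1, 10, 3))
        ds_small = TimeSeriesDataset(["c"], cube, ["a", "b", "c"])
        with pytest.raises(ValueError, match="network"):
            build_feature_table(ds_small, net, att, emb)

    def test_csv_round_trip(self, table_inputs, tmp_path):
        net, dataset, att, emb = table_inputs
        table = build_feature_table(dataset, net, att, emb, times=np.arange(3))
        path = tmp_path / "features.csv"
        table.to_csv(path)
        back = FeatureTable.from_csv(path)
        pd.testing.assert_frame_equal(
            back.frame[list(ALL_FEATURES)],
            table.frame[list(ALL_FEATURES)].reset_index(drop=True),
            atol=1e-9,
            check_dtype=False,
        )


class TestBuildTargets:
    def test_row_count_per_series(self, dataset):
        targets = build_targets(dataset, horizon=1)
        assert len(targets) == 4 * 99 * 132

    def test_shift_matches_manual_slicing(self, dataset):
        targets = build_targets(dataset, horizon=2)
        sub = targets[(targets.condition == "tgfb") & (targets.species == "SMAD3")]
        np.testing.assert_allclose(
            sub.sort_values("time")["target"].to_numpy(),
            dataset.series("tgfb", "SMAD3")[2:],
        )

    def test_horizon_bounds(self, dataset):
        with pytest.raises(ValueError):
            build_targets(dataset, horizon=0)
        with pytest.raises(ValueError):
            build_targets(dataset, horizon=100)
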