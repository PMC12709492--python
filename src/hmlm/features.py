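"""Multi-scale temporal feature engineering for the ensemble predictor.

For every (condition, species, timepoint) row the table carries three
feature blocks, one per biological scale:

* molecular — current activity ``x_i(t)``, its central-difference temporal
  derivative, the maximum lagged correlation with any network neighbor
  (lags 0-3), the exponentially weighted memory state ``M_i(t)`` with decay
  ``alpha = 0.3``, the attention-weighted activity of the other species, and
  the spectral positional-embedding components scaled by current activity;
* pathway — mean activity and mean derivative of the species' functional
  module;
* cellular — global network statistics: mean activity, activity variance,
  and the fibrosis index (mean activity of the ECM/fibrosis module).

The supervision target for next-step prediction is the activity at
``t + horizon``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attention import AttentionMatrices, lagged_correlation_matrices
from .network import EmbeddingTable, SignalingNetwork, adjacency_matrix
from .simulate import TimeSeriesDataset

__all__ = [
    "FeatureTable",
    "MOLECULAR_FEATURES",
    "PATHWAY_FEATURES",
    "CELLULAR_FEATURES",
    "temporal_derivative",
    "max_lag_correlation",
    "memory_state",
    "build_feature_table",
    "build_targets",
]

FEATURE_LAGS = (0, 1, 2, 3)
MEMORY_ALPHA = 0.3
N_EMBEDDING = 4
ATTN_THRESHOLD = 0.3


def _significant_attention(mat: np.ndarray) -> np.ndarray:
    """Zero the diagonal and sub-threshold links of an attention matrix."""
    attn = mat.copy()
    np.fill_diagonal(attn, 0.0)
    attn[attn <= ATTN_THRESHOLD] = 0.0
    return attn

MOLECULAR_FEATURES = (
    "activity",
    "derivative",
    "max_lag_corr",
    "memory",
    "attn_neighbor",
) + tuple(f"emb{k}_x" for k in range(N_EMBEDDING))
PATHWAY_FEATURES = ("module_mean_activity", "module_mean_derivative")
CELLULAR_FEATURES = ("global_mean", "global_var", "fibrosis_index")

INDEX_COLUMNS = ("condition", "species", "time")
ALL_FEATURES = MOLECULAR_FEATURES + PATHWAY_FEATURES + CELLULAR_FEATURES


@dataclass
class FeatureTable:
    """Long-format feature table plus the scale -> column mapping."""

    frame: pd.DataFrame

    @property
    def blocks(self) -> dict[str, list[str]]:
        return {
            "molecular": list(MOLECULAR_FEATURES),
            "pathway": list(PATHWAY_FEATURES),
            "cellular": list(CELLULAR_FEATURES),
        }

    def to_csv(self, path) -> None:
        cols = list(INDEX_COLUMNS) + list(ALL_FEATURES)
        extra = [c for c in self.frame.columns if c not in cols]
        self.frame[cols + extra].to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path))


def temporal_derivative(series: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Central-difference derivative, one-sided at the two endpoints."""
    x = np.asarray(series, dtype=float)
    if x.ndim == 0 or x.shape[-1] < 3:
        raise ValueError("series must contain at least 3 points")
    return np.gradient(x, dt, axis=-1)


def memory_state(series: np.ndarray, alpha: float = MEMORY_ALPHA) -> np.ndarray:
    """Exponentially weighted memory: M(t) = alpha*x(t) + (1-alpha)*M(t-1).

    Initialized at M(0) = x(0).  ``alpha`` in (0, 1]; alpha = 1 reduces to
    the raw series.  Works on the last axis of a 1-d or 2-d input.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    x = np.atleast_2d(np.asarray(series, dtype=float))
    m = np.empty_like(x)
    m[:, 0] = x[:, 0]
    for t in range(1, x.shape[1]):
        m[:, t] = alpha * x[:, t] + (1 - alpha) * m[:, t - 1]
    return m.reshape(np.asarray(series, dtype=float).shape)


def max_lag_correlation(
    dataset: TimeSeriesDataset,
    net: SignalingNetwork,
    lags: tuple[int, ...] = FEATURE_LAGS,
) -> pd.DataFrame:
    """Per-(condition, species) max lagged correlation with network neighbors.

    For species i the scalar feature is the maximum over its neighbors j
    (either edge direction) and over ``lags`` of the Pearson correlation
    between x_i(t) and x_j(t + tau).  Isolated species yield 0.
    """
    adj = adjacency_matrix(net)
    neighbor = (adj + adj.T) > 0
    np.fill_diagonal(neighbor, False)
    rows = []
    for c, cname in enumerate(dataset.conditions):
        mats = lagged_correlation_matrices(dataset.activity[c], lags)
        stacked = np.max(np.stack([mats[tau] for tau in lags]), axis=0)
        masked = np.where(neighbor, stacked, -np.inf)
        best = masked.max(axis=1)
        best[~neighbor.any(axis=1)] = 0.0
        for s, sp in enumerate(dataset.species):
            rows.append((cname, sp, float(best[s])))
    return pd.DataFrame(rows, columns=["condition", "species", "max_lag_corr"])


def build_feature_table(
    dataset: TimeSeriesDataset,
    net: SignalingNetwork,
    attention: AttentionMatrices,
    embeddings: EmbeddingTable,
    times: np.ndarray | None = None,
) -> FeatureTable:
    """Assemble the molecular/pathway/cellular feature blocks.

    ``times`` restricts the rows to a subset of timepoint indices (all by
    default).  The attention-weighted neighbor activity of species i
    aggregates the species that attend to i (A[u, i] scores how informative
    u is for predicting i): ``sum_u A_ui x_u(t) / sum_u A_ui`` over u != i,
    restricted to significant attention links (A > 0.3, the attention-graph
    threshold) so the aggregate reflects i's regulators rather than a
    network-wide average.
    """
    _check_species(dataset, net, attention, embeddings)
    mat = attention.refined if attention.refined is not None else attention.initial
    pos = embeddings.positional_block[:, :N_EMBEDDING]
    if pos.shape[1] < N_EMBEDDING:  # narrow embeddings: zero-pad the schema
        pos = np.pad(pos, ((0, 0), (0, N_EMBEDDING - pos.shape[1])))
    n_cond, n_t, n_sp = dataset.activity.shape
    if times is None:
        times = np.arange(n_t)
    times = np.asarray(times, dtype=int)

    module_of = np.array([net.node(s).module for s in dataset.species])
    modules = sorted(set(module_of))
    module_masks = {m: module_of == m for m in modules}
    fibrosis_mask = module_masks.get("ecm_fibrosis", np.zeros(n_sp, dtype=bool))

    attn = _significant_attention(mat)
    attn_colsum = attn.sum(axis=0)  # attention mass placed on species i

    corr_table = max_lag_correlation(dataset, net)
    corr_lookup = corr_table.set_index(["condition", "species"])["max_lag_corr"]

    frames = []
    for c, cname in enumerate(dataset.conditions):
        x = dataset.activity[c]  # (T, S)
        dx = temporal_derivative(x.T, dataset.dt).T
        mem = memory_state(x.T).T
        # attention-weighted activity informing species j: weighted mean of
        # the other species' activities with weights A[., j]
        with np.errstate(invalid="ignore", divide="ignore"):
            attn_act = np.where(attn_colsum > 0, (x @ attn) / attn_colsum, 0.0)
        g_mean = x.mean(axis=1)
        g_var = x.var(axis=1)
        fib = x[:, fibrosis_mask].mean(axis=1) if fibrosis_mask.any() else np.zeros(n_t)
        mod_mean = {m: x[:, module_masks[m]].mean(axis=1) for m in modules}
        mod_dmean = {m: dx[:, module_masks[m]].mean(axis=1) for m in modules}

        t_idx = np.repeat(times, n_sp)
        s_idx = np.tile(np.arange(n_sp), times.size)
        df = pd.DataFrame(
            {
                "condition": cname,
                "species": np.array(dataset.species)[s_idx],
                "time": t_idx,
                "activity": x[t_idx, s_idx],
                "derivative": dx[t_idx, s_idx],
                "max_lag_corr": corr_lookup.loc[
                    [(cname, sp) for sp in np.array(dataset.species)[s_idx]]
                ].to_numpy(),
                "memory": mem[t_idx, s_idx],
                "attn_neighbor": attn_act[t_idx, s_idx],
            }
        )
        for k in range(N_EMBEDDING):
            df[f"emb{k}_x"] = pos[s_idx, k] * x[t_idx, s_idx]
        mod_mean_arr = np.stack([mod_mean[m] for m in modules])
        mod_dmean_arr = np.stack([mod_dmean[m] for m in modules])
        mod_pos = np.searchsorted(modules, module_of)
        df["module_mean_activity"] = mod_mean_arr[mod_pos[s_idx], t_idx]
        df["module_mean_derivative"] = mod_dmean_arr[mod_pos[s_idx], t_idx]
        df["global_mean"] = g_mean[t_idx]
        df["global_var"] = g_var[t_idx]
        df["fibrosis_index"] = fib[t_idx]
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    if table[list(ALL_FEATURES)].isna().any().any():
        raise ValueError("feature table contains missing values")
    return FeatureTable(table)


def build_targets(dataset: TimeSeriesDataset, horizon: int = 1) -> pd.DataFrame:
    """Next-step supervision: target(c, i, t) = activity(c, i, t + horizon)."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if horizon >= dataset.n_timepoints:
        raise ValueError(
            f"horizon {horizon} must be smaller than n_timepoints "
            f"{dataset.n_timepoints}"
        )
    n_cond, n_t, n_sp = dataset.activity.shape
    usable = np.arange(n_t - horizon)
    frames = []
    for c, cname in enumerate(dataset.conditions):
        t_idx = np.repeat(usable, n_sp)
        s_idx = np.tile(np.arange(n_sp), usable.size)
        frames.append(
            pd.DataFrame(
                {
                    "condition": cname,
                    "species": np.array(dataset.species)[s_idx],
                    "time": t_idx,
                    "target": dataset.activity[c, t_idx + horizon, s_idx],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _check_species(
    dataset: TimeSeriesDataset,
    net: SignalingNetwork,
    attention: AttentionMatrices,
    embeddings: EmbeddingTable,
) -> None:
    offenders = []
    for name, order in (
        ("network", net.species),
        ("attention", attention.species),
        ("embeddings", embeddings.species),
    ):
        if list(order) != list(dataset.species):
            offenders.append(name)
    if offenders:
        raise ValueError(
            "species order mismatch with dataset in: " + ", ".join(offenders)
        )
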