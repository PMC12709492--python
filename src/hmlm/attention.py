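"""Topology-initialized, correlation-refined attention between species.

The attention weight A[i, j] scores how informative species i is for
predicting species j.  It is initialized purely from graph distance,

    A0[i, j] = 1.0 (i == j), 0.8 (direct edge), 0.4 (shortest path 2),
               0.2 (shortest path 3), 0.0 otherwise,

and refined with lagged temporal correlations observed in the data,

    A[i, j] = clip01( 0.3 * A0[i, j] + 0.7 * max_{tau in {0,1,2}} R_ij(tau) ),

where R_ij(tau) is the Pearson correlation between x_i(t) and x_j(t + tau),
computed per condition and averaged over conditions before the max (pooling
conditions by concatenation would manufacture correlation from condition
offsets).  Pathway-level attention averages A over all ordered cross-module
species pairs.  Significance is assessed against nulls with degree-preserving
randomized connectivity on bootstrap-resampled temporal profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import SignalingNetwork, path_length_matrix
from .simulate import TimeSeriesDataset

__all__ = [
    "AttentionMatrices",
    "PathwayAttention",
    "init_attention",
    "lagged_pearson",
    "lagged_correlation_matrices",
    "refine_attention",
    "pathway_attention",
    "attention_graph",
    "attention_null_test",
]

INIT_LEVELS = {0: 1.0, 1: 0.8, 2: 0.4, 3: 0.2}
REFINE_LAGS = (0, 1, 2)
STRUCTURE_WEIGHT = 0.3
CORRELATION_WEIGHT = 0.7


@dataclass
class AttentionMatrices:
    """Initial (topology) and refined (topology + correlation) attention."""

    species: list[str]
    initial: np.ndarray
    refined: np.ndarray | None = None
    lags: tuple[int, ...] = REFINE_LAGS

    def to_frame(self, which: str = "refined") -> pd.DataFrame:
        mat = self.refined if which == "refined" else self.initial
        if mat is None:
            raise ValueError(f"{which} attention not computed")
        return pd.DataFrame(mat, index=self.species, columns=self.species)


@dataclass
class PathwayAttention:
    """Module-pair attention: mean molecular attention over ordered pairs."""

    modules: list[str]
    matrix: np.ndarray
    module_sizes: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.modules, columns=self.modules)

    def get(self, source_module: str, target_module: str) -> float:
        return float(
            self.matrix[self.modules.index(source_module), self.modules.index(target_module)]
        )


def init_attention(net: SignalingNetwork) -> AttentionMatrices:
    """Topology-based attention initialization from capped path lengths."""
    dist = path_length_matrix(net, max_len=3)
    a0 = np.zeros(dist.shape)
    for d, level in INIT_LEVELS.items():
        a0[dist == d] = level
    np.fill_diagonal(a0, 1.0)
    return AttentionMatrices(list(net.species), a0)


def lagged_pearson(x: np.ndarray, y: np.ndarray, tau: int) -> float:
    """Pearson correlation of x(t) against y(t + tau) on the overlap.

    Means and variances are computed on the overlapping segment.  Series
    with zero variance on the overlap yield 0 (not NaN): constant control
    trajectories must not poison the max over lags.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = x.size - tau
    if n < 3:
        raise ValueError("overlap after shifting must contain >= 3 points")
    xs = x[: x.size - tau] if tau else x
    ys = y[tau:]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    denom = np.sqrt((xs**2).sum() * (ys**2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((xs * ys).sum() / denom, -1.0, 1.0))


def lagged_correlation_matrices(
    data: np.ndarray, lags: tuple[int, ...] = REFINE_LAGS
) -> dict[int, np.ndarray]:
    """All-pairs R_ij(tau) for one condition matrix (time x species).

    Vectorized equivalent of :func:`lagged_pearson` applied to every ordered
    species pair; zero-variance columns produce 0 rows/columns.
    """
    out: dict[int, np.ndarray] = {}
    t = data.shape[0]
    for tau in lags:
        a = data[: t - tau] if tau else data
        b = data[tau:]
        za = a - a.mean(axis=0)
        zb = b - b.mean(axis=0)
        sa = np.sqrt((za**2).sum(axis=0))
        sb = np.sqrt((zb**2).sum(axis=0))
        sa[sa == 0] = np.inf  # zero-variance convention: correlation 0
        sb[sb == 0] = np.inf
        r = (za / sa).T @ (zb / sb)
        out[tau] = np.clip(r, -1.0, 1.0)
    return out


def refine_attention(
    initial: AttentionMatrices,
    dataset: TimeSeriesDataset,
    lags: tuple[int, ...] = REFINE_LAGS,
) -> AttentionMatrices:
    """Blend topological attention with max lagged correlation (0.3 / 0.7).

    Correlations are computed per condition, averaged across conditions, the
    max taken over ``lags``, and the blend clamped to [0, 1].
    """
    if initial.species != dataset.species:
        raise ValueError("attention and dataset species orders differ")
    n_cond = len(dataset.conditions)
    mean_r = {tau: np.zeros(initial.initial.shape) for tau in lags}
    for c in range(n_cond):
        mats = lagged_correlation_matrices(dataset.activity[c], lags)
        for tau in lags:
            mean_r[tau] += mats[tau] / n_cond
    max_r = np.max(np.stack([mean_r[tau] for tau in lags]), axis=0)
    refined = np.clip(
        STRUCTURE_WEIGHT * initial.initial + CORRELATION_WEIGHT * max_r, 0.0, 1.0
    )
    return AttentionMatrices(initial.species, initial.initial, refined, tuple(lags))


def pathway_attention(
    attention: AttentionMatrices | np.ndarray,
    module_map: dict[str, set[str] | list[str]],
    species: list[str] | None = None,
) -> PathwayAttention:
    """Aggregate molecular attention to module (pathway) pairs.

    ``P[k, l]`` is the mean of ``A[i, j]`` over i in module k, j in module l
    (ordered pairs, normalization 1 / (|M_k| * |M_l|)).  ``module_map`` may be
    any grouping of species — the 11 structural modules or a custom pathway
    grouping.
    """
    if isinstance(attention, AttentionMatrices):
        mat = attention.refined if attention.refined is not None else attention.initial
        species = attention.species
    else:
        mat = np.asarray(attention)
        if species is None:
            raise ValueError("species order required with a bare matrix")
    idx = {s: k for k, s in enumerate(species)}
    modules = sorted(module_map)
    sizes: dict[str, int] = {}
    index_sets: dict[str, np.ndarray] = {}
    for m in modules:
        members = [idx[s] for s in module_map[m] if s in idx]
        if not members:
            raise ValueError(f"module {m!r} has no members in the species set")
        index_sets[m] = np.array(members)
        sizes[m] = len(members)
    p = np.zeros((len(modules), len(modules)))
    for a, ma in enumerate(modules):
        for b, mb in enumerate(modules):
            p[a, b] = mat[np.ix_(index_sets[ma], index_sets[mb])].mean()
    return PathwayAttention(modules, p, sizes)


def attention_graph(
    attention: AttentionMatrices | np.ndarray,
    threshold: float = 0.3,
    species: list[str] | None = None,
) -> nx.DiGraph:
    """Thresholded attention graph with degree-centrality node annotations.

    Keeps off-diagonal ordered pairs with attention strictly above
    ``threshold``; edge attribute ``attention`` carries the weight.
    """
    if isinstance(attention, AttentionMatrices):
        mat = attention.refined if attention.refined is not None else attention.initial
        species = attention.species
    else:
        mat = np.asarray(attention)
        if species is None:
            raise ValueError("species order required with a bare matrix")
    g = nx.DiGraph()
    g.add_nodes_from(species)
    n = len(species)
    for i in range(n):
        for j in range(n):
            if i != j and mat[i, j] > threshold:
                g.add_edge(species[i], species[j], attention=float(mat[i, j]))
    centrality = nx.degree_centrality(g)
    nx.set_node_attributes(g, centrality, "degree_centrality")
    return g


def _rewire_degree_preserving(
    net: SignalingNetwork, rng: np.random.Generator
) -> SignalingNetwork:
    """Randomize connectivity while preserving in- and out-degrees."""
    from .network import Edge

    edges = list(net.edges)
    n_edges = len(edges)
    pairs = {(e.source, e.target) for e in edges}
    n_swaps = 0
    attempts = 0
    # aim for ~2 successful swaps per edge
    while n_swaps < 2 * n_edges and attempts < 40 * n_edges:
        attempts += 1
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        e1, e2 = edges[i], edges[j]
        a, b = (e1.source, e2.target), (e2.source, e1.target)
        if a[0] == a[1] or b[0] == b[1] or a in pairs or b in pairs:
            continue
        pairs.discard((e1.source, e1.target))
        pairs.discard((e2.source, e2.target))
        pairs.update([a, b])
        edges[i] = Edge(a[0], a[1], e1.sign, e1.weight)
        edges[j] = Edge(b[0], b[1], e2.sign, e2.weight)
        n_swaps += 1
    return SignalingNetwork(net.nodes, edges)


def attention_null_test(
    refined: AttentionMatrices,
    net: SignalingNetwork,
    dataset: TimeSeriesDataset,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical per-pair p-values against randomized-connectivity nulls.

    Each of ``n_boot`` null draws rewires the network degree-preservingly,
    re-initializes attention from the rewired topology, and re-refines it on
    a dataset whose timepoints are bootstrap-resampled (jointly across
    species, per condition).  The p-value for pair (i, j) is the add-one
    fraction ``(1 + #{null >= observed}) / (n_boot + 1)``.

    Returns a long-format frame with columns source, target, observed, p.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if refined.refined is None:
        raise ValueError("refined attention required")
    rng = np.random.default_rng(seed)
    obs = refined.refined
    exceed = np.zeros(obs.shape)
    t = dataset.n_timepoints
    for _ in range(n_boot):
        null_net = _rewire_degree_preserving(net, rng)
        a0 = init_attention(null_net)
        take = rng.integers(0, t, size=t)
        resampled = TimeSeriesDataset(
            list(dataset.conditions),
            dataset.activity[:, take, :].copy(),
            list(dataset.species),
            dataset.dt,
        )
        null = refine_attention(a0, resampled, refined.lags).refined
        exceed += null >= obs
    pvals = (1.0 + exceed) / (n_boot + 1.0)
    n = len(refined.species)
    src, tgt = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return pd.DataFrame(
        {
            "source": [refined.species[i] for i in src.ravel()],
            "target": [refined.species[j] for j in tgt.ravel()],
            "observed": obs.ravel(),
            "p": pvals.ravel(),
        }
    )
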