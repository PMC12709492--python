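"""Comparison models sharing the forecaster contract.

Four baseline families, each the canonical minimal representative of its
class, trained and evaluated on exactly the same datasets as the ensemble:

* ``ode`` — the mechanistic baseline: per-module integration/degradation
  rates estimated by least squares against observed one-step differences
  under the network's structural form (signed weighted-sum input
  integration, first-order kinetics);
* ``lde`` — linear difference equations: one ridge-regularized linear map
  ``x(t+1) = B x(t) + c``;
* ``gnn`` — a topology-aware regressor: one random forest on each species'
  own activity plus mean/max in-neighbor activities at t and t-1 (one round
  of neighborhood aggregation);
* ``bayes`` — a discrete Bayesian network: activities discretized into
  equal-frequency bins, conditional probability tables (add-one smoothing)
  over up to 3 highest-weight parents, prediction = expected bin value;
* ``mean`` — the mean predictor, as a floor control.

Every model implements ``fit(net, dataset)``, ``one_step_frame/mse`` and
``rollout`` with the same semantics as the ensemble forecaster, so the
benchmark harness cannot distinguish model kinds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge

from .network import SignalingNetwork, adjacency_matrix, weighted_adjacency
from .simulate import TimeSeriesDataset

__all__ = [
    "BaselineModel",
    "ODEBaseline",
    "LDEBaseline",
    "GNNBaseline",
    "BayesBaseline",
    "MeanBaseline",
    "make_model",
    "MODEL_KINDS",
]


class BaselineModel:
    """Shared one-step evaluation and rollout plumbing."""

    kind = "base"

    def fit(self, net: SignalingNetwork, dataset: TimeSeriesDataset):
        raise NotImplementedError

    def _predict_cube(self, dataset: TimeSeriesDataset) -> np.ndarray:
        """Predictions of x(t+1) from observed history; shape (C, T-1, S)."""
        raise NotImplementedError

    def predict_tip(self, history: np.ndarray) -> np.ndarray:
        """Next-state prediction from a (T_so_far, S) trajectory."""
        raise NotImplementedError

    def one_step_frame(
        self, dataset: TimeSeriesDataset, times: np.ndarray | None = None
    ) -> pd.DataFrame:
        cube = self._predict_cube(dataset)
        n_c, n_tm1, n_s = cube.shape
        if times is None:
            times = np.arange(n_tm1)
        times = np.asarray([t for t in np.asarray(times) if t < n_tm1], dtype=int)
        rows = []
        for c, cname in enumerate(dataset.conditions):
            t_idx = np.repeat(times, n_s)
            s_idx = np.tile(np.arange(n_s), times.size)
            rows.append(
                pd.DataFrame(
                    {
                        "condition": cname,
                        "species": np.array(dataset.species)[s_idx],
                        "time": t_idx,
                        "prediction": cube[c, t_idx, s_idx],
                        "target": dataset.activity[c, t_idx + 1, s_idx],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def one_step_mse(
        self, dataset: TimeSeriesDataset, times: np.ndarray | None = None
    ) -> float:
        frame = self.one_step_frame(dataset, times)
        return float(np.mean((frame["prediction"] - frame["target"]) ** 2))

    def rollout(self, context: np.ndarray, horizon: int) -> np.ndarray:
        traj = np.asarray(context, dtype=float).copy()
        for _ in range(horizon):
            nxt = np.clip(self.predict_tip(traj), 0.0, 1.0)
            traj = np.vstack([traj, nxt])
        return traj


class ODEBaseline(BaselineModel):
    """Structurally well-specified baseline with estimated kinetic rates.

    With ``use_true_structure`` the signed edge weights of the network are
    used for input integration; otherwise only the topology is trusted and
    unit weights are assumed.  Rows where the observed transition was
    clipped at the activity bounds are excluded from the fit (the linear
    model does not hold there).
    """

    kind = "ode"

    def __init__(self, use_true_structure: bool = True, dt: float = 1.0):
        self.use_true_structure = use_true_structure
        self.dt = dt

    def fit(self, net: SignalingNetwork, dataset: TimeSeriesDataset):
        self.net_ = net
        w = weighted_adjacency(net)
        if not self.use_true_structure:
            w = np.sign(w)
        self.w_ = w
        self.input_mask_ = np.array([n.module == "inputs" for n in net.nodes])
        modules = [n.module for n in net.nodes]
        self.rates_ = {}
        self.ridge_fallback_ = False
        acts = dataset.activity
        omega = np.clip(np.einsum("cts,sv->ctv", acts, w), 0.0, 1.0)
        s_now = acts[:, :-1, :]
        s_next = acts[:, 1:, :]
        delta = s_next - s_now
        interior = (s_next > 1e-9) & (s_next < 1 - 1e-9)
        for m in sorted(set(modules)):
            cols = np.array([k for k, mm in enumerate(modules) if mm == m])
            if m == "inputs":
                continue
            o = omega[:, :-1, cols].ravel()
            s = s_now[:, :, cols].ravel()
            d = delta[:, :, cols].ravel()
            keep = interior[:, :, cols].ravel()
            x = np.column_stack([self.dt * o[keep], -self.dt * s[keep]])
            yv = d[keep]
            if x.shape[0] < 2 or np.linalg.matrix_rank(x.T @ x) < 2:
                coef = np.linalg.solve(
                    x.T @ x + 1e-6 * np.eye(2), x.T @ yv
                ) if x.shape[0] else np.zeros(2)
                self.ridge_fallback_ = True
            else:
                coef, *_ = np.linalg.lstsq(x, yv, rcond=None)
            self.rates_[m] = (max(float(coef[0]), 0.0), max(float(coef[1]), 0.0))
        self.k_int_ = np.array(
            [0.0 if mm == "inputs" else self.rates_[mm][0] for mm in modules]
        )
        self.k_deg_ = np.array(
            [0.0 if mm == "inputs" else self.rates_[mm][1] for mm in modules]
        )
        return self

    def predict_tip(self, history: np.ndarray) -> np.ndarray:
        s = history[-1]
        omega = np.clip(self.w_.T @ s, 0.0, 1.0)
        nxt = s + self.dt * (self.k_int_ * omega - self.k_deg_ * s)
        nxt[self.input_mask_] = s[self.input_mask_]  # stimuli: persistence
        return np.clip(nxt, 0.0, 1.0)

    def _predict_cube(self, dataset: TimeSeriesDataset) -> np.ndarray:
        acts = dataset.activity[:, :-1, :]
        omega = np.clip(np.einsum("cts,sv->ctv", acts, self.w_), 0.0, 1.0)
        nxt = acts + self.dt * (self.k_int_ * omega - self.k_deg_ * acts)
        nxt[:, :, self.input_mask_] = acts[:, :, self.input_mask_]
        return np.clip(nxt, 0.0, 1.0)


class LDEBaseline(BaselineModel):
    """Linear difference equation x(t+1) = B x(t) + c (ridge, lambda=1e-3)."""

    kind = "lde"

    def __init__(self, alpha: float = 1e-3):
        self.alpha = alpha

    def fit(self, net: SignalingNetwork, dataset: TimeSeriesDataset):
        x = dataset.activity[:, :-1, :].reshape(-1, len(dataset.species))
        y = dataset.activity[:, 1:, :].reshape(-1, len(dataset.species))
        self.model_ = Ridge(alpha=self.alpha).fit(x, y)
        self.B_ = self.model_.coef_.T
        self.c_ = self.model_.intercept_
        return self

    def predict_tip(self, history: np.ndarray) -> np.ndarray:
        return np.clip(history[-1] @ self.B_ + self.c_, 0.0, 1.0)

    def _predict_cube(self, dataset: TimeSeriesDataset) -> np.ndarray:
        x = dataset.activity[:, :-1, :]
        return np.clip(x @ self.B_ + self.c_, 0.0, 1.0)


class GNNBaseline(BaselineModel):
    """One-hop neighborhood-aggregation features into a random forest."""

    kind = "gnn"

    def __init__(
        self,
        n_estimators: int = 150,
        max_depth: int = 12,
        max_samples: float | None = 0.33,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_samples = max_samples
        self.random_state = random_state

    def _neighbor_stats(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mean and max of in-neighbor activities; zeros for isolated nodes.

        ``x`` has species on the last axis.
        """
        adj = self.adj_
        deg = adj.sum(axis=0)
        mean = np.where(deg > 0, x @ adj / np.maximum(deg, 1), 0.0)
        mx = np.zeros_like(x)
        for v in range(adj.shape[0]):
            nbrs = np.flatnonzero(adj[:, v])
            if nbrs.size:
                mx[..., v] = x[..., nbrs].max(axis=-1)
        return mean, mx

    def _design(self, acts: np.ndarray) -> np.ndarray:
        """Rows for predicting t+1 from (t, t-1); acts shape (C, T, S)."""
        mean, mx = self._neighbor_stats(acts)
        now = np.stack([acts, mean, mx], axis=-1)  # (C, T, S, 3)
        prev = np.concatenate([now[:, :1], now[:, :-1]], axis=1)  # t-1 (edge: copy t=0)
        full = np.concatenate([now, prev], axis=-1)  # (C, T, S, 6)
        return full

    def fit(self, net: SignalingNetwork, dataset: TimeSeriesDataset):
        self.adj_ = adjacency_matrix(net).astype(float)
        acts = dataset.activity
        full = self._design(acts)
        x = full[:, :-1].reshape(-1, 6)
        y = acts[:, 1:, :].reshape(-1)
        self.model_ = RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            random_state=self.random_state,
            max_samples=self.max_samples,
            n_jobs=1,
        ).fit(x, y)
        return self

    def predict_tip(self, history: np.ndarray) -> np.ndarray:
        acts = history[None, -2:, :] if history.shape[0] >= 2 else history[None]
        full = self._design(acts)
        return np.clip(self.model_.predict(full[0, -1]), 0.0, 1.0)

    def _predict_cube(self, dataset: TimeSeriesDataset) -> np.ndarray:
        full = self._design(dataset.activity)[:, :-1]
        c, t, s, d = full.shape
        pred = self.model_.predict(full.reshape(-1, d))
        return np.clip(pred.reshape(c, t, s), 0.0, 1.0)


class BayesBaseline(BaselineModel):
    """Discrete Bayesian network over binned activities.

    Parents are the up-to-3 highest-|weight| regulators of each species;
    conditional probability tables over parent bin states at t predict the
    child's bin at t+1 with add-one smoothing; the prediction is the
    probability-weighted mean of bin representative values.
    """

    kind = "bayes"

    def __init__(self, n_bins: int = 3, max_parents: int = 3):
        self.n_bins = n_bins
        self.max_parents = max_parents

    def _bin(self, x: np.ndarray, s: int) -> np.ndarray:
        return np.clip(
            np.searchsorted(self.edges_[s], x, side="right") - 1, 0, self.n_bins - 1
        )

    def fit(self, net: SignalingNetwork, dataset: TimeSeriesDataset):
        w = np.abs(weighted_adjacency(net))
        n_s = len(dataset.species)
        acts = dataset.activity
        flat = acts.reshape(-1, n_s)
        qs = np.linspace(0, 1, self.n_bins + 1)[1:-1]
        self.edges_ = []
        self.mids_ = []
        for s in range(n_s):
            cuts = np.quantile(flat[:, s], qs)
            edges = np.concatenate([[-np.inf], cuts])
            self.edges_.append(edges)
            bins = np.clip(
                np.searchsorted(edges, flat[:, s], side="right") - 1, 0, self.n_bins - 1
            )
            mids = np.array(
                [
                    flat[bins == b, s].mean() if (bins == b).any() else flat[:, s].mean()
                    for b in range(self.n_bins)
                ]
            )
            self.mids_.append(mids)
        self.parents_ = []
        for s in range(n_s):
            col = w[:, s]
            order = np.argsort(-col)
            self.parents_.append([int(p) for p in order[: self.max_parents] if col[p] > 0])
        # CPTs
        self.cpt_ = []
        binned = np.stack([self._bin(flat[:, s], s) for s in range(n_s)], axis=1)
        binned = binned.reshape(acts.shape[0], acts.shape[1], n_s)
        for s in range(n_s):
            ps = self.parents_[s]
            n_states = self.n_bins ** len(ps)
            counts = np.ones((n_states, self.n_bins))  # add-one smoothing
            child_next = binned[:, 1:, s].ravel()
            if ps:
                state = np.zeros(binned[:, :-1, 0].size, dtype=int)
                for k, p in enumerate(ps):
                    state = state * self.n_bins + binned[:, :-1, p].ravel()
            else:
                state = np.zeros(child_next.size, dtype=int)
            np.add.at(counts, (state, child_next), 1)
            self.cpt_.append(counts / counts.sum(axis=1, keepdims=True))
        return self

    def _predict_states(self, x: np.ndarray) -> np.ndarray:
        """x shape (..., S) activities at t; returns expected values at t+1."""
        lead = x.shape[:-1]
        n_s = x.shape[-1]
        binned = np.stack(
            [self._bin(x[..., s].ravel(), s) for s in range(n_s)], axis=-1
        )
        out = np.empty_like(binned, dtype=float)
        for s in range(n_s):
            ps = self.parents_[s]
            if ps:
                state = np.zeros(binned.shape[0], dtype=int)
                for p in ps:
                    state = state * self.n_bins + binned[:, p]
            else:
                state = np.zeros(binned.shape[0], dtype=int)
            out[:, s] = self.cpt_[s][state] @ self.mids_[s]
        return out.reshape(*lead, n_s)

    def predict_tip(self, history: np.ndarray) -> np.ndarray:
        return np.clip(self._predict_states(history[-1]), 0.0, 1.0)

    def _predict_cube(self, dataset: TimeSeriesDataset) -> np.ndarray:
        return np.clip(self._predict_states(dataset.activity[:, :-1, :]), 0.0, 1.0)


class MeanBaseline(BaselineModel):
    """Per-species training-mean prediction; the benchmark floor."""

    kind = "mean"

    def fit(self, net: SignalingNetwork, dataset: TimeSeriesDataset):
        self.mean_ = dataset.activity.mean(axis=(0, 1))
        return self

    def predict_tip(self, history: np.ndarray) -> np.ndarray:
        return self.mean_.copy()

    def _predict_cube(self, dataset: TimeSeriesDataset) -> np.ndarray:
        c, t, s = dataset.activity.shape
        return np.broadcast_to(self.mean_, (c, t - 1, s)).copy()


def make_model(kind: str, seed: int = 0):
    """Factory over all model kinds, including the hierarchical ensemble."""
    from .model import HMLMForecaster

    kinds = {
        "hmlm": lambda: HMLMForecaster(random_state=seed),
        "ode": ODEBaseline,
        "lde": LDEBaseline,
        "gnn": lambda: GNNBaseline(random_state=seed),
        "bayes": BayesBaseline,
        "mean": MeanBaseline,
    }
    if kind not in kinds:
        raise ValueError(f"unknown model kind {kind!r}; valid kinds: {sorted(kinds)}")
    return kinds[kind]()


MODEL_KINDS = ("hmlm", "ode", "lde", "gnn", "bayes", "mean")
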