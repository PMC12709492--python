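"""Hierarchical three-head ensemble predictor.

The predictive core is :class:`HMLMRegressor`, a scikit-learn style
estimator holding three random-forest heads, one per biological scale:

* molecular head — ``n_estimators=150, max_depth=12`` on the molecular
  feature block,
* pathway head — ``n_estimators=150, max_depth=10`` on the pathway block,
* cellular head — ``n_estimators=150, max_depth=8`` on the cellular block.

One sample is one (condition, species, timepoint) row of the multi-scale
feature table; the model predicts the species' next-step activity, pooling
all species so that shared local dynamics rules (how a species responds to
its regulators) transfer across the network and across conditions.  Each
head is trained independently on its scale's feature block; the ensemble
combines the heads with nonnegative weights learned by cross-validation
(inverse-CV-MSE rule: ``w_h \\propto 1 / MSE_h^{CV}``, normalized to sum
to 1).  Predictions are clipped to the [0, 1] activity range.

:class:`HMLMForecaster` wraps the regressor into the full pipeline on a
network + dataset: spectral embeddings, attention refinement, feature-table
construction, one-step prediction, and autoregressive rollout.  Because the
one-step map is fitted on stochastic trajectories, rollouts simulate the
fitted *stochastic* system: several noise-injected trajectories are drawn
(state noise calibrated to the training one-step residuals) and averaged.
A deterministic rollout fed with its own smooth predictions would be out of
distribution for the fitted map and systematically under-responds; the
stochastic ensemble mean is the faithful point forecast of the learned
dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from . import features as ft
from .attention import init_attention, refine_attention
from .network import SignalingNetwork, spectral_positional_embedding
from .simulate import TimeSeriesDataset

__all__ = [
    "HeadConfig",
    "HMLMRegressor",
    "HMLMForecaster",
    "train",
    "save_model",
    "load_model",
]

DEFAULT_DEPTHS = {"molecular": 12, "pathway": 10, "cellular": 8}


@dataclass(frozen=True)
class HeadConfig:
    """Configuration of one scale-specific prediction head."""

    scale: str
    n_estimators: int = 150
    max_depth: int = 0  # 0 -> scale default (12 / 10 / 8)
    seed: int = 0

    def resolved_depth(self) -> int:
        return self.max_depth or DEFAULT_DEPTHS[self.scale]


class HMLMRegressor(BaseEstimator, RegressorMixin):
    """Three-scale random-forest ensemble with cross-validated weights.

    Parameters
    ----------
    n_estimators : int
        Trees per head (150 in the reference configuration).
    max_depth_molecular, max_depth_pathway, max_depth_cellular : int
        Per-head depth limits (12 / 10 / 8).
    cv_folds : int
        Folds used to estimate per-head generalization MSE for the
        inverse-CV-MSE ensemble weights.
    cv_max_rows : int
        Row cap for the weight-estimation CV.  Weights only need *relative*
        head MSEs, which stabilize on a modest subsample; the final heads
        are always fit on every row.
    max_samples : float or None
        Bootstrap sample fraction per tree (bagging subsample); bounds
        training cost on large feature tables without changing the tree
        count or depths.
    random_state : int
        Seeds forests, CV shuffling and the weight subsample.

    Attributes
    ----------
    heads_ : dict of scale -> fitted forest
    scalers_ : dict of scale -> fitted standardizer
    ensemble_weights_ : ndarray of 3 nonnegative weights summing to 1
    cv_mse_ : dict of scale -> cross-validated MSE behind the weights
    metadata_ : dict with seed and degenerate-target flags
    """

    _scales = ("molecular", "pathway", "cellular")

    def __init__(
        self,
        n_estimators: int = 150,
        max_depth_molecular: int = 12,
        max_depth_pathway: int = 10,
        max_depth_cellular: int = 8,
        cv_folds: int = 5,
        cv_max_rows: int = 6000,
        max_samples: float | None = 0.33,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth_molecular = max_depth_molecular
        self.max_depth_pathway = max_depth_pathway
        self.max_depth_cellular = max_depth_cellular
        self.cv_folds = cv_folds
        self.cv_max_rows = cv_max_rows
        self.max_samples = max_samples
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _depth(self, scale: str) -> int:
        return {
            "molecular": self.max_depth_molecular,
            "pathway": self.max_depth_pathway,
            "cellular": self.max_depth_cellular,
        }[scale]

    def _blocks(self) -> dict[str, list[str]]:
        return {
            "molecular": list(ft.MOLECULAR_FEATURES),
            "pathway": list(ft.PATHWAY_FEATURES),
            "cellular": list(ft.CELLULAR_FEATURES),
        }

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(ft.ALL_FEATURES):
            raise ValueError(
                "array input must have one column per feature "
                f"({len(ft.ALL_FEATURES)}); pass a DataFrame for named columns"
            )
        return pd.DataFrame(arr, columns=list(ft.ALL_FEATURES))

    def _head_matrix(self, frame: pd.DataFrame, scale: str) -> np.ndarray:
        cols = self._blocks()[scale]
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise ValueError(f"missing feature columns for {scale} head: {missing}")
        return frame[cols].to_numpy(dtype=float)

    def _make_head(self, scale: str) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_depth=self._depth(scale),
            random_state=self.random_state + self._scales.index(scale),
            max_samples=self.max_samples,
            n_jobs=1,
        )

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y) -> "HMLMRegressor":
        frame = self._as_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(frame) != y.size:
            raise ValueError("X and y are not aligned")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

        self.metadata_ = {"random_state": self.random_state, "n_rows": int(y.size)}
        if np.var(y) == 0:
            self.metadata_["zero_variance_target"] = True
            warnings.warn("target has zero variance", UserWarning, stacklevel=2)

        rng = np.random.default_rng(self.random_state)
        n = y.size
        sub = (
            rng.choice(n, size=self.cv_max_rows, replace=False)
            if n > self.cv_max_rows
            else np.arange(n)
        )

        mats = {s: self._head_matrix(frame, s) for s in self._scales}
        self.cv_mse_ = {}
        n_splits = min(self.cv_folds, sub.size)
        kf = KFold(n_splits=n_splits, shuffle=True, random_state=self.random_state)
        for scale in self._scales:
            xs, ys = mats[scale][sub], y[sub]
            errs = []
            for tr, va in kf.split(xs):
                scaler = StandardScaler().fit(xs[tr])
                head = self._make_head(scale).fit(scaler.transform(xs[tr]), ys[tr])
                pred = head.predict(scaler.transform(xs[va]))
                errs.append(float(np.mean((ys[va] - pred) ** 2)))
            self.cv_mse_[scale] = float(np.mean(errs))

        inv = np.array([1.0 / max(self.cv_mse_[s], 1e-12) for s in self._scales])
        self.ensemble_weights_ = inv / inv.sum()

        self.heads_ = {}
        self.scalers_ = {}
        for scale in self._scales:
            scaler = StandardScaler().fit(mats[scale])
            self.scalers_[scale] = scaler
            self.heads_[scale] = self._make_head(scale).fit(
                scaler.transform(mats[scale]), y
            )
        self.n_features_in_ = sum(m.shape[1] for m in mats.values())
        return self

    def predict_per_head(self, X) -> dict[str, np.ndarray]:
        check_is_fitted(self, "heads_")
        frame = self._as_frame(X)
        return {
            s: self.heads_[s].predict(
                self.scalers_[s].transform(self._head_matrix(frame, s))
            )
            for s in self._scales
        }

    def predict(self, X) -> np.ndarray:
        per_head = self.predict_per_head(X)
        out = np.zeros(len(next(iter(per_head.values()))))
        for w, s in zip(self.ensemble_weights_, self._scales):
            out += w * per_head[s]
        return np.clip(out, 0.0, 1.0)


class HMLMForecaster:
    """End-to-end pipeline: network + dataset -> features -> ensemble.

    ``fit`` computes spectral embeddings, initializes attention from
    topology, refines it on the training data, builds the multi-scale
    feature table and fits the :class:`HMLMRegressor`.  The fitted attention
    matrix and the per-species correlation feature are frozen and reused for
    prediction and rollout.
    """

    def __init__(
        self,
        regressor: HMLMRegressor | None = None,
        horizon: int = 1,
        n_embedding: int = ft.N_EMBEDDING,
        n_rollout_draws: int = 5,
        random_state: int = 0,
    ):
        self.regressor = regressor or HMLMRegressor(random_state=random_state)
        self.horizon = horizon
        self.n_embedding = n_embedding
        self.n_rollout_draws = n_rollout_draws
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, net: SignalingNetwork, dataset: TimeSeriesDataset) -> "HMLMForecaster":
        self.net_ = net
        self.species_ = list(dataset.species)
        self.embeddings_ = spectral_positional_embedding(net, k=self.n_embedding)
        self.attention_ = refine_attention(init_attention(net), dataset)
        table = ft.build_feature_table(dataset, net, self.attention_, self.embeddings_)
        targets = ft.build_targets(dataset, self.horizon)
        merged = table.frame.merge(targets, on=["condition", "species", "time"])
        self.feature_columns_ = list(ft.ALL_FEATURES)
        self.regressor = clone(self.regressor)
        self.regressor.set_params(random_state=self.random_state)
        self.regressor.fit(merged[self.feature_columns_], merged["target"].to_numpy())
        # noise scale of the learned stochastic dynamics: one-step residual sd
        resid = merged["target"].to_numpy() - self.regressor.predict(
            merged[self.feature_columns_]
        )
        self.residual_sd_ = float(np.std(resid))
        # species-level correlation feature frozen for rollout
        corr = ft.max_lag_correlation(dataset, net)
        self.frozen_corr_ = (
            corr.groupby("species")["max_lag_corr"]
            .mean()
            .reindex(self.species_)
            .to_numpy()
        )
        return self

    # -- one-step evaluation ----------------------------------------------

    def one_step_frame(
        self, dataset: TimeSeriesDataset, times: np.ndarray | None = None
    ) -> pd.DataFrame:
        """Teacher-forced predictions and observed targets per usable row."""
        check_is_fitted(self.regressor, "heads_")
        table = ft.build_feature_table(
            dataset, self.net_, self.attention_, self.embeddings_, times=times
        )
        targets = ft.build_targets(dataset, self.horizon)
        merged = table.frame.merge(targets, on=["condition", "species", "time"])
        merged["prediction"] = self.regressor.predict(merged[self.feature_columns_])
        return merged

    def one_step_mse(
        self, dataset: TimeSeriesDataset, times: np.ndarray | None = None
    ) -> float:
        frame = self.one_step_frame(dataset, times)
        return float(np.mean((frame["prediction"] - frame["target"]) ** 2))

    # -- rollout -----------------------------------------------------------

    def rollout(
        self,
        context: np.ndarray,
        horizon: int,
        n_draws: int | None = None,
        noise_sd: float | None = None,
        seed: int | None = None,
    ) -> np.ndarray:
        """Autoregressive forecast from an initial context window.

        ``context`` is a (W, S) matrix of observed activities (W >= 2).
        Returns the (W + horizon, S) trajectory whose first W rows are the
        context.  The forecast is the mean of ``n_draws`` simulations of the
        fitted stochastic one-step map, each injecting Gaussian state noise
        with standard deviation ``noise_sd`` (default: the training one-step
        residual sd, i.e. the noise level the map was fitted under).
        Derivative and memory features are recomputed from each growing
        trajectory; attention and the correlation feature stay frozen.
        Deterministic given the seed (default: the forecaster's
        random_state).
        """
        if horizon < 0:
            raise ValueError("horizon must be >= 0")
        context = np.asarray(context, dtype=float)
        if context.ndim != 2 or context.shape[1] != len(self.species_):
            raise ValueError("context must be (timepoints, n_species)")
        if context.shape[0] < 2:
            raise ValueError("context must contain at least 2 timepoints")
        if horizon == 0:
            return context.copy()
        n_draws = n_draws if n_draws is not None else self.n_rollout_draws
        sd = noise_sd if noise_sd is not None else getattr(self, "residual_sd_", 0.0)
        rng = np.random.default_rng(
            self.random_state if seed is None else seed
        )
        draws = []
        for _ in range(max(n_draws, 1)):
            traj = context.copy()
            mem = ft.memory_state(traj.T).T[-1]
            for _ in range(horizon):
                frame = self._tip_features(traj, mem)
                nxt = self.regressor.predict(frame)
                if sd > 0 and n_draws > 1:
                    nxt = nxt + rng.normal(0.0, sd, size=nxt.shape)
                traj = np.vstack([traj, np.clip(nxt, 0.0, 1.0)])
                mem = ft.MEMORY_ALPHA * traj[-1] + (1 - ft.MEMORY_ALPHA) * mem
            draws.append(traj)
        return np.mean(draws, axis=0)

    def _tip_features(self, traj: np.ndarray, mem: np.ndarray) -> pd.DataFrame:
        """Feature rows for all species at the last timepoint of ``traj``."""
        x = traj[-1]
        dx = traj[-1] - traj[-2]  # backward difference at the rolling tip
        attn = ft._significant_attention(self.attention_.refined)
        colsum = attn.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            attn_act = np.where(colsum > 0, (x @ attn) / colsum, 0.0)
        pos = self.embeddings_.positional_block[:, : ft.N_EMBEDDING]
        if pos.shape[1] < ft.N_EMBEDDING:
            pos = np.pad(pos, ((0, 0), (0, ft.N_EMBEDDING - pos.shape[1])))
        module_of = np.array([self.net_.node(s).module for s in self.species_])
        frame = pd.DataFrame(
            {
                "activity": x,
                "derivative": dx,
                "max_lag_corr": self.frozen_corr_,
                "memory": mem,
                "attn_neighbor": attn_act,
            }
        )
        for k in range(ft.N_EMBEDDING):
            frame[f"emb{k}_x"] = pos[:, k] * x
        mod_mean = {m: x[module_of == m].mean() for m in np.unique(module_of)}
        mod_dmean = {m: dx[module_of == m].mean() for m in np.unique(module_of)}
        frame["module_mean_activity"] = [mod_mean[m] for m in module_of]
        frame["module_mean_derivative"] = [mod_dmean[m] for m in module_of]
        frame["global_mean"] = x.mean()
        frame["global_var"] = x.var()
        fib = module_of == "ecm_fibrosis"
        frame["fibrosis_index"] = x[fib].mean() if fib.any() else 0.0
        return frame


def train(
    feature_table: ft.FeatureTable,
    targets: pd.DataFrame,
    head_configs: tuple[HeadConfig, ...] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> HMLMRegressor:
    """Fit an :class:`HMLMRegressor` from an explicit table + target frame."""
    kwargs: dict = {"cv_folds": cv_folds, "random_state": seed}
    if head_configs:
        by_scale = {h.scale: h for h in head_configs}
        n_est = {h.n_estimators for h in head_configs}
        if len(n_est) == 1:
            kwargs["n_estimators"] = n_est.pop()
        for scale in ("molecular", "pathway", "cellular"):
            if scale in by_scale:
                kwargs[f"max_depth_{scale}"] = by_scale[scale].resolved_depth()
    model = HMLMRegressor(**kwargs)
    merged = feature_table.frame.merge(targets, on=["condition", "species", "time"])
    model.fit(merged[list(ft.ALL_FEATURES)], merged["target"].to_numpy())
    return model


def save_model(model, path) -> None:
    """Serialize a fitted model/forecaster (joblib archive, versioned)."""
    joblib.dump({"format_version": 1, "model": model}, path)


def load_model(path):
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError("unrecognized model archive version")
    return payload["model"]
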