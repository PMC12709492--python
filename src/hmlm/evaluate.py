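"""Metrics, benchmark protocols, statistical testing, crosstalk.

Two evaluation protocols are provided:

* the temporal-resolution benchmark — datasets are subsampled to 4/8/16
  timepoints, linearly re-interpolated onto the full 100-point grid, and
  every model kind is trained on the first 70% of timepoints and scored by
  one-step MSE on the last 30%, over several independently seeded trials;
* the leave-one-condition-out rollout — the ensemble is trained on three
  stimulation conditions and forecasts the held-out condition
  autoregressively from a short context window; predicted and simulated
  trajectories of named readouts are compared by Pearson correlation pooled
  over the four rotations.

Pathway crosstalk follows the correlation convention: the crosstalk
coefficient between pathways k and l is the absolute Pearson correlation of
their mean-activity time series (per-condition mean-centered before
concatenation, so condition offsets do not manufacture correlation);
coefficients above 0.3 are flagged as biologically significant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import make_model
from .model import HMLMForecaster
from .network import SignalingNetwork
from .simulate import (
    SimulationConfig,
    TimeSeriesDataset,
    generate_dataset,
    subsample_and_interpolate,
)

__all__ = [
    "mse",
    "pearson",
    "EvaluationReport",
    "resolution_benchmark",
    "compare_models",
    "bootstrap_ci",
    "CrosstalkMatrix",
    "crosstalk_matrix",
    "readout_correlations",
    "leave_one_condition_out_rollout",
    "DEFAULT_READOUTS",
    "CROSSTALK_THRESHOLD",
]

CROSSTALK_THRESHOLD = 0.3
#: Readouts for prediction-accuracy correlations.  TGF-beta signaling
#: dynamics are read at the receptor (TGFBR): the ligand itself is the
#: clamped experimental stimulus, so correlating its "prediction" would
#: only echo the protocol.
DEFAULT_READOUTS = ("TGFBR", "proCI", "SMAD3", "p38", "contractility")
TRAIN_FRACTION = 0.7


def mse(y_true, y_pred) -> float:
    """Mean squared error."""
    a = np.asarray(y_true, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("need at least one observation")
    return float(np.mean((a - b) ** 2))


def pearson(x, y) -> float:
    """Product-moment correlation; raises on constant input."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("pearson undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# temporal-resolution benchmark
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Per-model, per-resolution benchmark errors and summary statistics."""

    table: pd.DataFrame  # columns: model, resolution, trial, mse
    n_trials: int
    resolutions: tuple[int, ...]
    metadata: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby(["model", "resolution"])["mse"]
        out = g.agg(["mean", "std"]).reset_index()
        out["cv"] = out["std"] / out["mean"]
        return out

    def mean_mse(self, model: str, resolution: int) -> float:
        sel = self.table[
            (self.table["model"] == model) & (self.table["resolution"] == resolution)
        ]["mse"]
        return float(sel.mean())

    def cv(self, model: str, resolution: int) -> float:
        sel = self.table[
            (self.table["model"] == model) & (self.table["resolution"] == resolution)
        ]["mse"]
        return float(sel.std(ddof=1) / sel.mean())

    def trial_errors(self, model: str, resolution: int) -> np.ndarray:
        sel = self.table[
            (self.table["model"] == model) & (self.table["resolution"] == resolution)
        ].sort_values("trial")["mse"]
        return sel.to_numpy()

    def to_json(self, path) -> None:
        payload = {
            "n_trials": self.n_trials,
            "resolutions": list(self.resolutions),
            "metadata": self.metadata,
            "records": self.table.to_dict(orient="records"),
            "summary": self.summary().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def resolution_benchmark(
    net: SignalingNetwork,
    sim_config: SimulationConfig,
    model_kinds: Sequence[str] = ("hmlm", "ode", "lde", "gnn", "bayes"),
    resolutions: Sequence[int] = (4, 8, 16),
    n_trials: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Train/evaluate every model kind across temporal resolutions.

    Per trial a fresh dataset is simulated (trial-specific seed derived from
    ``seed``), subsampled to each resolution and linearly re-interpolated
    onto the full grid; models train on the first 70% of timepoints of all
    conditions and are scored by one-step MSE on the remaining 30%,
    evaluated on the interpolated grid so errors are comparable across
    resolutions.
    """
    records = []
    for trial in range(n_trials):
        trial_seed = int(
            np.random.SeedSequence(seed, spawn_key=(trial,)).generate_state(1)[0]
            % 2**31
        )
        cfg = SimulationConfig(**{**sim_config.__dict__, "seed": trial_seed})
        dataset = generate_dataset(net, cfg)
        n_t = dataset.n_timepoints
        split = int(TRAIN_FRACTION * n_t)
        test_times = np.arange(split, n_t - 1)
        for resolution in resolutions:
            _, interp = subsample_and_interpolate(dataset, resolution)
            train_ds = interp.slice_times(0, split)
            for kind in model_kinds:
                model = make_model(kind, seed=trial_seed)
                model.fit(net, train_ds)
                err = model.one_step_mse(interp, times=test_times)
                records.append(
                    {"model": kind, "resolution": resolution, "trial": trial, "mse": err}
                )
    table = pd.DataFrame(records)
    return EvaluationReport(
        table,
        n_trials=n_trials,
        resolutions=tuple(resolutions),
        metadata={"seed": seed, "split": f"temporal {TRAIN_FRACTION:.0%} train"},
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def compare_models(
    errors_a: Sequence[float],
    errors_b: Sequence[float],
    n_comparisons: int = 1,
) -> tuple[float, float, float]:
    """Paired two-sided Wilcoxon signed-rank test with Bonferroni adjustment.

    Returns (statistic, raw p, adjusted p); all-zero differences give p = 1.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.allclose(a, b):
        return 0.0, 1.0, 1.0
    res = stats.wilcoxon(a, b, alternative="two-sided", mode="auto")
    p_adj = min(1.0, n_comparisons * float(res.pvalue))
    return float(res.statistic), float(res.pvalue), p_adj


def bootstrap_ci(
    statistic_fn: Callable[[np.ndarray], float],
    data: Sequence[float] | np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for a 1-sample statistic."""
    arr = np.asarray(data, dtype=float)
    if arr.shape[0] < 10:
        raise ValueError("need at least 10 observations")
    rng = np.random.default_rng(seed)
    vals = np.array(
        [
            statistic_fn(arr[rng.integers(0, arr.shape[0], size=arr.shape[0])])
            for _ in range(n_boot)
        ]
    )
    lo = (1 - level) / 2
    return float(np.quantile(vals, lo)), float(np.quantile(vals, 1 - lo))


# ---------------------------------------------------------------------------
# crosstalk
# ---------------------------------------------------------------------------


@dataclass
class CrosstalkMatrix:
    """Absolute-correlation crosstalk between pathway mean activities."""

    pathways: list[str]
    matrix: np.ndarray
    significant: np.ndarray
    series: pd.DataFrame  # concatenated centered mean-activity series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.pathways, columns=self.pathways)

    def get(self, k: str, l: str) -> float:
        return float(self.matrix[self.pathways.index(k), self.pathways.index(l)])


def crosstalk_matrix(
    dataset: TimeSeriesDataset,
    pathway_sets: Mapping[str, Sequence[str]],
    threshold: float = CROSSTALK_THRESHOLD,
) -> CrosstalkMatrix:
    """Pairwise pathway crosstalk coefficients.

    The mean-activity series of each pathway is computed per condition,
    mean-centered within the condition, and concatenated; the crosstalk
    coefficient is the absolute Pearson correlation between two pathways'
    series.  Constant series produce 0 with a warning flag instead of NaN.
    """
    import warnings

    names = sorted(pathway_sets)
    series = {}
    for name in names:
        members = list(pathway_sets[name])
        if not members:
            raise ValueError(f"pathway {name!r} is empty")
        missing = [m for m in members if m not in dataset.species]
        if missing:
            raise ValueError(f"pathway {name!r} members absent from dataset: {missing}")
        cols = [dataset.species.index(m) for m in members]
        chunks = []
        for c in range(len(dataset.conditions)):
            bar = dataset.activity[c][:, cols].mean(axis=1)
            chunks.append(bar - bar.mean())
        series[name] = np.concatenate(chunks)
    frame = pd.DataFrame(series)
    n = len(names)
    mat = np.zeros((n, n))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            sa, sb = series[a], series[b]
            if np.var(sa) == 0 or np.var(sb) == 0:
                warnings.warn(
                    f"constant pathway series in ({a}, {b}); crosstalk set to 0",
                    UserWarning,
                    stacklevel=2,
                )
                mat[i, j] = 0.0
            else:
                mat[i, j] = abs(pearson(sa, sb))
    return CrosstalkMatrix(names, mat, mat > threshold, frame)


# ---------------------------------------------------------------------------
# readout correlations (leave-one-condition-out rollout)
# ---------------------------------------------------------------------------


def leave_one_condition_out_rollout(
    net: SignalingNetwork,
    dataset: TimeSeriesDataset,
    context_len: int = 5,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Rollout every condition from a model trained on the other three.

    Returns condition name -> predicted (n_timepoints, n_species) trajectory
    (the first ``context_len`` rows are the observed context).
    """
    out = {}
    for held in dataset.conditions:
        train_ds = dataset.subset_conditions(
            [c for c in dataset.conditions if c != held]
        )
        model = HMLMForecaster(random_state=seed).fit(net, train_ds)
        context = dataset.get(held)[:context_len]
        out[held] = model.rollout(context, dataset.n_timepoints - context_len)
    return out


def readout_correlations(
    predicted: Mapping[str, np.ndarray],
    observed: TimeSeriesDataset,
    readouts: Sequence[str] = DEFAULT_READOUTS,
    skip_context: int = 0,
) -> pd.DataFrame:
    """Pearson r between predicted and observed readout trajectories.

    One row per readout with the correlation pooled across all conditions
    (and, if requested, the per-condition breakdown columns).
    """
    missing = [r for r in readouts if r not in observed.species]
    if missing:
        raise ValueError(f"readout species absent from dataset: {missing}")
    rows = []
    for readout in readouts:
        s = observed.species.index(readout)
        pooled_pred, pooled_obs = [], []
        per_condition = {}
        for cname in observed.conditions:
            if cname not in predicted:
                raise ValueError(f"no predicted trajectory for condition {cname!r}")
            pred = np.asarray(predicted[cname])[skip_context:, s]
            obs = observed.get(cname)[skip_context:, s]
            if pred.shape != obs.shape:
                raise ValueError("predicted/observed trajectory lengths differ")
            pooled_pred.append(pred)
            pooled_obs.append(obs)
            if np.var(pred) > 0 and np.var(obs) > 0:
                per_condition[cname] = pearson(obs, pred)
            else:
                per_condition[cname] = np.nan
        row = {
            "readout": readout,
            "r": pearson(np.concatenate(pooled_obs), np.concatenate(pooled_pred)),
        }
        row.update({f"r_{c}": v for c, v in per_condition.items()})
        rows.append(row)
    return pd.DataFrame(rows)
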