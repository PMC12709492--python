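"""Discrete-time transducer dynamics on a signaling network.

Each species v carries an activity state ``s_v(t)`` in [0, 1].  Per step, the
incoming signal is the clipped signed weighted sum of upstream outputs plus
any external drive,

    Omega_v(t) = clip01( sum_u W[u, v] * s_u(t) + drive_v ),

and the state follows an explicit first-order update with module-specific
integration and degradation rates,

    s_v(t+1) = clip01( s_v(t) + dt * (k_int,v * Omega_v - k_deg,v * s_v(t))
                       + eps ),   eps ~ Normal(0, noise_sd),

the additive Gaussian term realizing the stochastic-transducer extension of
the deterministic dynamics.  Species in the ``inputs`` module are clamped to
their condition drive (plus noise): they are the experimental stimuli.

Four stimulation conditions mirror a fibroblast activation experiment:
``control`` (all inputs at a 0.05 baseline), ``tgfb`` (TGF-beta step to 1.0),
``strain`` (mechanical-strain step to 1.0), and ``combined`` (both).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import DEFAULT_MODULE_RATES, SignalingNetwork, weighted_adjacency

__all__ = [
    "TransducerSpec",
    "SimulationConfig",
    "Condition",
    "TimeSeriesDataset",
    "standard_conditions",
    "integrate_inputs",
    "step",
    "simulate",
    "generate_dataset",
    "subsample_and_interpolate",
]

CONDITION_NAMES = ("control", "tgfb", "strain", "combined")

#: Input nodes stimulated by each standard condition.
_CONDITION_STIMULI: dict[str, tuple[str, ...]] = {
    "control": (),
    "tgfb": ("TGFB",),
    "strain": ("mech_strain",),
    "combined": ("TGFB", "mech_strain"),
}


@dataclass(frozen=True)
class TransducerSpec:
    """Per-species dynamical parameters (rates per unit time)."""

    integration_rate: float
    degradation_rate: float
    output_fn: str = "identity"  # identity | logistic
    noise_sd: float = 0.0
    initial_state: float = 0.05

    def __post_init__(self) -> None:
        if self.integration_rate < 0 or self.degradation_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.initial_state <= 1.0:
            raise ValueError("initial_state must lie in [0, 1]")
        if self.output_fn not in ("identity", "logistic"):
            raise ValueError("output_fn must be 'identity' or 'logistic'")


@dataclass
class SimulationConfig:
    """Configuration of a multi-condition simulation.

    ``module_rates`` maps each functional module to its
    (integration_rate, degradation_rate) pair; the defaults are the
    fibroblast calibration: receptors (0.40, 0.05), kinases / second
    messengers and related signaling modules (0.35, 0.08), transcription
    factors and feedback (0.25, 0.06), ECM/fibrosis and matrix remodeling
    (0.15, 0.03).  ``noise_sd`` defaults to 0.015, the midpoint of the
    0.01-0.02 measurement-noise band, applied per species per step;
    ``module_noise_sd`` overrides it for individual modules.
    """

    n_timepoints: int = 100
    dt: float = 1.0
    module_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MODULE_RATES)
    )
    noise_sd: float = 0.015
    module_noise_sd: dict[str, float] = field(default_factory=dict)
    baseline_drive: float = 0.05
    stimulus_level: float = 1.0
    initial_state: float = 0.05
    init_mode: str = "burn_in"  # burn_in: rest at the control steady state
    burn_in_steps: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.init_mode not in ("burn_in", "uniform"):
            raise ValueError("init_mode must be 'burn_in' or 'uniform'")

    def rates_for(self, module: str) -> tuple[float, float]:
        try:
            return self.module_rates[module]
        except KeyError:
            raise KeyError(f"no rates configured for module {module!r}") from None

    def noise_for(self, module: str) -> float:
        return self.module_noise_sd.get(module, self.noise_sd)


@dataclass(frozen=True)
class Condition:
    """A stimulation condition: constant drives applied to input nodes."""

    name: str
    input_levels: Mapping[str, float]

    def drive_vector(self, net: SignalingNetwork) -> np.ndarray:
        drive = np.zeros(net.n_nodes)
        for nid, level in self.input_levels.items():
            if nid not in net.species:
                raise KeyError(f"condition {self.name!r}: unknown node {nid!r}")
            drive[net.index(nid)] = level
        return drive


def standard_conditions(
    net: SignalingNetwork, config: SimulationConfig | None = None
) -> list[Condition]:
    """The four standard conditions: control, tgfb, strain, combined."""
    config = config or SimulationConfig()
    conditions = []
    for name in CONDITION_NAMES:
        stimulated = _CONDITION_STIMULI[name]
        levels = {}
        for nid in net.input_nodes():
            levels[nid] = (
                config.stimulus_level if nid in stimulated else config.baseline_drive
            )
        conditions.append(Condition(name, levels))
    return conditions


@dataclass
class TimeSeriesDataset:
    """Condition x timepoint x species activity tensor.

    ``activity`` has shape (n_conditions, n_timepoints, n_species), all
    values in [0, 1]; ``species`` matches the network's canonical order.
    """

    conditions: list[str]
    activity: np.ndarray
    species: list[str]
    dt: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.activity, dtype=float)
        if a.ndim != 3:
            raise ValueError("activity must be 3-d (condition, time, species)")
        if a.shape[0] != len(self.conditions) or a.shape[2] != len(self.species):
            raise ValueError("activity shape does not match labels")
        if np.isnan(a).any():
            raise ValueError("activity contains missing values")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("activity must lie in [0, 1]")
        self.activity = np.clip(a, 0.0, 1.0)

    @property
    def n_timepoints(self) -> int:
        return self.activity.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt

    def condition_index(self, name: str) -> int:
        return self.conditions.index(name)

    def get(self, condition: str) -> np.ndarray:
        """(n_timepoints, n_species) matrix for one condition."""
        return self.activity[self.condition_index(condition)]

    def series(self, condition: str, species: str) -> np.ndarray:
        return self.get(condition)[:, self.species.index(species)]

    def slice_times(self, start: int, stop: int) -> "TimeSeriesDataset":
        """Contiguous timepoint window [start, stop) as a new dataset."""
        return TimeSeriesDataset(
            list(self.conditions),
            self.activity[:, start:stop, :].copy(),
            list(self.species),
            self.dt,
        )

    def subset_conditions(self, names: Sequence[str]) -> "TimeSeriesDataset":
        idx = [self.condition_index(n) for n in names]
        return TimeSeriesDataset(
            list(names), self.activity[idx].copy(), list(self.species), self.dt
        )

    # -- tidy CSV round-trip ----------------------------------------------

    def to_tidy(self) -> pd.DataFrame:
        frames = []
        for c, cname in enumerate(self.conditions):
            mat = self.activity[c]
            df = pd.DataFrame(mat, columns=self.species)
            df.insert(0, "time", self.times)
            long = df.melt(id_vars="time", var_name="species", value_name="activity")
            long.insert(0, "condition", cname)
            frames.append(long)
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_tidy().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, dt: float | None = None) -> "TimeSeriesDataset":
        required = {"condition", "time", "species", "activity"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"tidy frame missing columns {sorted(missing)}")
        conditions = list(pd.unique(df["condition"]))
        species = list(pd.unique(df["species"]))
        times = np.sort(pd.unique(df["time"]))
        if dt is None:
            dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
        cube = np.full((len(conditions), len(times), len(species)), np.nan)
        tpos = {t: k for k, t in enumerate(times)}
        cpos = {c: k for k, c in enumerate(conditions)}
        spos = {s: k for k, s in enumerate(species)}
        for row in df.itertuples(index=False):
            cube[cpos[row.condition], tpos[row.time], spos[row.species]] = row.activity
        return cls(conditions, cube, species, dt)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeSeriesDataset":
        return cls.from_tidy(pd.read_csv(path))


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def integrate_inputs(
    net: SignalingNetwork,
    outputs: Mapping[str, float] | np.ndarray,
    v: str,
    drive: float = 0.0,
) -> float:
    """Input-integration function Omega_v: clipped signed weighted sum.

    ``outputs`` maps species to their current output (or is a vector in
    canonical species order).  Nodes with no incoming edges and no drive
    integrate to 0.
    """
    if isinstance(outputs, np.ndarray):
        y = outputs
    else:
        y = np.array([outputs.get(s, 0.0) for s in net.species])
    w = weighted_adjacency(net)
    total = float(w[:, net.index(v)] @ y + drive)
    return float(np.clip(total, 0.0, 1.0))


class _CompiledDynamics:
    """Vectorized per-network arrays so stepping is a few BLAS calls."""

    def __init__(self, net: SignalingNetwork, config: SimulationConfig):
        self.net = net
        self.config = config
        self.w = weighted_adjacency(net)
        modules = [n.module for n in net.nodes]
        self.k_int = np.array([config.rates_for(m)[0] for m in modules])
        self.k_deg = np.array([config.rates_for(m)[1] for m in modules])
        self.noise_sd = np.array([config.noise_for(m) for m in modules])
        self.input_mask = np.array([m == "inputs" for m in modules])

    def step(
        self, state: np.ndarray, drive: np.ndarray, rng: np.random.Generator | None
    ) -> np.ndarray:
        omega = np.clip(self.w.T @ state + drive, 0.0, 1.0)
        nxt = state + self.config.dt * (self.k_int * omega - self.k_deg * state)
        if rng is not None and np.any(self.noise_sd > 0):
            nxt = nxt + rng.normal(0.0, 1.0, size=state.shape) * self.noise_sd
        nxt = np.clip(nxt, 0.0, 1.0)
        # stimuli are clamped to their drive (noise still reflects measurement)
        nxt[self.input_mask] = np.clip(
            drive[self.input_mask]
            + (
                rng.normal(0.0, 1.0, size=int(self.input_mask.sum()))
                * self.noise_sd[self.input_mask]
                if rng is not None and np.any(self.noise_sd > 0)
                else 0.0
            ),
            0.0,
            1.0,
        )
        return nxt


def step(
    state: np.ndarray,
    net: SignalingNetwork,
    config: SimulationConfig,
    condition: Condition,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One explicit first-order update of all species states."""
    dyn = _CompiledDynamics(net, config)
    return dyn.step(np.asarray(state, dtype=float), condition.drive_vector(net), rng)


def simulate(
    net: SignalingNetwork,
    config: SimulationConfig,
    condition: Condition,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one condition; returns (n_timepoints, n_species) in [0, 1].

    Row 0 holds the initial states.  With the default ``burn_in`` mode the
    system is first relaxed noise-free under the control (baseline) drive, so
    stimulation starts from the rested steady state as in a real stimulation
    experiment; ``uniform`` mode starts every species at
    ``config.initial_state``.  When ``rng`` is omitted one is derived from
    ``config.seed`` and the condition name, so repeated calls are
    reproducible.
    """
    if rng is None:
        rng = _condition_rng(config.seed, condition.name)
    if config.noise_sd == 0 and not config.module_noise_sd:
        rng = None
    dyn = _CompiledDynamics(net, config)
    drive = condition.drive_vector(net)
    out = np.empty((config.n_timepoints, net.n_nodes))
    state = _initial_state(net, config, dyn)
    state[dyn.input_mask] = np.clip(drive[dyn.input_mask], 0.0, 1.0)
    out[0] = state
    for t in range(1, config.n_timepoints):
        state = dyn.step(state, drive, rng)
        out[t] = state
    return out


def _initial_state(
    net: SignalingNetwork, config: SimulationConfig, dyn: "_CompiledDynamics"
) -> np.ndarray:
    """Resting state: control-steady-state burn-in or uniform level."""
    state = np.full(net.n_nodes, config.initial_state)
    if config.init_mode == "burn_in":
        baseline = np.zeros(net.n_nodes)
        baseline[dyn.input_mask] = config.baseline_drive
        state[dyn.input_mask] = config.baseline_drive
        for _ in range(config.burn_in_steps):
            state = dyn.step(state, baseline, rng=None)
    return state


def _condition_rng(seed: int, condition_name: str) -> np.random.Generator:
    # deterministic per-condition sub-stream of the dataset seed
    idx = CONDITION_NAMES.index(condition_name) if condition_name in CONDITION_NAMES else (
        sum(condition_name.encode()) % 1000 + 10
    )
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))


def generate_dataset(
    net: SignalingNetwork,
    config: SimulationConfig | None = None,
    conditions: Sequence[Condition] | None = None,
) -> TimeSeriesDataset:
    """Simulate all conditions into one dataset (default: the standard four)."""
    config = config or SimulationConfig()
    if conditions is None:
        conditions = standard_conditions(net, config)
    cube = np.stack([simulate(net, config, c) for c in conditions])
    return TimeSeriesDataset(
        [c.name for c in conditions], cube, list(net.species), config.dt
    )


def subsample_and_interpolate(
    dataset: TimeSeriesDataset, n_points: int
) -> tuple[TimeSeriesDataset, TimeSeriesDataset]:
    """Subsample to ``n_points`` even timepoints and linearly re-interpolate.

    Returns ``(sparse, interpolated)``: the sparse grid always contains the
    first and last timepoint; the interpolated dataset is piecewise-linear
    back on the original grid (identical to the original when
    ``n_points == n_timepoints``).
    """
    t_full = dataset.n_timepoints
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if n_points > t_full:
        raise ValueError(f"n_points={n_points} exceeds n_timepoints={t_full}")
    idx = np.unique(np.round(np.linspace(0, t_full - 1, n_points)).astype(int))
    sparse = TimeSeriesDataset(
        list(dataset.conditions),
        dataset.activity[:, idx, :].copy(),
        list(dataset.species),
        dataset.dt,  # note: sparse grid is non-uniform in general
    )
    full_t = np.arange(t_full, dtype=float)
    interp = np.empty_like(dataset.activity)
    for c in range(dataset.activity.shape[0]):
        for s in range(dataset.activity.shape[2]):
            interp[c, :, s] = np.interp(full_t, idx.astype(float), dataset.activity[c, idx, s])
    return sparse, TimeSeriesDataset(
        list(dataset.conditions), interp, list(dataset.species), dataset.dt
    )
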