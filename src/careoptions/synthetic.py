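"""Synthetic demand paths and survey-like panels with known parameters.

Demand paths are simulated from the geometric Brownian motion
``dQ = alpha Q dt + sigma Q dz`` by exact lognormal stepping,

    Q_{t+dt} = Q_t * exp((alpha - sigma^2/2) dt + sigma sqrt(dt) eps),

which is distribution-exact for any step size (no Euler discretization
bias, no positivity violations). Survey-like panels sample a single GBM
path at the wave spacing, yielding a proportion series whose true drift
and volatility are known — the ground truth for estimator-consistency
checks. All generators are deterministic under a fixed integer seed;
replicate ``k`` of an ensemble uses ``seed + k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import DemandProcess, InvalidParameterError
from .estimation import SurveySeries

__all__ = [
    "GBMPath",
    "SyntheticPanel",
    "simulate_gbm",
    "simulate_gbm_ensemble",
    "simulate_survey_panel",
    "simulate_panel_ensemble",
]


@dataclass(frozen=True)
class GBMPath:
    """One simulated demand path on a uniform time grid."""

    times: np.ndarray   # years
    values: np.ndarray  # demand units, strictly positive
    drift: float
    volatility: float
    seed: int

    def log_increments(self) -> np.ndarray:
        """log(Q_{t+dt}/Q_t): i.i.d. N((alpha - sigma^2/2) dt, sigma^2 dt)."""
        return np.diff(np.log(self.values))


@dataclass(frozen=True)
class SyntheticPanel:
    """A survey-like proportion panel generated from a known GBM."""

    wave_years: tuple[int, ...]
    proportions: tuple[float, ...]  # percent
    drift: float
    volatility: float
    seed: int

    def as_series(self) -> SurveySeries:
        """View consumable by the estimation module."""
        return SurveySeries(years=self.wave_years, proportions=self.proportions)


def _validate_grid(horizon: float, dt: float) -> int:
    if not dt > 0:
        raise InvalidParameterError(f"dt must be positive, got {dt!r}")
    if horizon < dt:
        raise InvalidParameterError(
            f"horizon must be at least one step, got horizon={horizon!r}, dt={dt!r}"
        )
    return int(round(horizon / dt))


def simulate_gbm(
    process: DemandProcess, horizon: float, dt: float, seed: int
) -> GBMPath:
    """Simulate one demand path over ``horizon`` years at step ``dt``."""
    n_steps = _validate_grid(horizon, dt)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n_steps)
    log_steps = (process.drift - 0.5 * process.volatility**2) * dt + (
        process.volatility * np.sqrt(dt)
    ) * eps
    values = process.initial_demand * np.exp(np.concatenate(([0.0], np.cumsum(log_steps))))
    times = dt * np.arange(n_steps + 1)
    return GBMPath(
        times=times,
        values=values,
        drift=process.drift,
        volatility=process.volatility,
        seed=seed,
    )


def simulate_gbm_ensemble(
    process: DemandProcess, horizon: float, dt: float, n_paths: int, seed: int
) -> np.ndarray:
    """Simulate ``n_paths`` independent paths; shape (n_paths, n_steps + 1).

    Vectorized single-stream variant for Monte-Carlo moment checks; the
    whole ensemble is reproducible from one seed.
    """
    if n_paths < 1:
        raise InvalidParameterError(f"n_paths must be >= 1, got {n_paths!r}")
    n_steps = _validate_grid(horizon, dt)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_paths, n_steps))
    log_steps = (process.drift - 0.5 * process.volatility**2) * dt + (
        process.volatility * np.sqrt(dt)
    ) * eps
    log_paths = np.concatenate(
        [np.zeros((n_paths, 1)), np.cumsum(log_steps, axis=1)], axis=1
    )
    return process.initial_demand * np.exp(log_paths)


def simulate_survey_panel(
    process: DemandProcess,
    n_waves: int = 8,
    delta_y: float = 3.0,
    seed: int = 0,
    start_year: int = 1998,
) -> SyntheticPanel:
    """Sample a GBM at wave spacing ``delta_y``, as a survey would observe it.

    The default shape (8 waves, 3-year spacing) mirrors the packaged
    CLHLS aggregates. ``process.initial_demand`` is the first-wave
    proportion in percent.
    """
    if n_waves < 3:
        raise InvalidParameterError(f"n_waves must be >= 3, got {n_waves!r}")
    path = simulate_gbm(process, horizon=delta_y * (n_waves - 1), dt=delta_y, seed=seed)
    years = tuple(int(round(start_year + delta_y * i)) for i in range(n_waves))
    return SyntheticPanel(
        wave_years=years,
        proportions=tuple(path.values),
        drift=process.drift,
        volatility=process.volatility,
        seed=seed,
    )


def simulate_panel_ensemble(
    process: DemandProcess,
    n_replicates: int,
    n_waves: int = 8,
    delta_y: float = 3.0,
    seed: int = 0,
) -> np.ndarray:
    """Proportion matrix of ``n_replicates`` independent panels.

    Shape (n_replicates, n_waves); replicate k is exactly
    ``simulate_survey_panel(..., seed=seed + k)``.
    """
    if n_replicates < 1:
        raise InvalidParameterError(f"n_replicates must be >= 1, got {n_replicates!r}")
    if n_waves < 3:
        raise InvalidParameterError(f"n_waves must be >= 3, got {n_waves!r}")
    out = np.empty((n_replicates, n_waves))
    for k in range(n_replicates):
        panel = simulate_survey_panel(
            process, n_waves=n_waves, delta_y=delta_y, seed=seed + k
        )
        out[k] = panel.proportions
    return out
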