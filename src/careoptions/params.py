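"""Scenario parameters and the demand process.

A scenario bundles the economic and policy inputs of an elderly-care
service project (ECSP): the sunk investment cost, the regulated service
price, the project lifetime and bed scale, the two subsidy instruments
(a one-time per-bed construction subsidy and a recurring per-elder
operating subsidy) with their quality-supervision pass-through
coefficients, the premium cost multiplier for the care intensity of the
target clientele, and the risk-neutral demand dynamics (drift, volatility,
risk-free rate).

Demand for beds follows a geometric Brownian motion
``dQ_t = alpha * Q_t dt + sigma * Q_t dz(t)``; the rate-of-return
shortfall ``delta = r - alpha`` must be strictly positive, otherwise
waiting is costless and the investment option is never exercised.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "CareOptionsError",
    "InvalidParameterError",
    "InvalidDataError",
    "InsufficientDataError",
    "InfeasiblePolicyError",
    "ScenarioParams",
    "DemandProcess",
    "load_params",
]


class CareOptionsError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(CareOptionsError, ValueError):
    """A scenario parameter violates its admissible range."""


class InvalidDataError(CareOptionsError, ValueError):
    """A survey series is malformed (bad counts, zero proportions...)."""


class InsufficientDataError(InvalidDataError):
    """Too few survey waves for the requested estimation."""


class InfeasiblePolicyError(CareOptionsError, ValueError):
    """No admissible subsidy can achieve the requested outcome."""


#: Config-file keys (the conventional symbols) -> dataclass field names.
_SYMBOL_TO_FIELD = {
    "I_t": "investment_cost",
    "P": "price",
    "T": "lifetime",
    "N_s": "scale",
    "S_cs": "construction_subsidy",
    "S_ps": "operating_subsidy",
    "rho": "rho",
    "theta": "theta",
    "mu": "premium",
    "r": "rate",
    "alpha": "drift",
    "sigma": "volatility",
}
_FIELD_TO_SYMBOL = {v: k for k, v in _SYMBOL_TO_FIELD.items()}


@dataclass(frozen=True)
class ScenarioParams:
    """Economic and policy inputs of one ECSP investment scenario.

    Defaults are the baseline numerical example: a 300-bed project
    costing 60 million CNY, charging 36,000 CNY per elder-year over a
    30-year lifetime, with a 12,000 CNY/bed construction subsidy and a
    4,800 CNY/elder-year operating subsidy, both passed through at 90%
    under quality supervision, a 1.2 premium cost multiplier, a 10%
    risk-free rate and demand dynamics (alpha, sigma) = (0.005, 0.12).
    """

    investment_cost: float = 60_000_000.0  # I_t, CNY
    price: float = 36_000.0                # P, CNY per elder-year
    lifetime: float = 30.0                 # T, years
    scale: float = 300.0                   # N_s, beds
    construction_subsidy: float = 12_000.0  # S_cs, CNY per bed, one-time
    operating_subsidy: float = 4_800.0     # S_ps, CNY per elder-year
    rho: float = 0.90                      # construction pass-through in [0, 1]
    theta: float = 0.90                    # operating pass-through in [0, 1]
    premium: float = 1.20                  # mu, care-intensity cost multiplier
    rate: float = 0.10                     # r, risk-free rate per year
    drift: float = 0.005                   # alpha, per year
    volatility: float = 0.12               # sigma, per year

    def __post_init__(self) -> None:
        positive = {
            "investment_cost": self.investment_cost,
            "price": self.price,
            "lifetime": self.lifetime,
            "scale": self.scale,
            "volatility": self.volatility,
            "premium": self.premium,
            "rate": self.rate,
        }
        for name, value in positive.items():
            if not math.isfinite(value) or value <= 0:
                raise InvalidParameterError(f"{name} must be positive, got {value!r}")
        for name, value in (("rho", self.rho), ("theta", self.theta)):
            if not 0.0 <= value <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {value!r}")
        for name, value in (
            ("construction_subsidy", self.construction_subsidy),
            ("operating_subsidy", self.operating_subsidy),
        ):
            if value < 0:
                raise InvalidParameterError(f"{name} must be non-negative, got {value!r}")
        if self.rate <= self.drift:
            raise InvalidParameterError(
                "rate must exceed drift (delta = r - alpha > 0); "
                f"got r={self.rate}, alpha={self.drift}"
            )

    @property
    def delta(self) -> float:
        """Rate-of-return shortfall delta = r - alpha (> 0 by construction)."""
        return self.rate - self.drift

    @property
    def discount_factor(self) -> float:
        """Lifetime annuity discount factor 1 - exp(-delta * T)."""
        return 1.0 - math.exp(-self.delta * self.lifetime)

    @property
    def revenue_multiple(self) -> float:
        """Expected discounted revenue per unit of current demand.

        P * (1 - exp(-delta*T)) / delta: the present value of the cash
        flow generated by one elder-year of demand held over the project
        lifetime under the risk-neutral measure.
        """
        return self.price * self.discount_factor / self.delta

    def replace(self, **changes: Any) -> "ScenarioParams":
        """Return a copy with the given fields replaced (re-validated)."""
        mapped = {_SYMBOL_TO_FIELD.get(k, k): v for k, v in changes.items()}
        unknown = [k for k in mapped if k not in _FIELD_TO_SYMBOL]
        if unknown:
            raise InvalidParameterError(f"unknown scenario parameters: {sorted(unknown)}")
        return dataclasses.replace(self, **mapped)

    def process(self, initial_demand: float) -> "DemandProcess":
        """The GBM demand law of this scenario, anchored at ``initial_demand``."""
        return DemandProcess(self.drift, self.volatility, initial_demand)

    def to_dict(self) -> dict[str, float]:
        """Symbol-keyed dict (round-trips through :func:`load_params`)."""
        return {
            sym: getattr(self, field) for sym, field in _SYMBOL_TO_FIELD.items()
        }

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ScenarioParams":
        unknown = [k for k in mapping if k not in _SYMBOL_TO_FIELD and k not in _FIELD_TO_SYMBOL]
        if unknown:
            raise InvalidParameterError(f"unknown scenario keys: {sorted(unknown)}")
        fields = {_SYMBOL_TO_FIELD.get(k, k): float(v) for k, v in mapping.items()}
        return cls(**fields)


def load_params(path: str | Path) -> ScenarioParams:
    """Load a scenario from a flat YAML or JSON key-value file.

    Keys are the conventional symbols ``I_t, P, T, N_s, S_cs, S_ps, rho,
    theta, mu, r, alpha, sigma`` (long field names are also accepted).
    Missing keys fall back to the baseline defaults; unknown keys raise
    :class:`InvalidParameterError`.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise InvalidParameterError(f"{path}: expected a flat key-value mapping")
    return ScenarioParams.from_mapping(raw)


@dataclass(frozen=True)
class DemandProcess:
    """Geometric Brownian motion for actual demand.

    dQ_t = drift * Q_t dt + volatility * Q_t dz(t), dz = eps * sqrt(dt),
    eps ~ N(0, 1). Units of ``initial_demand`` are whatever the caller
    uses consistently (beds demanded, or percentage points of a survey
    proportion); the dynamics are scale-free.
    """

    drift: float
    volatility: float
    initial_demand: float

    def __post_init__(self) -> None:
        if self.volatility < 0:
            # sigma = 0 (deterministic exponential growth) is admitted as the
            # degenerate case for simulation; valuation requires sigma > 0.
            raise InvalidParameterError(
                f"volatility must be non-negative, got {self.volatility!r}"
            )
        if not self.initial_demand > 0:
            raise InvalidParameterError(
                f"initial_demand must be positive, got {self.initial_demand!r}"
            )

    def expected_demand(self, t: float) -> float:
        """E[Q_t] = Q_0 * exp(drift * t) for t >= 0."""
        if t < 0:
            raise InvalidParameterError(f"t must be non-negative, got {t!r}")
        return self.initial_demand * math.exp(self.drift * t)
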