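"""Closed-form real-options valuation of an unsubsidized care project.

The investor holds a perpetual option to sink ``mu * I_t`` irreversibly
in exchange for the discounted revenue stream of a project whose demand
Q_t follows a geometric Brownian motion. Under risk neutrality the
option value F(Q) solves the homogeneous ODE

    (sigma^2/2) Q^2 F'' + (r - delta) Q F' - r F = 0,

whose power solutions Q^beta have exponents given by the fundamental
quadratic ``(sigma^2/2) beta (beta - 1) + (r - delta) beta - r = 0``
with roots beta1 > 1 and beta2 < 0. Absorbing the lim_{Q->0} F = 0,
value-matching and smooth-pasting conditions at the exercise threshold
yields the investment trigger

    Q* = beta1/(beta1 - 1) * delta * mu * I_t / (P * (1 - exp(-delta T)))

and the piecewise option value: the waiting value
``mu I_t/(beta1-1) * (Q/Q*)^beta1`` below the trigger and the immediate
payoff ``V(Q) = P Q (1 - exp(-delta T))/delta - mu I_t`` at and above it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .params import DemandProcess, InvalidParameterError, ScenarioParams

__all__ = [
    "BetaRoots",
    "ValuationPoint",
    "beta_roots",
    "expected_demand",
    "trigger_value",
    "option_value",
    "net_expected_value",
    "valuation_grid",
]


@dataclass(frozen=True)
class BetaRoots:
    """Roots of the fundamental quadratic; beta1 > 1, beta2 < 0."""

    beta1: float
    beta2: float

    def wedge(self) -> float:
        """The option-value multiple beta1 / (beta1 - 1) > 1."""
        return self.beta1 / (self.beta1 - 1.0)


@dataclass(frozen=True)
class ValuationPoint:
    """Option value and immediate payoff at one demand level."""

    demand: float
    option_value: float
    net_expected_value: float
    exercised: bool  # demand at or above the trigger


def beta_roots(params: ScenarioParams) -> BetaRoots:
    """Both roots of (sigma^2/2) b(b-1) + (r - delta) b - r = 0.

    With delta = r - alpha the drift coefficient r - delta equals alpha,
    giving the closed forms

        beta_{1,2} = 1/2 - alpha/sigma^2
                     +/- sqrt((alpha/sigma^2 - 1/2)^2 + 2 r / sigma^2).

    beta1 > 1 always holds when delta > 0; beta2 < 0 when r > 0.
    """
    sigma2 = params.volatility**2
    if sigma2 <= 0 or params.rate <= 0:
        raise InvalidParameterError("beta roots require sigma > 0 and r > 0")
    a = params.drift / sigma2
    disc = math.sqrt((a - 0.5) ** 2 + 2.0 * params.rate / sigma2)
    return BetaRoots(beta1=0.5 - a + disc, beta2=0.5 - a - disc)


def expected_demand(process: DemandProcess, t: float) -> float:
    """Expected demand E[Q_t] = Q_0 * exp(alpha * t), t >= 0."""
    return process.expected_demand(t)


def trigger_value(params: ScenarioParams) -> float:
    """Investment trigger Q*: the least demand at which investing now is optimal.

    Q* = beta1/(beta1-1) * delta * mu * I_t / (P * (1 - exp(-delta*T))).
    Equivalently, the demand at which the discounted revenue equals
    beta1/(beta1-1) times the effective sunk cost — the classic
    option-value wedge above the Marshallian break-even point.
    """
    roots = beta_roots(params)
    return roots.wedge() * params.premium * params.investment_cost / params.revenue_multiple


def net_expected_value(params: ScenarioParams, demand: float) -> float:
    """Immediate-investment payoff V(Q) = P*Q*(1 - e^{-delta T})/delta - mu*I_t.

    Affine in demand; V(0) = -mu*I_t. Defined for all Q >= 0.
    """
    if demand < 0:
        raise InvalidParameterError(f"demand must be non-negative, got {demand!r}")
    return params.revenue_multiple * demand - params.premium * params.investment_cost


def option_value(params: ScenarioParams, demand: float) -> float:
    """Value of the investment option F(Q).

    Below the trigger: the waiting value
    ``mu*I_t/(beta1 - 1) * (Q/Q*)^beta1``; at and above it, the
    immediate payoff V(Q). Continuous with continuous first derivative
    at Q* (value matching and smooth pasting).
    """
    if not demand > 0:
        raise InvalidParameterError(f"demand must be positive, got {demand!r}")
    q_star = trigger_value(params)
    if demand >= q_star:
        return net_expected_value(params, demand)
    beta1 = beta_roots(params).beta1
    scale = params.premium * params.investment_cost / (beta1 - 1.0)
    return scale * (demand / q_star) ** beta1


def _valuation_point(params: ScenarioParams, demand: float) -> ValuationPoint:
    q_star = trigger_value(params)
    return ValuationPoint(
        demand=demand,
        option_value=option_value(params, demand),
        net_expected_value=net_expected_value(params, demand),
        exercised=demand >= q_star,
    )


def valuation_grid(
    params: ScenarioParams, demand_grid: Iterable[float]
) -> pd.DataFrame:
    """Evaluate F and V on a demand grid; columns (Q, F, V, exercised)."""
    grid = np.asarray(list(demand_grid), dtype=float)
    points = [_valuation_point(params, q) for q in grid]
    return pd.DataFrame(
        {
            "Q": grid,
            "F": [p.option_value for p in points],
            "V": [p.net_expected_value for p in points],
            "exercised": [p.exercised for p in points],
        }
    )
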