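"""Construction vs operating subsidy schemes for care-project investment.

Two pure policy instruments lower the investment trigger:

* **Construction subsidy** — a one-time payment of S_cs per bed. With
  pass-through rho under quality supervision it reduces the effective
  sunk cost to ``I'_t = I_t - rho * N_s * S_cs``; everything else in the
  valuation is unchanged.
* **Operating subsidy** — a recurring payment of S_ps per elder served
  per year. With pass-through theta it raises the effective price to
  ``P + theta * S_ps``, scaling up the revenue stream.

Each scheme has its own trigger, option value and payoff (same closed
forms with the effective cost or price substituted), a required-subsidy
curve (the per-unit amount that makes the subsidized trigger equal the
current demand, so investment is triggered immediately), and spillover
values (the scheme's F and V minus the unsubsidized ones).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .params import InfeasiblePolicyError, InvalidParameterError, ScenarioParams
from .valuation import beta_roots, net_expected_value, option_value, trigger_value

__all__ = [
    "SubsidyScheme",
    "SchemeComparison",
    "effective_investment_cost",
    "effective_price",
    "trigger_construction",
    "trigger_operating",
    "required_construction_subsidy",
    "required_operating_subsidy",
    "option_value_construction",
    "net_value_construction",
    "option_value_operating",
    "net_value_operating",
    "subsidy_curves",
    "spillover_table",
    "compare_schemes",
]


class SubsidyScheme(str, enum.Enum):
    NONE = "none"
    CONSTRUCTION = "construction"
    OPERATING = "operating"


def effective_investment_cost(params: ScenarioParams) -> float:
    """I'_t = I_t - rho * N_s * S_cs; must stay positive."""
    received = params.rho * params.scale * params.construction_subsidy
    cost = params.investment_cost - received
    if cost <= 0:
        raise InfeasiblePolicyError(
            "construction subsidy received exceeds the investment cost "
            f"(rho*N_s*S_cs = {received:,.0f} >= I_t = {params.investment_cost:,.0f})"
        )
    return cost


def effective_price(params: ScenarioParams) -> float:
    """P + theta * S_ps, the per-elder-year revenue under the operating subsidy."""
    return params.price + params.theta * params.operating_subsidy


def _with_construction(params: ScenarioParams) -> ScenarioParams:
    """Scenario re-expressed with the subsidized cost and subsidies stripped."""
    return params.replace(
        investment_cost=effective_investment_cost(params),
        construction_subsidy=0.0,
        operating_subsidy=0.0,
    )


def _with_operating(params: ScenarioParams) -> ScenarioParams:
    return params.replace(
        price=effective_price(params),
        construction_subsidy=0.0,
        operating_subsidy=0.0,
    )


def trigger_construction(params: ScenarioParams) -> float:
    """Trigger under the construction subsidy.

    Q*_cs = beta1/(beta1-1) * delta*mu*(I_t - rho*N_s*S_cs) / (P*(1-e^{-delta T})),
    i.e. the unsubsidized trigger scaled by I'_t / I_t.
    """
    return trigger_value(_with_construction(params))


def trigger_operating(params: ScenarioParams) -> float:
    """Trigger under the operating subsidy.

    Q*_ps = beta1/(beta1-1) * delta*mu*I_t / ((P + theta*S_ps)*(1-e^{-delta T})),
    i.e. the unsubsidized trigger scaled by P / (P + theta*S_ps).
    """
    return trigger_value(_with_operating(params))


def required_construction_subsidy(params: ScenarioParams, demand: float) -> float:
    """Per-bed construction subsidy that triggers investment at the current demand.

    Inverts the subsidized trigger formula for S_cs:

        S_cs = I_t/(rho*N_s)
               - (beta1-1)/beta1 * P*Q*(1-e^{-delta T}) / (rho*N_s*delta*mu)

    for demand below the unsubsidized trigger; zero at and above it (no
    subsidy is needed once waiting is no longer optimal).
    """
    if not demand > 0:
        raise InvalidParameterError(f"demand must be positive, got {demand!r}")
    q_star = trigger_value(params)
    if demand >= q_star:
        return 0.0
    if params.rho == 0:
        raise InfeasiblePolicyError(
            "rho = 0: no construction subsidy can pass through to the investor"
        )
    roots = beta_roots(params)
    denom = params.rho * params.scale
    needed = (
        params.investment_cost
        - params.revenue_multiple * demand / (roots.wedge() * params.premium)
    ) / denom
    return max(needed, 0.0)


def required_operating_subsidy(params: ScenarioParams, demand: float) -> float:
    """Per-elder-year operating subsidy that triggers investment at the current demand.

    Inverts the subsidized trigger formula for S_ps:

        S_ps = beta1/(beta1-1) * delta*mu*I_t / (theta*Q*(1-e^{-delta T})) - P/theta

    for demand below the unsubsidized trigger; zero at and above it.
    Convex and decreasing in demand (hyperbolic in 1/Q).
    """
    if not demand > 0:
        raise InvalidParameterError(f"demand must be positive, got {demand!r}")
    q_star = trigger_value(params)
    if demand >= q_star:
        return 0.0
    if params.theta == 0:
        raise InfeasiblePolicyError(
            "theta = 0: no operating subsidy can pass through to the investor"
        )
    roots = beta_roots(params)
    price_needed = (
        roots.wedge()
        * params.delta
        * params.premium
        * params.investment_cost
        / (demand * params.discount_factor)
    )
    return max((price_needed - params.price) / params.theta, 0.0)


def option_value_construction(params: ScenarioParams, demand: float) -> float:
    """F_cs(Q): waiting value with the reduced cost below Q*_cs, payoff above."""
    return option_value(_with_construction(params), demand)


def net_value_construction(params: ScenarioParams, demand: float) -> float:
    """V_cs(Q) = P*Q*(1-e^{-delta T})/delta - mu*(I_t - rho*N_s*S_cs)."""
    return net_expected_value(_with_construction(params), demand)


def option_value_operating(params: ScenarioParams, demand: float) -> float:
    """F_ps(Q): waiting value with the raised price below Q*_ps, payoff above."""
    return option_value(_with_operating(params), demand)


def net_value_operating(params: ScenarioParams, demand: float) -> float:
    """V_ps(Q) = Q*(P + theta*S_ps)*(1-e^{-delta T})/delta - mu*I_t."""
    return net_expected_value(_with_operating(params), demand)


def subsidy_curves(
    params: ScenarioParams, demand_grid: Iterable[float]
) -> pd.DataFrame:
    """Required per-unit subsidy of each scheme on a demand grid.

    Columns ``(Q, S_cs_required, S_ps_required)``. The two curves are in
    different denominations (CNY per bed, one-time, vs CNY per
    elder-year, recurring); they are reported per-unit, as convention-
    ally plotted. See :func:`total_outlay` for a common-denomination view.
    """
    grid = np.asarray(list(demand_grid), dtype=float)
    return pd.DataFrame(
        {
            "Q": grid,
            "S_cs_required": [required_construction_subsidy(params, q) for q in grid],
            "S_ps_required": [required_operating_subsidy(params, q) for q in grid],
        }
    )


def total_outlay(params: ScenarioParams, demand_grid: Iterable[float]) -> pd.DataFrame:
    """Government outlay view of the required-subsidy curves.

    Not a like-for-like comparison of the per-unit curves: construction
    outlay ``S_cs * N_s`` is a one-time sum, operating outlay
    ``S_ps * Q`` recurs every year of operation. Provided so the
    per-unit curves are not mistaken for amounts in a common unit.
    """
    grid = np.asarray(list(demand_grid), dtype=float)
    s_cs = np.array([required_construction_subsidy(params, q) for q in grid])
    s_ps = np.array([required_operating_subsidy(params, q) for q in grid])
    return pd.DataFrame(
        {
            "Q": grid,
            "construction_outlay_once": s_cs * params.scale,
            "operating_outlay_per_year": s_ps * grid,
        }
    )


def spillover_table(
    params: ScenarioParams, demand_grid: Iterable[float]
) -> pd.DataFrame:
    """Subsidy spillovers to the investor on a demand grid.

    Columns ``(Q, dF_cs, dF_ps, dV_cs, dV_ps)`` where dX is the scheme
    value minus the unsubsidized value. With positive subsidy amounts
    all four are non-negative; dV_cs = mu*rho*N_s*S_cs is constant in Q
    and dV_ps = Q*theta*S_ps*(1-e^{-delta T})/delta grows linearly.
    """
    grid = np.asarray(list(demand_grid), dtype=float)
    rows = []
    for q in grid:
        f0 = option_value(params, q)
        v0 = net_expected_value(params, q)
        rows.append(
            (
                q,
                option_value_construction(params, q) - f0,
                option_value_operating(params, q) - f0,
                net_value_construction(params, q) - v0,
                net_value_operating(params, q) - v0,
            )
        )
    return pd.DataFrame(rows, columns=["Q", "dF_cs", "dF_ps", "dV_cs", "dV_ps"])


@dataclass(frozen=True)
class SchemeComparison:
    """Triggers, value orderings and spillovers of the two subsidy schemes."""

    trigger_none: float
    trigger_construction: float
    trigger_operating: float
    spillovers: pd.DataFrame
    ordering_holds: bool  # F_ps >= F_cs >= F and V_ps >= V_cs >= V on the grid
    preferred: SubsidyScheme
    rationale: str

    @property
    def triggers(self) -> dict[str, float]:
        return {
            "none": self.trigger_none,
            "construction": self.trigger_construction,
            "operating": self.trigger_operating,
        }


def compare_schemes(
    params: ScenarioParams, demand_grid: Iterable[float]
) -> SchemeComparison:
    """Compare the two schemes at equal nominal generosity on a demand grid.

    Reports the three triggers, whether the pointwise value ordering
    (operating above construction above none) holds everywhere on the
    grid, and the scheme with the lower trigger and larger spillovers.
    """
    grid = list(demand_grid)
    spill = spillover_table(params, grid)
    t_none = trigger_value(params)
    t_cs = trigger_construction(params)
    t_ps = trigger_operating(params)
    tol = 1e-9 * params.investment_cost
    ordering = bool(
        (spill["dF_ps"] >= spill["dF_cs"] - tol).all()
        and (spill["dV_ps"] >= spill["dV_cs"] - tol).all()
        and (spill[["dF_cs", "dF_ps", "dV_cs", "dV_ps"]] >= -tol).all().all()
    )
    if t_ps < t_cs and ordering:
        preferred = SubsidyScheme.OPERATING
        rationale = (
            "operating subsidy yields the lowest trigger "
            f"({t_ps:.1f} < {t_cs:.1f} < {t_none:.1f}) and the larger "
            "spillover option and net values on the comparison grid"
        )
    elif t_cs < t_ps:
        preferred = SubsidyScheme.CONSTRUCTION
        rationale = (
            f"construction subsidy yields the lower trigger ({t_cs:.1f} < {t_ps:.1f})"
        )
    else:
        preferred = SubsidyScheme.OPERATING if t_ps < t_none else SubsidyScheme.NONE
        rationale = "schemes tie on triggers; value ordering mixed on the grid"
    return SchemeComparison(
        trigger_none=t_none,
        trigger_construction=t_cs,
        trigger_operating=t_ps,
        spillovers=spill,
        ordering_holds=ordering,
        preferred=preferred,
        rationale=rationale,
    )
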