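"""GBM drift and volatility estimation from a panel of survey proportions.

Wave-level aggregates of a longitudinal survey — for each wave, the
number of valid respondents and the number living in nursing homes —
are converted to proportions Q_t (in percent). The demand dynamics are
then calibrated from the period-on-period relative changes

    omega_i = (Q_t - Q_{t-dy}) / Q_{t-dy},

with drift ``alpha = mean(omega) / dy`` and volatility ``sigma = k / dy``
where ``k = sqrt( sum_i (omega_i - mean(omega))^2 / (n - 2) )`` and n is
the number of waves (so n - 1 relative changes enter the sum). The
``k / dy`` time-scaling and the ``n - 2`` divisor are the conventions of
the calibration procedure this module reproduces; note that the usual
scaling of i.i.d. GBM increments would be ``k / sqrt(dy)`` instead — see
the package methods note for the consequences.

The packaged series (``clhls_waves``) holds the eight CLHLS waves
1998–2018 of nursing-home residence among the Chinese oldest-old, which
calibrate the baseline scenario to alpha = 0.005 and sigma = 0.12.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .params import InsufficientDataError, InvalidDataError

__all__ = [
    "SurveySeries",
    "EstimationResult",
    "clhls_waves",
    "relative_changes",
    "estimate_gbm",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.185 -> 0.19 at 2 dp), as printed tables round."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SurveySeries:
    """Wave-level survey aggregates with derived proportions.

    Either raw counts (``total_valid``, ``in_homes``) or ready-made
    ``proportions`` (percent) may be supplied; estimation depends only
    on the ordered proportion sequence.
    """

    years: tuple[int, ...]
    proportions: tuple[float, ...]  # percent, full precision
    total_valid: tuple[int, ...] | None = None
    in_homes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.years) != len(self.proportions):
            raise InvalidDataError("years and proportions must have equal length")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise InvalidDataError("wave years must be strictly increasing")
        if any(p < 0 for p in self.proportions):
            raise InvalidDataError("proportions must be non-negative")

    @classmethod
    def from_counts(
        cls,
        years: Sequence[int],
        total_valid: Sequence[int],
        in_homes: Sequence[int],
    ) -> "SurveySeries":
        """Build the series from raw counts; proportion = in_homes/total * 100."""
        years = tuple(int(y) for y in years)
        total = tuple(int(n) for n in total_valid)
        homes = tuple(int(c) for c in in_homes)
        if not len(years) == len(total) == len(homes):
            raise InvalidDataError("count columns must have equal length")
        for y, n, c in zip(years, total, homes):
            if n <= 0:
                raise InvalidDataError(f"wave {y}: total_valid must be positive")
            if not 0 <= c <= n:
                raise InvalidDataError(
                    f"wave {y}: in_homes must lie in [0, total_valid], got {c}/{n}"
                )
        props = tuple(100.0 * c / n for c, n in zip(homes, total))
        return cls(years=years, proportions=props, total_valid=total, in_homes=homes)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SurveySeries":
        """Read a (year, total_valid, in_homes) CSV, or (year, proportion)."""
        df = pd.read_csv(path)
        cols = set(df.columns)
        if {"year", "total_valid", "in_homes"} <= cols:
            return cls.from_counts(df["year"], df["total_valid"], df["in_homes"])
        if {"year", "proportion"} <= cols:
            return cls(
                years=tuple(int(y) for y in df["year"]),
                proportions=tuple(float(p) for p in df["proportion"]),
            )
        raise InvalidDataError(
            f"{path}: expected columns (year, total_valid, in_homes) or (year, proportion)"
        )

    def __len__(self) -> int:
        return len(self.years)

    def to_frame(self, display_dp: int | None = None) -> pd.DataFrame:
        """Tabular view; with ``display_dp`` the proportions are rounded half-up."""
        data: dict[str, object] = {"year": self.years}
        if self.total_valid is not None:
            data["total_valid"] = self.total_valid
            data["in_homes"] = self.in_homes
        props = self.proportions
        if display_dp is not None:
            props = tuple(round_half_up(p, display_dp) for p in props)
        data["proportion"] = props
        return pd.DataFrame(data)


def clhls_waves() -> SurveySeries:
    """The packaged eight-wave CLHLS nursing-home residence series (1998-2018)."""
    ref = importlib.resources.files("careoptions.data") / "clhls_waves.csv"
    with importlib.resources.as_file(ref) as path:
        return SurveySeries.from_csv(path)


def relative_changes(series: SurveySeries) -> np.ndarray:
    """Period-on-period relative changes omega_i of the proportion sequence.

    Computed on full-precision proportions; n waves yield n - 1 values.
    """
    if len(series) < 2:
        raise InsufficientDataError("at least 2 waves are needed for relative changes")
    q = np.asarray(series.proportions, dtype=float)
    if np.any(q[:-1] <= 0):
        raise InvalidDataError("relative changes undefined for a zero proportion")
    return np.diff(q) / q[:-1]


@dataclass(frozen=True)
class EstimationResult:
    """Calibrated GBM parameters and the intermediates that produce them."""

    omegas: tuple[float, ...]
    omega_mean: float
    drift: float        # per year
    k: float            # dispersion of the omegas (dimensionless)
    volatility: float   # per year, k / delta_y convention
    delta_y: float      # years per wave interval (scalar mode)
    n: int              # number of waves
    per_interval: bool = field(default=False)

    def summary(self) -> pd.DataFrame:
        """Per-interval table: omega_i and squared deviations, full precision."""
        w = np.asarray(self.omegas)
        return pd.DataFrame(
            {"omega": w, "sq_deviation": (w - self.omega_mean) ** 2}
        )


def estimate_gbm(
    series: SurveySeries, delta_y: float | str = 3.0
) -> EstimationResult:
    """Calibrate GBM drift and volatility from a survey proportion series.

    Parameters
    ----------
    series
        At least three waves of proportions.
    delta_y
        Scalar wave spacing in years (the calibration convention treats
        the panel as evenly spaced; default 3). Passing ``"actual"``
        switches to a diagnostic mode that divides each relative change
        by its actual year gap before averaging — useful when wave gaps
        are uneven, but not the convention the packaged series is meant
        to reproduce.

    Returns
    -------
    EstimationResult
        drift = mean(omega)/delta_y and volatility = k/delta_y with
        ``k = sqrt(sum (omega_i - mean)^2 / (n - 2))``, n = number of waves.
    """
    n = len(series)
    if n < 3:
        raise InsufficientDataError(f"estimation needs >= 3 waves, got {n}")
    omegas = relative_changes(series)

    if isinstance(delta_y, str):
        if delta_y != "actual":
            raise InvalidDataError(f"delta_y must be a number or 'actual', got {delta_y!r}")
        gaps = np.diff(np.asarray(series.years, dtype=float))
        rates = omegas / gaps  # per-year relative changes
        mean_rate = float(rates.mean())
        k = float(np.sqrt(np.sum((rates - mean_rate) ** 2) / (n - 2)))
        return EstimationResult(
            omegas=tuple(omegas),
            omega_mean=float(omegas.mean()),
            drift=mean_rate,
            k=k,
            volatility=k,
            delta_y=float(gaps.mean()),
            n=n,
            per_interval=True,
        )

    dy = float(delta_y)
    if dy <= 0:
        raise InvalidDataError(f"delta_y must be positive, got {delta_y!r}")
    omega_mean = float(omegas.mean())
    k = float(np.sqrt(np.sum((omegas - omega_mean) ** 2) / (n - 2)))
    return EstimationResult(
        omegas=tuple(omegas),
        omega_mean=omega_mean,
        drift=omega_mean / dy,
        k=k,
        volatility=k / dy,
        delta_y=dy,
        n=n,
    )
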