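"""The closed-form neonatal growth law and quantities derived from it.

Weight of a suckling puppy during its first three weeks follows, at maximum
growth rate, a log-quadratic law

    P(x) = P0 * exp(b1*x - b2*x**2)

with ``P`` the weight in grams on day ``x`` and ``P0`` the weight on day 0
(the birth day).  The published coefficients, estimated across breeds from
toy to giant size, are b1 = 0.13084 /day and b2 = 0.001616 /day**2.  All
curves with different P0 are parallel on a log scale: the relative daily
gain (dP/dx)/P = b1 - 2*b2*x depends on age only, falling linearly from
~13.1 %/day at birth to ~6.3 %/day on day 21.

The model is only meaningful over the neonatal window (days 0-21; data up
to day 28 were examined during development).  The quadratic exponent has a
vertex near day 40, which is an artifact: evaluation beyond day 28 emits
an :class:`ExtrapolationWarning`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UnreachableTargetError

__all__ = [
    "PUBLISHED_B1",
    "PUBLISHED_B2",
    "PUBLISHED_COEFFS",
    "EXTRAPOLATION_DAY_LIMIT",
    "GrowthCoefficients",
    "ExtrapolationWarning",
    "predict_weight",
    "daily_gain",
    "relative_daily_gain",
    "mean_relative_daily_gain",
    "time_to_multiple",
    "setback_adjusted_p0",
    "growth_chart_table",
    "export_chart_csv",
]

#: Published first-order (growth-rate) coefficient, per day.
PUBLISHED_B1 = 0.13084
#: Published second-order (deceleration) coefficient, per day squared.
PUBLISHED_B2 = 0.001616

#: Largest day ever examined during model development; beyond this the
#: quadratic exponent is pure extrapolation and a warning is emitted.
EXTRAPOLATION_DAY_LIMIT = 28


class ExtrapolationWarning(UserWarning):
    """Evaluation beyond the neonatal window the model was built for."""


@dataclass(frozen=True)
class GrowthCoefficients:
    """Shared slope pair (b1, b2) of the log-quadratic growth law.

    Both coefficients are stored positive, with the model exponent written
    ``b1*x - b2*x**2``; the derivative coefficient 2*b2 (= 0.003232 for the
    published values) is not an independent symbol.

    Parameters
    ----------
    b1 : float
        Growth-rate coefficient, per day.  Must be > 0.
    b2 : float
        Deceleration coefficient, per day squared.  Must be >= 0, and small
        enough that the model is strictly increasing over days 0-21.
    """

    b1: float = PUBLISHED_B1
    b2: float = PUBLISHED_B2

    def __post_init__(self) -> None:
        if not (self.b1 > 0):
            raise InvalidArgumentError(f"b1 must be > 0, got {self.b1}")
        if not (self.b2 >= 0):
            raise InvalidArgumentError(f"b2 must be >= 0, got {self.b2}")
        if self.b1 - 2.0 * self.b2 * 21.0 <= 0:
            raise InvalidArgumentError(
                "coefficients imply non-increasing weight before day 21 "
                f"(b1 - 2*b2*21 = {self.b1 - 2 * self.b2 * 21:.6g} <= 0)"
            )

    @property
    def vertex_day(self) -> float:
        """Day at which the quadratic exponent peaks (b1 / 2*b2)."""
        if self.b2 == 0:
            return math.inf
        return self.b1 / (2.0 * self.b2)

    def log_gain(self, day):
        """Exponent b1*x - b2*x**2 (log of the growth factor since day 0)."""
        day = np.asarray(day, dtype=float)
        out = self.b1 * day - self.b2 * day * day
        return out if out.ndim else float(out)

    def growth_factor(self, day):
        """Multiplicative growth since day 0, exp(b1*x - b2*x**2)."""
        out = np.exp(self.log_gain(np.asarray(day, dtype=float)))
        return out if out.ndim else float(out)


#: The published coefficient pair, usable wherever coefficients default.
PUBLISHED_COEFFS = GrowthCoefficients()


def _check_day(day) -> None:
    arr = np.asarray(day, dtype=float)
    if np.any(arr < 0):
        raise InvalidArgumentError(f"day must be >= 0, got {day}")
    if np.any(arr > EXTRAPOLATION_DAY_LIMIT):
        warnings.warn(
            f"evaluating the growth model beyond day {EXTRAPOLATION_DAY_LIMIT}; "
            "the law was developed for the neonatal window only",
            ExtrapolationWarning,
            stacklevel=3,
        )


def predict_weight(p0_g, day, coeffs: GrowthCoefficients = PUBLISHED_COEFFS):
    """Weight in grams on ``day`` for a puppy following the curve with ``p0_g``.

    Accepts scalars or numpy arrays (broadcast).  Exact ``p0_g`` at day 0.
    """
    if np.any(np.asarray(p0_g, dtype=float) <= 0):
        raise InvalidArgumentError(f"p0_g must be > 0, got {p0_g}")
    _check_day(day)
    out = np.asarray(p0_g, dtype=float) * coeffs.growth_factor(day)
    return out if np.ndim(out) else float(out)


def daily_gain(p0_g, day, coeffs: GrowthCoefficients = PUBLISHED_COEFFS):
    """Absolute daily weight gain dP/dx in g/day: P(x) * (b1 - 2*b2*x).

    Proportional to current weight, which is why heavier littermates pull
    away in absolute terms while growing at the same relative rate.
    """
    w = predict_weight(p0_g, day, coeffs)
    rate = coeffs.b1 - 2.0 * coeffs.b2 * np.asarray(day, dtype=float)
    out = w * rate
    return out if np.ndim(out) else float(out)


def relative_daily_gain(day, coeffs: GrowthCoefficients = PUBLISHED_COEFFS):
    """Relative daily gain (dP/dx)/P = b1 - 2*b2*x, fraction per day.

    Independent of the puppy's weight; linear and strictly decreasing in age.
    """
    _check_day(day)
    out = coeffs.b1 - 2.0 * coeffs.b2 * np.asarray(day, dtype=float)
    return out if np.ndim(out) else float(out)


def mean_relative_daily_gain(
    day_start: float, day_end: float, coeffs: GrowthCoefficients = PUBLISHED_COEFFS
) -> float:
    """Average relative daily gain over [day_start, day_end].

    The integrand is linear in x, so the closed form is
    b1 - b2*(day_start + day_end); over days 0-21 with the published
    coefficients this is 0.097, i.e. roughly 10 %/day.
    """
    if not (0 <= day_start < day_end):
        raise InvalidArgumentError(
            f"need 0 <= day_start < day_end, got ({day_start}, {day_end})"
        )
    _check_day(day_end)
    return float(coeffs.b1 - coeffs.b2 * (day_start + day_end))


def time_to_multiple(
    multiple: float,
    coeffs: GrowthCoefficients = PUBLISHED_COEFFS,
    start_ratio: float = 1.0,
) -> float:
    """Days until weight reaches ``multiple`` times birth weight.

    ``start_ratio`` is the current curve's P0 divided by birth weight, so a
    puppy that fell to a lower curve (start_ratio < 1) takes longer: solve
    b2*x**2 - b1*x + ln(multiple/start_ratio) = 0 and take the smaller
    non-negative root (the first crossing; the larger root lies beyond the
    model's validity).  Returns 0 when the target is already met.

    Raises
    ------
    UnreachableTargetError
        If the multiple exceeds the curve's maximum (negative discriminant).
    """
    if not (multiple > 0):
        raise InvalidArgumentError(f"multiple must be > 0, got {multiple}")
    if not (start_ratio > 0):
        raise InvalidArgumentError(f"start_ratio must be > 0, got {start_ratio}")
    target = math.log(multiple / start_ratio)
    if target <= 0:
        return 0.0
    if coeffs.b2 == 0:
        return target / coeffs.b1
    disc = coeffs.b1 * coeffs.b1 - 4.0 * coeffs.b2 * target
    if disc < 0:
        raise UnreachableTargetError(
            f"multiple {multiple} (from start ratio {start_ratio}) exceeds the "
            f"curve's maximum exp(b1^2/(4*b2)) = "
            f"{math.exp(coeffs.b1 ** 2 / (4 * coeffs.b2)):.3g}"
        )
    return (coeffs.b1 - math.sqrt(disc)) / (2.0 * coeffs.b2)


def setback_adjusted_p0(
    retained_fraction: float,
    at_day: float,
    coeffs: GrowthCoefficients = PUBLISHED_COEFFS,
) -> float:
    """P0 (as a fraction of birth weight) of the curve a set-back puppy joins.

    A puppy that still weighs ``retained_fraction`` of its birth weight on
    ``at_day`` and resumes maximum growth from there follows the curve
    passing through that point, whose day-0 value is
    retained_fraction / exp(b1*x - b2*x**2).

    E.g. no gain for 1 day -> 0.8788, a 20 % loss by day 2 -> 0.6198.
    """
    if not (0 < retained_fraction <= 1):
        raise InvalidArgumentError(
            f"retained_fraction must be in (0, 1], got {retained_fraction}"
        )
    if at_day < 0:
        raise InvalidArgumentError(f"at_day must be >= 0, got {at_day}")
    return float(retained_fraction / coeffs.growth_factor(at_day))


def growth_chart_table(
    p0_values: Sequence[float],
    day_start: int = 0,
    day_end: int = 21,
    coeffs: GrowthCoefficients = PUBLISHED_COEFFS,
) -> pd.DataFrame:
    """Growth-chart table: one row per day, one column per reference curve.

    Columns are named ``p0_<grams>``; the day-0 row reproduces the P0 list
    exactly.  This is the spreadsheet-friendly form of the model used for
    monitoring a puppy against its expected curve.
    """
    p0_list = [float(p) for p in p0_values]
    if len(p0_list) == 0:
        raise InvalidArgumentError("p0_values must not be empty")
    if any(p <= 0 for p in p0_list):
        raise InvalidArgumentError("all p0 values must be > 0")
    if day_end < day_start:
        raise InvalidArgumentError(
            f"day_end must be >= day_start, got ({day_start}, {day_end})"
        )
    days = np.arange(int(day_start), int(day_end) + 1)
    factors = coeffs.growth_factor(days.astype(float))
    factors = np.atleast_1d(factors)
    _check_day(days)

    def col_name(p: float) -> str:
        return f"p0_{p:g}"

    data = {col_name(p): p * factors for p in p0_list}
    table = pd.DataFrame(data, index=pd.Index(days, name="day"))
    return table


def export_chart_csv(table: pd.DataFrame, path) -> None:
    """Write a growth-chart table to CSV, weights at 1-decimal precision."""
    table.to_csv(path, float_format="%.1f")
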