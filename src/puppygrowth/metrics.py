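"""Goodness-of-fit statistics for validating fitted growth curves.

Three statistics compare observed (O) against model-predicted (P) weights:

* MARE — mean absolute relative error, mean(|O - P| / P).  Note the
  *predicted* value in the denominator, which is the definition used for
  this model's validation (conventional MARE divides by the observed
  value; that variant is available behind ``denominator="observed"`` and
  every report labels which was used).
* RMSE — sqrt(mean((O - P)**2)), in grams, so it scales with breed size.
* Through-origin regression y = a*x of predicted (y) on observed (x):
  a = sum(x*y)/sum(x**2), with the uncentered r² = 1 - SSE/sum(y**2)
  (the centered convention is ill-defined without an intercept).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "FitMetrics",
    "mare",
    "rmse",
    "origin_regression",
    "compute_metrics",
    "per_breed_metrics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitMetrics:
    """Validation statistics for one group of (observed, predicted) pairs."""

    mare: float
    mare_sd: float
    rmse: float
    origin_slope: float
    origin_r2: float
    n_obs: int
    n_off_curve: int = 0
    mare_denominator: str = "predicted"


def _as_pair(observed, predicted) -> Tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise InvalidArgumentError(
            f"observed and predicted must be equal-length 1-D, got {o.shape} vs {p.shape}"
        )
    if len(o) == 0:
        raise InvalidArgumentError("need at least one observation")
    return o, p


def mare(observed, predicted, denominator: str = "predicted") -> Tuple[float, float]:
    """Mean absolute relative error and its sd over observations."""
    o, p = _as_pair(observed, predicted)
    if denominator == "predicted":
        denom = p
    elif denominator == "observed":
        denom = o
    else:
        raise InvalidArgumentError(
            f"denominator must be 'predicted' or 'observed', got {denominator!r}"
        )
    if np.any(denom <= 0):
        raise InvalidArgumentError("denominator weights must be > 0")
    rel = np.abs(o - p) / denom
    sd = float(np.std(rel, ddof=1)) if len(rel) > 1 else 0.0
    return float(np.mean(rel)), sd


def rmse(observed, predicted) -> float:
    """Root mean squared error in grams."""
    o, p = _as_pair(observed, predicted)
    return float(np.sqrt(np.mean((o - p) ** 2)))


def origin_regression(observed, predicted) -> Tuple[float, float]:
    """Slope and uncentered r² of the no-intercept fit predicted = a*observed."""
    o, p = _as_pair(observed, predicted)
    if len(o) < 2:
        raise InvalidArgumentError("need >= 2 observations for a regression")
    sxx = float(np.sum(o * o))
    if sxx == 0:
        raise InvalidArgumentError("all observed values are zero")
    a = float(np.sum(o * p) / sxx)
    syy = float(np.sum(p * p))
    if syy == 0:
        raise InvalidArgumentError("all predicted values are zero")
    sse = float(np.sum((p - a * o) ** 2))
    return a, 1.0 - sse / syy


def compute_metrics(
    observed, predicted, n_off_curve: int = 0, denominator: str = "predicted"
) -> FitMetrics:
    """Bundle all three statistics for one group."""
    m, sd = mare(observed, predicted, denominator=denominator)
    o, p = _as_pair(observed, predicted)
    if len(o) >= 2:
        slope, r2 = origin_regression(o, p)
    else:
        slope, r2 = float("nan"), float("nan")
    return FitMetrics(
        mare=m,
        mare_sd=sd,
        rmse=rmse(o, p),
        origin_slope=slope,
        origin_r2=r2,
        n_obs=len(o),
        n_off_curve=n_off_curve,
        mare_denominator=denominator,
    )


def per_breed_metrics(
    records: pd.DataFrame,
    trajectories: Dict[str, "TrajectoryFit"],
    denominator: str = "predicted",
) -> pd.DataFrame:
    """Per-breed and pooled validation metrics from fitted trajectories.

    Predictions come from each puppy's fitted segments; off-curve
    (transition) days carry no model claim and are excluded, with the
    excluded count reported per breed.  Breeds whose puppies have no
    trajectory are skipped with a logged notice.  The pooled row is labeled
    ``all``.
    """
    fitted = []
    for pid, traj in trajectories.items():
        days = records.loc[records["puppy_id"] == pid, "day"].to_numpy()
        tbl = traj.fitted_table(record_days=days)
        if len(tbl):
            fitted.append(tbl)
    if not fitted:
        raise InvalidArgumentError("no fitted trajectories supplied")
    pred = pd.concat(fitted, ignore_index=True)[["puppy_id", "day", "predicted_g"]]
    merged = records.merge(pred, on=["puppy_id", "day"], how="left")
    merged = merged[merged["puppy_id"].isin(trajectories.keys())]

    rows = []
    groups = [("all", merged)] + [
        (breed, grp) for breed, grp in merged.groupby("breed", sort=True)
    ]
    for breed, grp in groups:
        on_curve = grp.dropna(subset=["predicted_g"])
        n_off = int(grp["predicted_g"].isna().sum())
        if len(on_curve) == 0:
            logger.info("breed %s skipped: no on-curve observations", breed)
            continue
        fm = compute_metrics(
            on_curve["weight_g"].to_numpy(),
            on_curve["predicted_g"].to_numpy(),
            n_off_curve=n_off,
            denominator=denominator,
        )
        rows.append(
            {
                "breed": breed,
                "n_obs": fm.n_obs,
                "n_off_curve": fm.n_off_curve,
                "mare": fm.mare,
                "mare_sd": fm.mare_sd,
                "rmse_g": fm.rmse,
                "origin_slope": fm.origin_slope,
                "origin_r2": fm.origin_r2,
                "mare_denominator": fm.mare_denominator,
            }
        )
    out = pd.DataFrame(rows)
    # pooled row first, then breeds alphabetically
    return out.reset_index(drop=True)
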