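"""Shared-slope estimation of the global growth coefficients.

All puppies grow, on log scale, along parallel curves: the model

    ln y = sum_i a_i * I_i + sum_j b_j * x**j      (j = 1..n)

has one indicator column I_i per puppy (its intercept a_i = ln P0_i) and a
single set of polynomial slope coefficients b_j shared by every puppy.
There is no global constant; the indicator block partitions the rows.
Fitting is ordinary least squares on ln-weight via statsmodels, with the
polynomial order chosen by a 95%-CI significance gate plus adjusted R².
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import (
    InsufficientGroupError,
    InvalidArgumentError,
    SelectionFailureError,
    SingularFitError,
    UnderdeterminedFitError,
)
from .model import GrowthCoefficients

__all__ = [
    "DEFAULT_FIT_DAY_MAX",
    "GlobalFitResult",
    "build_design_matrix",
    "fit_shared_slope_model",
    "select_order",
    "residual_diagnostics",
    "compare_sex_growth_rates",
]

logger = logging.getLogger(__name__)

#: Records beyond this day are excluded from global fitting by default
#: (model development examined data up to ~4 weeks).
DEFAULT_FIT_DAY_MAX = 28


@dataclass
class GlobalFitResult:
    """Output of the shared-slope log-polynomial regression.

    ``slope_table`` has one row per polynomial term (index ``x^j``) with
    columns estimate / se / ci_lo / ci_hi; ``intercepts`` maps puppy_id to
    (a_i, se) with a_i = ln P0_i.  R² and adjusted R² are computed on the
    ln scale about the response mean, with p = n_puppies + order parameters
    (the design has no global constant; this convention is fixed and
    matches reporting both statistics for such a design).
    """

    order: int
    slope_table: pd.DataFrame
    intercepts: Dict[str, Tuple[float, float]]
    r2: float
    adj_r2: float
    resid_se: float
    residuals: pd.DataFrame
    n_obs: int
    order_comparison: Optional[pd.DataFrame] = None

    @property
    def slope_coeffs(self) -> np.ndarray:
        return self.slope_table["estimate"].to_numpy()

    @property
    def coeffs(self) -> Optional[GrowthCoefficients]:
        """The (b1, b2) pair when the fit is quadratic, else None."""
        if self.order != 2:
            return None
        b1, b2 = self.slope_coeffs
        return GrowthCoefficients(b1=b1, b2=-b2 if b2 < 0 else b2) if b1 > 0 else None

    @property
    def p0_estimates(self) -> Dict[str, float]:
        """Per-puppy birth-curve P0 in grams, exp(a_i)."""
        return {pid: math.exp(a) for pid, (a, _) in self.intercepts.items()}

    def to_report(self) -> dict:
        """JSON-ready summary with fixed key names."""
        rep = {
            "order": self.order,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "resid_se": self.resid_se,
            "n_obs": self.n_obs,
            "slopes": {
                str(term): {
                    "estimate": float(row["estimate"]),
                    "se": float(row["se"]),
                    "ci95": [float(row["ci_lo"]), float(row["ci_hi"])],
                }
                for term, row in self.slope_table.iterrows()
            },
            "intercepts": {
                str(pid): float(a) for pid, (a, _) in self.intercepts.items()
            },
        }
        if self.order == 2:
            b = self.slope_coeffs
            rep["coeffs"] = {"b1": float(b[0]), "b2": float(-b[1])}
        return rep


def build_design_matrix(
    records: pd.DataFrame, order: int
) -> Tuple[pd.DataFrame, pd.Series]:
    """Design matrix and ln-weight response for the shared-slope model.

    Columns: one 0/1 indicator per puppy (in order of first appearance)
    followed by day, day**2, ..., day**order.  Every puppy needs at least
    order + 1 records for its intercept and the slopes to be identified.
    """
    if not (1 <= int(order) <= 4):
        raise InvalidArgumentError(f"order must be in 1..4, got {order}")
    order = int(order)
    if np.any(records["weight_g"].to_numpy() <= 0):
        raise InvalidArgumentError("all weights must be > 0")
    counts = records["puppy_id"].value_counts()
    too_few = counts[counts < order + 1]
    if len(too_few):
        raise UnderdeterminedFitError(
            f"puppy {too_few.index[0]!r} has only {int(too_few.iloc[0])} records; "
            f"order {order} needs at least {order + 1}"
        )
    puppies = list(dict.fromkeys(records["puppy_id"]))
    day = records["day"].to_numpy(dtype=float)
    cols = {pid: (records["puppy_id"] == pid).to_numpy(dtype=float) for pid in puppies}
    for j in range(1, order + 1):
        cols["x" if j == 1 else f"x^{j}"] = day**j
    X = pd.DataFrame(cols, index=records.index)
    y = pd.Series(np.log(records["weight_g"].to_numpy(dtype=float)),
                  index=records.index, name="ln_weight")
    return X, y


def fit_shared_slope_model(
    records: pd.DataFrame, order: int, day_max: int = DEFAULT_FIT_DAY_MAX
) -> GlobalFitResult:
    """OLS fit of the shared-slope log-polynomial model.

    Records beyond ``day_max`` are excluded.  Standard errors come from the
    usual unscaled OLS covariance times the residual variance; 95% CIs are
    t-based.
    """
    use = records[records["day"] <= day_max].reset_index(drop=True)
    X, y = build_design_matrix(use, order)
    n_puppies = len(X.columns) - order
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise SingularFitError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns)"
        )
    res = sm.OLS(y, X).fit()
    n, p = len(y), X.shape[1]
    ssr = float(np.sum(res.resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else float("nan")
    resid_se = math.sqrt(ssr / (n - p)) if n > p else float("nan")

    ci = res.conf_int(alpha=0.05)
    slope_terms = list(X.columns[n_puppies:])
    slope_table = pd.DataFrame(
        {
            "estimate": res.params[slope_terms],
            "se": res.bse[slope_terms],
            "ci_lo": ci.loc[slope_terms, 0],
            "ci_hi": ci.loc[slope_terms, 1],
        }
    )
    intercepts = {
        pid: (float(res.params[pid]), float(res.bse[pid]))
        for pid in X.columns[:n_puppies]
    }
    residuals = pd.DataFrame(
        {
            "puppy_id": use["puppy_id"],
            "day": use["day"],
            "residual": res.resid.to_numpy(),
        }
    )
    return GlobalFitResult(
        order=order,
        slope_table=slope_table,
        intercepts=intercepts,
        r2=r2,
        adj_r2=adj_r2,
        resid_se=resid_se,
        residuals=residuals,
        n_obs=n,
    )


def select_order(
    records: pd.DataFrame, max_order: int = 4, day_max: int = DEFAULT_FIT_DAY_MAX
) -> GlobalFitResult:
    """Fit orders 1..max_order and pick the best admissible one.

    An order is admissible when every slope coefficient's 95% CI excludes
    zero; among admissible orders the one with the highest adjusted R² wins,
    with ties broken toward the lower (more parsimonious) order.
    """
    if max_order < 1:
        raise InvalidArgumentError(f"max_order must be >= 1, got {max_order}")
    fits: List[GlobalFitResult] = []
    rows = []
    for order in range(1, max_order + 1):
        try:
            fit = fit_shared_slope_model(records, order, day_max=day_max)
        except (UnderdeterminedFitError, SingularFitError) as exc:
            rows.append(
                {"order": order, "r2": np.nan, "adj_r2": np.nan,
                 "all_slopes_significant": False, "note": str(exc)}
            )
            continue
        significant = bool(
            np.all(
                (fit.slope_table["ci_lo"] > 0) | (fit.slope_table["ci_hi"] < 0)
            )
        )
        rows.append(
            {"order": order, "r2": fit.r2, "adj_r2": fit.adj_r2,
             "all_slopes_significant": significant, "note": ""}
        )
        if significant:
            fits.append(fit)
    comparison = pd.DataFrame(rows)
    if not fits:
        raise SelectionFailureError(
            "no polynomial order had all slope coefficients significant at 95%",
            comparison=comparison,
        )
    # max adjusted R²; ties go to the lower order (fits are in ascending order)
    best = max(fits, key=lambda f: (f.adj_r2, -f.order))
    best.order_comparison = comparison
    return best


def residual_diagnostics(fit: GlobalFitResult, records: pd.DataFrame) -> dict:
    """Randomness checks on the fit residuals.

    Per sex: residual mean and a two-sided one-sample t test against 0.
    Per puppy: lag-1 sample autocorrelation of the day-ordered residuals,
    flagged when |r| exceeds the 1.96/sqrt(m) 95% bound for that puppy's
    series length m.  Puppies with fewer than 4 residuals are skipped with
    a logged notice.
    """
    resid = fit.residuals.merge(
        records[["puppy_id", "day", "sex"]], on=["puppy_id", "day"], how="left"
    )
    by_sex = {}
    for sex, grp in resid.groupby("sex"):
        e = grp["residual"].to_numpy()
        if len(e) >= 2 and np.std(e) > 0:
            t, p = scipy.stats.ttest_1samp(e, 0.0)
        else:
            t, p = 0.0, 1.0
        by_sex[sex] = {"n": len(e), "mean": float(np.mean(e)),
                       "t": float(t), "p": float(p)}

    per_puppy = []
    for pid, grp in resid.groupby("puppy_id", sort=False):
        e = grp.sort_values("day")["residual"].to_numpy()
        m = len(e)
        if m < 4:
            logger.info("puppy %s skipped in autocorrelation check (%d residuals)",
                        pid, m)
            continue
        ec = e - e.mean()
        denom = float(np.sum(ec**2))
        # residuals at floating-point round-off level are an exact fit
        if denom > 0 and float(np.max(np.abs(e))) > 1e-9:
            r1 = float(np.sum(ec[:-1] * ec[1:]) / denom)
        else:
            r1 = 0.0
        bound = 1.96 / math.sqrt(m)
        per_puppy.append(
            {"puppy_id": pid, "n": m, "lag1_autocorr": r1,
             "bound": bound, "flagged": abs(r1) > bound}
        )
    per_puppy_df = pd.DataFrame(per_puppy)
    n_flagged = int(per_puppy_df["flagged"].sum()) if len(per_puppy_df) else 0
    return {
        "by_sex": by_sex,
        "per_puppy": per_puppy_df,
        "n_flagged": n_flagged,
        "n_checked": len(per_puppy_df),
    }


def observed_relative_gains(records: pd.DataFrame) -> pd.DataFrame:
    """Per-puppy mean observed relative daily gain (w[d+1]-w[d])/w[d].

    Only consecutive-day pairs contribute; puppies with no such pair are
    dropped.  Returns columns puppy_id, sex, mean_rel_gain, n_pairs.
    """
    rows = []
    for pid, grp in records.groupby("puppy_id", sort=False):
        grp = grp.sort_values("day")
        day = grp["day"].to_numpy()
        w = grp["weight_g"].to_numpy(dtype=float)
        consec = np.flatnonzero(np.diff(day) == 1)
        if len(consec) == 0:
            continue
        gains = (w[consec + 1] - w[consec]) / w[consec]
        rows.append(
            {"puppy_id": pid, "sex": grp["sex"].iloc[0],
             "mean_rel_gain": float(np.mean(gains)), "n_pairs": len(gains)}
        )
    return pd.DataFrame(rows)


def compare_sex_growth_rates(records: pd.DataFrame, welch: bool = False) -> dict:
    """Two-sample t test of mean observed relative daily gain, males vs females.

    The unit of analysis is the puppy (its mean over consecutive-day weight
    ratios).  Pooled-variance Student t by default; Welch behind ``welch``.
    """
    gains = observed_relative_gains(records)
    groups = {}
    for sex in ("male", "female"):
        vals = gains.loc[gains["sex"] == sex, "mean_rel_gain"].to_numpy()
        if len(vals) < 2:
            raise InsufficientGroupError(
                f"need >= 2 {sex} puppies with consecutive-day records, "
                f"got {len(vals)}"
            )
        groups[sex] = vals
    t, p = scipy.stats.ttest_ind(
        groups["male"], groups["female"], equal_var=not welch
    )
    return {
        "male": {"n": len(groups["male"]),
                 "mean": float(np.mean(groups["male"])),
                 "sd": float(np.std(groups["male"], ddof=1))},
        "female": {"n": len(groups["female"]),
                   "mean": float(np.mean(groups["female"])),
                   "sd": float(np.std(groups["female"], ddof=1))},
        "t": float(t),
        "p": float(p),
        "test": "welch" if welch else "pooled_t",
    }
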