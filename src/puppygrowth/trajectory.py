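"""Per-puppy piecewise description of a weight series as growth-curve segments.

With the global coefficients fixed, each puppy's series is described as an
ordered sequence of maximum-growth curves with strictly decreasing P0: a
puppy may "fall" from its current curve to a lower one (insufficient
nursing, milk production, ...) but is never observed to sustainably grow
faster than the law allows, so it never rejoins a higher curve.  Days that
sit on no curve (the 1-2 transition days of a fall, or an initial
stagnation/loss phase before the first curve is joined) are reported as
off-curve.

P0 of a segment is the exact closed-form least-squares minimizer in weight
space: with g_i = exp(b1*x_i - b2*x_i**2), P0 = sum(w_i*g_i)/sum(g_i**2).

Segmentation finds the *optimal piecewise description* of the series: the
chain of candidate curve segments that covers the most measurements with
the fewest curves, subject to the domain constraints (P0 strictly
decreasing by at least a minimum separation; at least ``min_seg_len``
member days per curve).  Candidate segments are all day intervals whose
robustly refitted curve keeps both endpoints within a membership
tolerance; the best chain is selected exactly by dynamic programming —
a daily series over three weeks is small enough that nothing needs to be
heuristic.  The membership tolerance adapts to the series' own noise
scale (estimated from second differences of log-weight), capped at the
drop threshold (default 0.03, ~3% in weight, above the ~2% noise floor of
breeder scales with 5-g divisions), so exact data is described exactly
while noisy data is not over-segmented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidArgumentError, UnsegmentableError
from .model import PUBLISHED_COEFFS, GrowthCoefficients

__all__ = [
    "Segment",
    "TrajectoryFit",
    "estimate_p0",
    "segment_trajectory",
    "classify_pattern",
    "population_summary",
]

#: Tolerance (log scale) for deciding that the day-0 measurement lies on
#: the first fitted curve, i.e. the puppy "gained from Day 0".  Wider than
#: the drop threshold because a single noisy measurement should not veto
#: membership of a curve whose P0 is estimated from the whole segment.
CURVE_MATCH_TOL_FACTOR = 2.0

#: A puppy with an initial stagnation/loss (trough within the first 2 days)
#: that joins a curve within 3 further days has joined by day 5.
DEFAULT_JOIN_DAY_LIMIT = 5


@dataclass(frozen=True)
class Segment:
    """One growth-curve segment: days [start_day, end_day] following one P0."""

    start_day: int
    end_day: int
    p0_g: float
    days: Tuple[int, ...]

    @property
    def n_points(self) -> int:
        return len(self.days)

    def predict(self, day, coeffs: GrowthCoefficients):
        return self.p0_g * coeffs.growth_factor(np.asarray(day, dtype=float))


@dataclass
class TrajectoryFit:
    """Piecewise curve description of one puppy's weight series."""

    puppy_id: str
    segments: List[Segment]
    off_curve_days: List[int]
    coeffs: GrowthCoefficients
    gained_from_day0: Optional[bool]
    days_to_first_curve: Optional[int]

    @property
    def n_curves(self) -> int:
        return len(self.segments)

    @property
    def pattern(self) -> str:
        return "single_curve" if self.n_curves == 1 else "multi_curve"

    @property
    def p0_sequence(self) -> List[float]:
        return [s.p0_g for s in self.segments]

    def fitted_table(self, record_days=None) -> pd.DataFrame:
        """Per-day fitted weights over each segment's day span.

        Every recorded day inside a segment's [start_day, end_day] span is
        predicted by that segment's curve — including noisy days that were
        not used to fit P0 — since the curve claims the whole period.
        Days between segments (fall transitions, the pre-join phase) carry
        no model claim and are absent.  With ``record_days=None`` only the
        fitted member days are tabulated.
        """
        rows = []
        for k, seg in enumerate(self.segments):
            if record_days is None:
                span = seg.days
            else:
                span = [
                    int(d) for d in record_days
                    if seg.start_day <= d <= seg.end_day
                ]
            for d in span:
                rows.append(
                    {
                        "puppy_id": self.puppy_id,
                        "day": d,
                        "segment": k,
                        "p0_g": seg.p0_g,
                        "predicted_g": float(seg.predict(d, self.coeffs)),
                    }
                )
        return pd.DataFrame(rows)

    def to_report(self) -> dict:
        return {
            "puppy_id": self.puppy_id,
            "n_curves": self.n_curves,
            "pattern": self.pattern,
            "segments": [
                {"start_day": s.start_day, "end_day": s.end_day,
                 "p0_g": s.p0_g, "n_points": s.n_points}
                for s in self.segments
            ],
            "off_curve_days": list(self.off_curve_days),
            "gained_from_day0": self.gained_from_day0,
            "days_to_first_curve": self.days_to_first_curve,
        }


def _extract_series(records) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        df = records.sort_values("day")
        days = df["day"].to_numpy(dtype=int)
        weights = df["weight_g"].to_numpy(dtype=float)
    else:
        days, weights = records
        order = np.argsort(np.asarray(days))
        days = np.asarray(days, dtype=int)[order]
        weights = np.asarray(weights, dtype=float)[order]
    if np.any(weights <= 0):
        raise InvalidArgumentError("all weights must be > 0")
    if len(np.unique(days)) != len(days):
        raise InvalidArgumentError("duplicate days in weight series")
    return days, weights


def estimate_p0(
    records,
    coeffs: GrowthCoefficients = PUBLISHED_COEFFS,
    day_window: Optional[Tuple[float, float]] = None,
    log_space: bool = False,
) -> float:
    """Least-squares P0 of the single curve best fitting a weight series.

    Default is the closed-form weight-space minimizer of
    sum((w_i - P0*g_i)**2), i.e. sum(w_i*g_i)/sum(g_i**2) — the same
    criterion a spreadsheet solver minimizes on raw weights.  With
    ``log_space=True`` the log-space variant exp(mean(ln w_i - ln g_i)) is
    used instead (useful for sensitivity checks; it weights all days
    equally on the relative scale).
    """
    days, weights = _extract_series(records)
    if day_window is not None:
        lo, hi = day_window
        keep = (days >= lo) & (days <= hi)
        days, weights = days[keep], weights[keep]
    if len(days) < 2:
        raise InsufficientDataError(
            f"need >= 2 records to estimate P0, got {len(days)}"
        )
    log_g = coeffs.log_gain(days.astype(float))
    if log_space:
        return float(np.exp(np.mean(np.log(weights) - log_g)))
    g = np.exp(log_g)
    return float(np.sum(weights * g) / np.sum(g * g))


def _noise_scale(days: np.ndarray, logw: np.ndarray) -> float:
    """Robust noise scale of a log-weight series from second differences.

    On the model curve the second difference of ln(weight) over consecutive
    days is the essentially negligible curvature -2*b2; for i.i.d.
    measurement noise its variance is 6 sigma**2.  The median absolute
    second difference is robust against the handful of fall days.
    """
    d2 = []
    for k in range(1, len(days) - 1):
        if days[k] - days[k - 1] == 1 and days[k + 1] - days[k] == 1:
            d2.append(logw[k + 1] - 2 * logw[k] + logw[k - 1])
    if len(d2) < 4:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d2))) / math.sqrt(6.0)


class _Candidate:
    __slots__ = ("a", "b", "members", "p0", "sse")

    def __init__(self, a, b, members, p0, sse):
        self.a, self.b, self.members, self.p0, self.sse = a, b, members, p0, sse


class _Segmenter:
    """Exact optimal-chain segmentation engine for one series."""

    def __init__(self, days, weights, coeffs, drop_threshold, min_seg_len,
                 min_fall):
        self.days = days
        self.w = weights
        self.logw = np.log(weights)
        self.lng = np.asarray(coeffs.log_gain(days.astype(float)))
        self.g = np.exp(self.lng)
        self.n = len(days)
        self.msl = min_seg_len
        self.thr = drop_threshold
        sigma = _noise_scale(days, self.logw)
        #: membership tolerance: 2.5 robust sigmas, floored at a third of
        #: the drop threshold and capped at the drop threshold itself
        self.tol = min(self.thr, max(2.5 * sigma, self.thr / 3.0))
        #: minimum log-separation between successive curves: both curves'
        #: membership bands must be disjoint, and never less than the
        #: absolute floor (estimation bias of a short segment can reach
        #: the tolerance, so anything closer is not a resolvable fall)
        self.min_sep = max(min_fall, 2.0 * self.tol)
        #: a minimum-length curve has no internal redundancy — its level
        #: is certified only to about sigma/sqrt(2) — so its separation
        #: must additionally clear a 99% one-sided margin on that level
        self.min_sep_weak = (
            self.min_sep + 2.33 * (self.tol / 2.5) / math.sqrt(2.0)
        )

    def est(self, idx) -> float:
        g = self.g[idx]
        return float(np.sum(self.w[idx] * g) / np.sum(g * g))

    def resid(self, idx, p0: float) -> np.ndarray:
        return self.logw[idx] - math.log(p0) - self.lng[idx]

    def fit_interval(self, a: int, b: int) -> Optional[_Candidate]:
        """Robustly fit one curve to [a, b]; None if not a valid segment.

        Iteratively reweights membership: fit P0 by least squares on the
        current members, keep the interval's points within tolerance,
        repeat to a fixed point.  The interval is canonical only if both
        endpoints remain members.
        """
        idx_all = np.arange(a, b + 1)
        # initialize membership from the median curve offset: the median
        # register is robust to the minority of off-curve days, where a
        # least-squares start can drift between registers
        med = float(np.median(self.logw[idx_all] - self.lng[idx_all]))
        inside = np.abs(self.logw[idx_all] - self.lng[idx_all] - med) <= self.tol
        members = idx_all[inside]
        if len(members) < self.msl:
            return None
        for _ in range(8):
            p0 = self.est(members)
            inside = np.abs(self.resid(idx_all, p0)) <= self.tol
            new = idx_all[inside]
            if len(new) < self.msl:
                return None
            if np.array_equal(new, members):
                break
            members = new
        p0 = self.est(members)
        if members[0] != a or members[-1] != b:
            return None
        r = self.resid(members, p0)
        return _Candidate(a, b, members, p0, float(np.sum(r * r)))

    def candidates(self) -> List[_Candidate]:
        out = {}
        for a in range(0, self.n - self.msl + 1):
            for b in range(a + self.msl - 1, self.n):
                cand = self.fit_interval(a, b)
                if cand is not None:
                    key = tuple(cand.members)
                    if key not in out:
                        out[key] = cand
        return sorted(out.values(), key=lambda c: (c.a, c.b))

    def best_chain(self) -> List[_Candidate]:
        """Exact DP over ordered candidate chains.

        Objective, lexicographic: net coverage (member days minus 1.5
        per curve, so an extra curve must explain at least two days no
        other curve explains), then fewest curves, then smallest total
        log-space SSE.  Chain constraints: intervals strictly ordered,
        successive P0 separated by at least the minimum downward
        separation (with an extra certification margin when either curve
        has only the minimum number of members), and a minimum-length
        curve never starts flush against its predecessor (a real fall
        always leaves an off-curve transition day).
        """
        cands = self.candidates()
        if not cands:
            return []
        m = len(cands)
        # Net coverage: a curve must explain substantially more than one
        # day that no other curve explains, so each member day is worth 1
        # and each curve costs 1.5; ties go to fewer curves, then to the
        # smaller total log-space SSE.
        seg_price = 1.5
        values = [len(ci.members) - seg_price for ci in cands]
        best: List[Tuple[float, float, float]] = []
        prev: List[int] = []
        for i, ci in enumerate(cands):
            score = (values[i], -1.0, -ci.sse)
            link = -1
            for j in range(i):
                cj = cands[j]
                if cj.b >= ci.a:
                    continue
                sep_needed = (
                    self.min_sep_weak
                    if self.msl in (len(ci.members), len(cj.members))
                    else self.min_sep
                )
                if not ci.p0 <= cj.p0 * math.exp(-sep_needed):
                    continue
                if len(ci.members) == self.msl and ci.a == cj.b + 1:
                    # every real fall leaves at least one off-curve
                    # transition day; a minimum-length "curve" starting
                    # flush against the previous one is that transition
                    continue
                cand_score = (
                    best[j][0] + values[i],
                    best[j][1] - 1.0,
                    best[j][2] - ci.sse,
                )
                if cand_score > score:
                    score = cand_score
                    link = j
            best.append(score)
            prev.append(link)
        end = max(range(m), key=lambda i: best[i])
        chain = []
        while end != -1:
            chain.append(cands[end])
            end = prev[end]
        return chain[::-1]


def segment_trajectory(
    records,
    coeffs: GrowthCoefficients = PUBLISHED_COEFFS,
    drop_threshold: float = 0.03,
    min_run: int = 2,
    min_seg_len: int = 2,
    min_fall: Optional[float] = None,
    puppy_id: Optional[str] = None,
) -> TrajectoryFit:
    """Describe one puppy's series as curves with strictly decreasing P0.

    The returned description is the optimal chain of candidate curve
    segments: most days covered, then fewest curves.  Days belonging to no
    segment (fall transitions, the initial stagnation/loss phase, isolated
    outliers) are reported in ``off_curve_days``.

    Parameters
    ----------
    records : DataFrame with columns day/weight_g, or (days, weights) arrays
        One puppy's series; at least 3 records.
    drop_threshold : float
        Upper bound on the curve-membership tolerance of the log-residual
        (0.03 ~ 3% in weight); the effective tolerance adapts downward for
        data cleaner than that.
    min_run : int
        Kept for interface stability; the optimal search makes it
        redundant (a fall is only ever recognized when the lower curve
        has at least ``min_seg_len`` member days).
    min_seg_len : int
        Minimum member days per segment (>= 2 so P0 is a fit, not a point).
    min_fall : float, optional
        Floor on the log-separation between successive curves (default
        4/3 of ``drop_threshold``); the effective separation additionally
        requires the two curves' membership bands to be disjoint.
    """
    if isinstance(records, pd.DataFrame) and puppy_id is None and len(records):
        if "puppy_id" in records.columns:
            puppy_id = str(records["puppy_id"].iloc[0])
    days, weights = _extract_series(records)
    n = len(days)
    if n < 3:
        raise InvalidArgumentError(f"need >= 3 records, got {n}")
    if min_seg_len < 2:
        raise InvalidArgumentError("min_seg_len must be >= 2")
    if min_fall is None:
        min_fall = drop_threshold * 4.0 / 3.0
    seg_engine = _Segmenter(days, weights, coeffs, drop_threshold,
                            min_seg_len, min_fall)
    chain = seg_engine.best_chain()

    # A minimum-length first curve starting after the first record can be
    # a chance alignment in the pre-join stagnation phase.  The giveaway
    # is the day right after it: a stagnating puppy's weight stays put,
    # while a puppy on a real curve keeps growing near the model rate (or
    # falls, which moves the weight too).  Such a flat-continued, loosely
    # fitting claim stays off-curve.
    def _flat_after(cand) -> bool:
        nxt = cand.members[-1] + 1
        if nxt >= n:
            return False
        return (
            abs(seg_engine.logw[nxt] - seg_engine.logw[cand.members[-1]])
            <= seg_engine.tol
        )

    while (
        len(chain) >= 2
        and len(chain[0].members) == min_seg_len
        and chain[0].a > 0
        and np.max(np.abs(seg_engine.resid(chain[0].members, chain[0].p0)))
        > drop_threshold / 3.0
        and _flat_after(chain[0])
    ):
        chain = chain[1:]

    if not chain:
        raise UnsegmentableError(
            f"no growth-curve segment of >= {min_seg_len} points could be "
            f"formed (puppy {puppy_id!r})"
        )

    assigned = set()
    segments = []
    for cand in chain:
        assigned.update(int(k) for k in cand.members)
        segments.append(
            Segment(
                start_day=int(days[cand.members[0]]),
                end_day=int(days[cand.members[-1]]),
                p0_g=cand.p0,
                days=tuple(int(days[k]) for k in cand.members),
            )
        )
    p0s = [s.p0_g for s in segments]
    assert all(a > b for a, b in zip(p0s, p0s[1:])), "P0 must strictly decrease"

    off_days = sorted(int(days[k]) for k in range(n) if k not in assigned)

    # The day the puppy joined its first curve is measured as the first
    # day whose weight lies on that curve within the match tolerance
    # (wider than the membership band: one noisy measurement should not
    # defer the join).  "Gained from day 0" is the same question asked of
    # the day-0 record.
    match_tol = CURVE_MATCH_TOL_FACTOR * drop_threshold
    first_resid = np.log(weights) - math.log(segments[0].p0_g) - np.asarray(
        coeffs.log_gain(days.astype(float))
    )
    matching = np.flatnonzero(
        (np.abs(first_resid) <= match_tol) & (days <= segments[0].start_day)
    )
    join_day = int(days[matching[0]]) if len(matching) else int(segments[0].start_day)
    gained: Optional[bool] = None
    if 0 in days:
        gained = join_day == 0
    return TrajectoryFit(
        puppy_id=puppy_id or "",
        segments=segments,
        off_curve_days=off_days,
        coeffs=coeffs,
        gained_from_day0=gained,
        days_to_first_curve=join_day,
    )


def classify_pattern(traj: TrajectoryFit, records) -> dict:
    """Summary of one trajectory's growth pattern.

    ``initial_loss_fraction`` is the minimum of w_d/w_0 over days 0-2 when
    below 1 (None when the puppy never dipped below its day-0 weight in
    that window, or day 0 is unrecorded).
    """
    days, weights = _extract_series(records)
    initial_loss: Optional[float] = None
    if 0 in days:
        w0 = float(weights[np.flatnonzero(days == 0)[0]])
        early = weights[(days >= 0) & (days <= 2)] / w0
        ratio = float(np.min(early))
        if ratio < 1:
            initial_loss = ratio
    return {
        "puppy_id": traj.puppy_id,
        "pattern": traj.pattern,
        "n_curves": traj.n_curves,
        "gained_from_day0": traj.gained_from_day0,
        "initial_loss_fraction": initial_loss,
        "days_to_first_curve": traj.days_to_first_curve,
    }


def population_summary(
    trajectories: Sequence[TrajectoryFit],
    join_day_limit: int = DEFAULT_JOIN_DAY_LIMIT,
) -> dict:
    """Population proportions of the growth-pattern taxonomy.

    Reports the fraction following a single curve, the fraction following
    three or more, the distribution of curve counts, the fraction that
    gained from day 0 (among those where day 0 was recorded) and — among
    the puppies that started with a drop — the fraction whose first curve
    started by ``join_day_limit`` (trough within 2 days + 3 days to join).
    """
    trajs = list(trajectories)
    if not trajs:
        raise InvalidArgumentError("need at least one trajectory")
    n = len(trajs)
    n_curves = [t.n_curves for t in trajs]
    known_day0 = [t for t in trajs if t.gained_from_day0 is not None]
    gainers = [t for t in known_day0 if t.gained_from_day0]
    droppers = [t for t in known_day0 if not t.gained_from_day0]
    joined_prompt = [
        t for t in droppers if t.days_to_first_curve <= join_day_limit
    ]
    dist: Dict[int, int] = {}
    for c in n_curves:
        dist[c] = dist.get(c, 0) + 1
    return {
        "n_puppies": n,
        "frac_single_curve": sum(c == 1 for c in n_curves) / n,
        "frac_three_plus_curves": sum(c >= 3 for c in n_curves) / n,
        "n_curves_distribution": dict(sorted(dist.items())),
        "n_day0_known": len(known_day0),
        "frac_gained_from_day0": (
            len(gainers) / len(known_day0) if known_day0 else float("nan")
        ),
        "n_with_initial_drop": len(droppers),
        "frac_joined_within_limit": (
            len(joined_prompt) / len(droppers) if droppers else float("nan")
        ),
        "join_day_limit": join_day_limit,
    }
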