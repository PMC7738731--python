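# Methods

## The growth law

Weight of a suckling puppy over its first three weeks is modelled as

    P(x) = P0 · exp(b1·x − b2·x²),   b1 = 0.13084 /day, b2 = 0.001616 /day²

with `P0` the day-0 value of the curve. The model's content is threefold:

1. **Parallel log-curves.** All puppies share the slope pair (b1, b2);
   individuals differ only in `P0`. Equivalently, the relative daily gain
   (dP/dx)/P = b1 − 2·b2·x is a function of age alone, decreasing
   linearly from 13.1 %/day at birth to 6.3 %/day on day 21 (mean
   b1 − b2·(0+21) = 0.097 over the window).
2. **Maximum growth.** The curves describe growth free of limiting
   factors. Observed growth never sustainably exceeds them; deviations
   are one-sided.
3. **Falls.** A puppy may leave its curve and, after 1–2 transition
   days, follow a curve with strictly lower `P0`. No puppy rejoins a
   higher curve; a setback is never recovered within the window.

Assumptions and limits: the law is valid on days 0–21 (data to ~day 28
were examined during development); the quadratic exponent peaks near day
40, which is an artifact of the polynomial, so any evaluation past day 28
emits an `ExtrapolationWarning`. Coefficients are stored as a positive
pair (b1, b2) with the exponent written `b1·x − b2·x²`; the derivative
coefficient 2·b2 = 0.003232 is not an independent parameter. Days are
real-valued in the core (the doubling time 5.7 is fractional); charting
uses integer grids. Display rounding is one decimal for days and
percentages; full precision is kept internally.

A note on the two setback scenarios: the curve joined after retaining a
fraction r of birth weight at day x has P0 = r / exp(b1·x − b2·x²) times
birth weight. For "no gain in the first 24 h" this is 0.8788 and for "a
20 % loss by 48 h" 0.6198; chart-style presentations sometimes round
these to 0.9 and 0.615, but the analytic values are what this package
returns.

## Global coefficient estimation (`jointfit`)

The shared-slope model is fitted as ordinary least squares on ln-weight
with one 0/1 indicator column per puppy (intercept a_i = ln P0_i) and
common polynomial columns x, x², …, xⁿ — no global constant; the
indicator block partitions the rows. Standard errors and 95 % CIs are the
usual t-based OLS quantities. R² and adjusted R² are computed about the
response mean with p = n_puppies + order parameters; this convention is
fixed and documented because the design lacks a constant. Records beyond
day 28 are excluded from fitting by default.

Order selection fits n = 1…4 and keeps, among orders whose every slope
CI excludes zero, the one with the highest adjusted R², breaking ties
toward the lower order (on exactly quadratic data orders 2–4 all give
adjusted R² = 1 to machine precision; parsimony decides). On noisy
multi-puppy data small cubic/quartic terms can reach nominal
significance; the analysis drivers therefore always report the quadratic
fit alongside the gate's choice.

Residual diagnostics: per-sex residual means with a one-sample t test
against zero, and per-puppy lag-1 autocorrelation flagged beyond
±1.96/√m (m = series length; puppies with <4 residuals are skipped,
series at float round-off level count as exact fits). The sex comparison
uses each puppy's mean observed relative daily gain over consecutive-day
pairs and a pooled-variance two-sample t test (Welch behind a flag).

## Trajectory segmentation (`trajectory`)

The study identified curve-following periods visually and adjusted `P0`
per period by least squares on the raw weights. This package mechanizes
both steps.

**P0 estimation** is the exact weight-space minimizer: with
g_i = exp(b1·x_i − b2·x_i²), P0 = Σw_i·g_i / Σg_i² (a log-space variant,
exp(mean(ln w − ln g)), is available for sensitivity checks).

**Segmentation** finds the optimal piecewise description by exhaustive
search — a daily series over three weeks has at most ~22 points, so no
heuristic is needed:

* *Candidates*: every day interval whose robustly refitted curve keeps
  both endpoints within the membership tolerance. The fit starts from
  the interval's median curve offset (robust to the minority of
  off-curve days) and iterates least squares / membership to a fixed
  point.
* *Membership tolerance*: `min(thr, max(2.5·σ̂, thr/3))` with
  thr = `drop_threshold` = 0.03 (≈3 % in weight, above the ~2 % noise
  floor of breeder scales with 5-g divisions) and σ̂ a robust noise scale
  from second differences of ln-weight (variance 6σ² under i.i.d.
  noise). Exact data thus gets a tight band — fall-transition days,
  which sit a few percent off *every* curve, are never absorbed — while
  noisy data uses the full threshold.
* *Chain constraints*: segments are ordered with strictly decreasing
  P0; successive curves must be separated by at least
  `max(min_fall, 2·tol)` in log (membership bands must be disjoint, and
  never less than the floor `min_fall` = 4/3·thr — anything closer is
  indistinguishable from estimation bias). A minimum-length (2-point)
  curve has no internal redundancy, so its separation must additionally
  clear a 99 % one-sided margin on its level estimate; and it may not
  start flush against the previous curve (every real fall leaves at
  least one off-curve transition day).
* *Objective*: dynamic programming maximizes net coverage — member days
  minus 1.5 per curve, so an extra curve must explain at least two days
  no other curve explains — with ties to fewer curves, then smaller
  log-space SSE. This resolves exactly the cases where a greedy
  forward pass fails: whether two early points are a genuine short first
  curve or noise, and whether a pair of transition days is a curve of
  its own.
* *Pre-join guard*: a minimum-length first curve that starts after the
  first record, immediately gives way to a lower curve, fits no better
  than the noise floor, and is followed by a flat day is indistinguishable
  from a chance alignment in the descent/stagnation phase before the
  first curve is joined; it stays off-curve.

`min_run` is kept in the signature for interface stability but is
redundant under the optimal search (a fall is recognized only when the
lower curve has ≥ `min_seg_len` member days).

Classification: the day the first curve was joined is the first day whose
weight lies within 2·thr (log) of that curve — deliberately wider than
the membership band so one noisy measurement cannot defer the join — and
"gained from day 0" is that question asked of the day-0 record (reported
as unknown when day 0 was not weighed, e.g. litters first weighed later).
Population summaries report the single-curve fraction, the ≥3-curves
fraction, the curve-count distribution, the gained-from-day-0 fraction
and, among puppies that started with a drop, the fraction joining a curve
by day 5 (trough within 2 days + 3 days to join).

## Validation metrics (`metrics`)

MARE = mean|O − P|/P with the **predicted** value in the denominator —
that is the definition used for this model's validation; the conventional
observed-denominator variant is implemented behind a flag and every
report labels which was used. RMSE = √(mean(O−P)²) in grams. The
through-origin regression fits predicted = a·observed with
a = Σxy/Σx² and the uncentered r² = 1 − SSE/Σy² (the centered convention
is ill-defined without an intercept).

Predictions cover every recorded day inside a segment's day span — the
curve claims the whole period, including noisy days not used to fit P0;
excluding them would bias MARE down by scoring only well-fitting days.
Only between-segment days (fall transitions, the pre-join phase) carry no
model claim; their count is reported for transparency.

## Synthetic data (`simulate`)

The study's raw data are private, so the generator emulates its reported
structure, with the generative truth carried alongside every series:

| parameter | default | meaning |
|---|---|---|
| breeds | 19-breed table | litters, litter sizes, birth-weight ranges (70–1,000 g overall); birth weights uniform within range |
| p_gain_from_day0 | 0.48 | follows the birth-weight curve from day 0 |
| p_initial_loss | 0.33 | population share starting with a distinct (>2 %) loss, up to `initial_loss_max` = 0.20, trough within 2 days |
| max_days_to_join_curve / p_join_within_max | 3 / 0.96 | a dropper joins a curve within 3 days of its trough with this probability |
| p_single_curve / p_three_plus_curves | 0.10 / 0.67 | curve-count pattern (three-plus split 2:1 between 3 and 4 curves) |
| fall_magnitude | (0.05, 0.15) | uniform fall sizes; timing uniform over feasible days |
| fall_min_separation_days | 4 | keeps every intermediate curve observable ≥2 days given 1–2 transition days |
| noise_sd_log | 0.026 | multiplicative noise; E\|ε\| = σ√(2/π) ≈ 2.07 %, calibrating the pipeline MARE to ≈2 % |
| scale_quantum_g | 5 | rounding to the scale's divisions, applied after noise |

The reported starting proportions do not sum to one (48 % gainers + ~one
third with a distinct loss); the remaining ~19 % are modelled as
non-gainers with a near-flat start (<2 % loss). Fall transitions
interpolate log-linearly between the two curves over 1–2 days. Sex has no
effect on generated growth (none was found in the first three weeks); a
config hook (`sex_growth_effect`) can inject one for power studies.
Identical seeds give byte-identical datasets.

What the generator does **not** emulate: litter-level correlation of
growth (litters share a dam; here puppies are independent given their
birth weight), day-to-day correlated noise (weighing conditions), missing
weighing days, and any association between breed and fall frequency.
Passing tests therefore demonstrate correctness of the pipeline under the
reported population structure, not robustness to those real-data
features.

## Problem sizes and calibration results

The test suite and the analysis drivers use: five exact puppies (days
0–21) for coefficient recovery; 100-replicate Monte-Carlo runs for CI
coverage, diagnostics flag rates and fall-recovery; a 400-puppy
single-breed cohort for binomial checks of the pattern proportions; and
the full 19-breed table (..330 puppies, ~7,300 weights) for the
validation metrics. With the calibrated measurement process the pipeline
reproduces an all-breeds MARE of ≈1.8 %, breed RMSE growing with size,
and a through-origin slope within 0.005 of unity.

## Known limitations

* **Two-point curves are at the information limit.** At 2.6 % noise a
  curve observed for only two days is hard to distinguish from a fall's
  two transition days or from two same-direction noise excursions; the
  certification margins above resolve most, not all, such cases. In
  fall-recovery experiments (falls ≥8 %, 1–2 transition days, ≥4-day
  separation) the curve count is recovered in ≈90 of 100 seeded
  trajectories; with exact measurements recovery is 100/100 with every
  P0 within 1 %.
* **Detection attenuates the ≥3-curves fraction.** Falls drawn near the
  5 % floor are below the resolvable separation at the calibrated noise,
  so the measured ≥3-curves share of a default population (~0.56) sits
  below the generative 0.67; the single-curve and gained-from-day-0
  fractions are recovered within binomial bounds. Calibration checks of
  the generator itself use the truth registry.
* The global fit assumes independent residuals; litter effects would
  require a mixed model, deliberately out of scope.
* The published Table-level statistics of the real cohorts (R² = 0.9948,
  breed MAREs, p = 0.92) cannot be recomputed without the private data;
  the synthetic analogues above stand in for them qualitatively.
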