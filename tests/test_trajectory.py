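"""Per-puppy curve-fall segmentation and pattern classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import puppygrowth as pg
from puppygrowth.errors import InsufficientDataError, InvalidArgumentError
from puppygrowth.simulate import simulate_puppy
from puppygrowth.trajectory import population_summary

C = pg.PUBLISHED_COEFFS
DAYS = np.arange(22)


def curve(p0, days=DAYS):
    return p0 * C.growth_factor(np.asarray(days, dtype=float))


class TestEstimateP0:
    def test_exact_series_recovers_p0(self):
        days = np.arange(11)
        assert pg.estimate_p0((days, curve(300.0, days))) == pytest.approx(
            300.0, abs=1e-10
        )

    def test_two_point_series_matches_grid_search_oracle(self):
        days = np.array([0, 1])
        weights = np.array([100.0, 120.0])
        est = pg.estimate_p0((days, weights))
        grid = np.linspace(50, 200, 300001)
        g = C.growth_factor(days.astype(float))
        sse = ((weights[None, :] - grid[:, None] * g[None, :]) ** 2).sum(axis=1)
        assert est == pytest.approx(grid[np.argmin(sse)], rel=1e-5)

    @given(
        p0=st.floats(min_value=80, max_value=900),
        scale=st.floats(min_value=0.5, max_value=2.0),
    )
    @settings(max_examples=30, derandomize=True)
    def test_scaling_weights_scales_estimate(self, p0, scale):
        days = np.arange(8)
        w = curve(p0, days) * np.exp(0.01 * np.sin(days.astype(float)))
        assert pg.estimate_p0((days, w * scale)) == pytest.approx(
            scale * pg.estimate_p0((days, w)), rel=1e-12
        )

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, derandomize=True)
    def test_matches_grid_oracle_on_noisy_instances(self, seed):
        rng = np.random.default_rng(seed)
        days = np.sort(rng.choice(21, size=5, replace=False))
        p0 = rng.uniform(100, 800)
        w = curve(p0, days) * np.exp(rng.normal(0, 0.03, 5))
        est = pg.estimate_p0((days, w))
        g = C.growth_factor(days.astype(float))
        grid = est * np.linspace(0.98, 1.02, 20001)
        sse = ((w[None, :] - grid[:, None] * g[None, :]) ** 2).sum(axis=1)
        assert abs(grid[np.argmin(sse)] / est - 1) < 1e-4

    def test_log_space_variant(self):
        days = np.arange(5)
        w = curve(200.0, days)
        assert pg.estimate_p0((days, w), log_space=True) == pytest.approx(
            200.0, rel=1e-10
        )

    def test_day_window_filter(self):
        days = np.arange(10)
        w = curve(250.0, days).copy()
        w[5:] *= 0.8  # later points on a lower curve
        est = pg.estimate_p0((days, w), day_window=(0, 4))
        assert est == pytest.approx(250.0, abs=1e-9)

    def test_single_record_rejected(self):
        with pytest.raises(InsufficientDataError):
            pg.estimate_p0((np.array([3]), np.array([200.0])))


class TestSegmentation:
    def test_exact_single_curve(self):
        t = pg.segment_trajectory((DAYS, curve(403.0)), puppy_id="rr")
        assert t.n_curves == 1
        assert t.pattern == "single_curve"
        assert t.segments[0].p0_g == pytest.approx(403.0, abs=1e-9)
        assert t.off_curve_days == []
        assert t.gained_from_day0 is True
        assert t.days_to_first_curve == 0

    def test_constructed_fall_with_transition_days(self):
        w = np.empty(22)
        w[:10] = curve(250.0, DAYS[:10])
        w[10] = 250.0 * C.growth_factor(10.0) * math.exp(-0.036)
        w[11] = 250.0 * C.growth_factor(11.0) * math.exp(-0.050)
        w[12:] = curve(230.0, DAYS[12:])
        t = pg.segment_trajectory((DAYS, w))
        assert [(s.start_day, s.end_day) for s in t.segments] == [(0, 9), (12, 21)]
        assert t.segments[0].p0_g == pytest.approx(250.0, abs=1e-6)
        assert t.segments[1].p0_g == pytest.approx(230.0, abs=1e-6)
        assert t.off_curve_days == [10, 11]

    def test_oscillation_within_threshold_is_one_segment(self):
        w = curve(300.0) * np.exp(0.01 * np.cos(2.0 * DAYS))
        t = pg.segment_trajectory((DAYS, w))
        assert t.n_curves == 1

    def test_p0_strictly_decreasing_and_partition(self):
        rng = np.random.default_rng(99)
        cfg = pg.cohort_config(4, fall_magnitude=(0.08, 0.15))
        for s in range(25):
            pup = simulate_puppy("p", float(rng.uniform(150, 800)), cfg, rng)
            t = pg.segment_trajectory(pup.records)
            p0s = t.p0_sequence
            assert all(a > b for a, b in zip(p0s, p0s[1:]))
            seg_days = [d for seg in t.segments for d in seg.days]
            assert len(seg_days) == len(set(seg_days))
            assert sorted(seg_days + t.off_curve_days) == list(DAYS)

    def test_idempotent_on_fitted_predictions(self):
        w = np.concatenate([curve(400.0, DAYS[:9]), curve(340.0, DAYS[9:])])
        t1 = pg.segment_trajectory((DAYS, w))
        fitted = t1.fitted_table()
        t2 = pg.segment_trajectory(
            (fitted["day"].to_numpy(), fitted["predicted_g"].to_numpy())
        )
        assert [s.p0_g for s in t2.segments] == pytest.approx(
            [s.p0_g for s in t1.segments], rel=1e-9
        )

    def test_noise_free_recovery_30_seeds(self):
        ok = 0
        for s in range(30):
            cfg = pg.cohort_config(
                4, noise_sd_log=0.0, scale_quantum_g=0.0,
                fall_magnitude=(0.05, 0.15), p_gain_from_day0=1.0,
                force_n_segments=1 + s % 4,
            )
            rng = np.random.default_rng(s)
            pup = simulate_puppy("p", float(rng.uniform(250, 500)), cfg, rng)
            t = pg.segment_trajectory(pup.records)
            true = pup.truth["segments"]
            ok += t.n_curves == len(true) and all(
                abs(seg.p0_g - tr[2]) / tr[2] < 0.01
                for seg, tr in zip(t.segments, true)
            )
        assert ok == 30

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pg.segment_trajectory((np.array([0, 1]), np.array([100.0, 113.0])))


class TestClassifyPattern:
    def test_single_curve_gainer(self):
        t = pg.segment_trajectory((DAYS, curve(300.0)))
        out = pg.classify_pattern(t, (DAYS, curve(300.0)))
        assert out["gained_from_day0"] is True
        assert out["days_to_first_curve"] == 0
        assert out["initial_loss_fraction"] is None

    def test_initial_loss_then_join_at_day3(self):
        w = np.empty(22)
        w[0] = 300.0
        w[1] = 270.0
        w[2] = 240.0  # 20% below birth weight
        p0 = 240.0 / C.growth_factor(3.0)
        w[3:] = curve(p0, DAYS[3:])
        t = pg.segment_trajectory((DAYS, w))
        out = pg.classify_pattern(t, (DAYS, w))
        assert out["initial_loss_fraction"] == pytest.approx(0.8)
        assert out["days_to_first_curve"] == 3
        assert out["gained_from_day0"] is False

    def test_three_segment_trajectory(self):
        w = np.concatenate(
            [curve(400.0, DAYS[:7]), curve(350.0, DAYS[7:14]), curve(300.0, DAYS[14:])]
        )
        t = pg.segment_trajectory((DAYS, w))
        out = pg.classify_pattern(t, (DAYS, w))
        assert out["n_curves"] == 3
        assert out["pattern"] == "multi_curve"


class TestPopulationSummary:
    def test_counting(self):
        single = pg.segment_trajectory((DAYS, curve(300.0)))
        trajs = [single] * 1 + [
            pg.segment_trajectory(
                (DAYS, np.concatenate([curve(400.0, DAYS[:9]), curve(330.0, DAYS[9:])]))
            )
        ] * 9
        summ = population_summary(trajs)
        assert summ["frac_single_curve"] == pytest.approx(0.1)
        assert summ["frac_three_plus_curves"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            population_summary([])

    def test_measured_proportions_recover_configuration(self):
        """Gained-from-day0 and single-curve fractions land inside exact
        binomial 95% bounds of the configured probabilities at n=400."""
        ds = pg.simulate_population(pg.cohort_config(400, seed=11))
        trajs = [
            pg.segment_trajectory(grp, puppy_id=str(p))
            for p, grp in ds.records.groupby("puppy_id", sort=False)
        ]
        summ = population_summary(trajs)
        n = summ["n_puppies"]
        for key, p in [("frac_gained_from_day0", 0.48), ("frac_single_curve", 0.10)]:
            half = 1.96 * math.sqrt(p * (1 - p) / n)
            assert p - half <= summ[key] <= p + half, (key, summ[key])
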