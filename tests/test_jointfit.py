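"""Shared-slope regression: design, estimation, order selection, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import puppygrowth as pg
from puppygrowth.errors import (
    InsufficientGroupError,
    SelectionFailureError,
    SingularFitError,
    UnderdeterminedFitError,
)
from conftest import make_records


class TestDesignMatrix:
    def test_shape_and_partition(self):
        rec = make_records({"A": 200.0, "B": 300.0}, days=[0, 1, 2])
        X, y = pg.build_design_matrix(rec, order=2)
        assert X.shape == (6, 4)
        indicator = X[["A", "B"]].to_numpy()
        assert (indicator.sum(axis=1) == 1).all()

    def test_row_contents(self):
        rec = make_records({"A": 150.0, "B": 200.0}, days=[1, 2, 3])
        X, y = pg.build_design_matrix(rec, order=2)
        row = rec[(rec.puppy_id == "B") & (rec.day == 3)].index[0]
        assert list(X.loc[row, ["A", "B", "x", "x^2"]]) == [0.0, 1.0, 3.0, 9.0]
        assert y.loc[row] == pytest.approx(math.log(rec.loc[row, "weight_g"]))

    @pytest.mark.parametrize("order", [1, 2, 3, 4])
    def test_column_count(self, order):
        rec = make_records({f"P{i}": 100.0 + 50 * i for i in range(3)})
        X, _ = pg.build_design_matrix(rec, order)
        assert X.shape[1] == 3 + order

    def test_underdetermined_puppy_named(self):
        rec = pd.concat(
            [
                make_records({"ok": 300.0}, days=range(10)),
                make_records({"thin": 200.0}, days=[0, 1]),
            ]
        ).reset_index(drop=True)
        with pytest.raises(UnderdeterminedFitError, match="thin"):
            pg.build_design_matrix(rec, order=2)


class TestSharedSlopeFit:
    def test_exact_recovery_of_generating_coefficients(self, five_puppies_exact):
        fit = pg.fit_shared_slope_model(five_puppies_exact, order=2)
        b1, b2 = fit.slope_coeffs
        assert b1 == pytest.approx(pg.PUBLISHED_B1, abs=1e-8)
        assert -b2 == pytest.approx(pg.PUBLISHED_B2, abs=1e-8)
        for (a, _), p0 in zip(fit.intercepts.values(), [150, 250, 350, 450, 600]):
            assert a == pytest.approx(math.log(p0), abs=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.adj_r2 <= fit.r2 + 1e-15

    def test_permutation_invariance(self, five_puppies_exact):
        shuffled = five_puppies_exact.sample(frac=1.0, random_state=3).reset_index(
            drop=True
        )
        f1 = pg.fit_shared_slope_model(five_puppies_exact, 2)
        f2 = pg.fit_shared_slope_model(shuffled, 2)
        assert np.allclose(f1.slope_coeffs, f2.slope_coeffs, atol=1e-12)
        for pid in f1.intercepts:
            assert f1.intercepts[pid][0] == pytest.approx(
                f2.intercepts[pid][0], abs=1e-12
            )

    def test_shifting_one_puppy_moves_only_its_intercept(self, five_puppies_exact):
        rec = five_puppies_exact.copy()
        c = 0.25
        mask = rec.puppy_id == "P2"
        rec.loc[mask, "weight_g"] *= math.exp(c)
        base = pg.fit_shared_slope_model(five_puppies_exact, 2)
        bumped = pg.fit_shared_slope_model(rec, 2)
        assert np.allclose(base.slope_coeffs, bumped.slope_coeffs, atol=1e-10)
        for pid in base.intercepts:
            delta = bumped.intercepts[pid][0] - base.intercepts[pid][0]
            assert delta == pytest.approx(c if pid == "P2" else 0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        # tiny instance solved independently via the normal equations
        rec = make_records({"A": 180.0, "B": 320.0}, days=[0, 2, 5, 9],
                           noise_sd=0.05, seed=4)
        X, y = pg.build_design_matrix(rec, order=2)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fit = pg.fit_shared_slope_model(rec, 2)
        est = np.concatenate(
            [[fit.intercepts["A"][0], fit.intercepts["B"][0]], fit.slope_coeffs]
        )
        assert np.allclose(est, beta, atol=1e-9)

    def test_rank_deficiency_raises(self):
        # a puppy weighed three times on the same day: its indicator column
        # is collinear with the slope columns
        bad = pd.DataFrame(
            {
                "puppy_id": ["C"] * 3,
                "litter_id": "L",
                "breed": "X",
                "sex": "female",
                "day": [7, 7, 7],
                "weight_g": [500.0, 501.0, 499.0],
            }
        )
        with pytest.raises(SingularFitError):
            pg.fit_shared_slope_model(bad, 2)

    def test_coverage_of_true_coefficients(self):
        """95% CIs should cover the generating slopes in >= 90/100 replicates."""
        rng = np.random.default_rng(12345)
        cover = 0
        for _ in range(100):
            p0s = {f"P{i}": p for i, p in
                   enumerate(rng.uniform(150, 600, 14))}
            rec = make_records(p0s, noise_sd=0.048, seed=int(rng.integers(2**31)))
            fit = pg.fit_shared_slope_model(rec, 2)
            st_ = fit.slope_table
            ok1 = st_.loc["x", "ci_lo"] <= pg.PUBLISHED_B1 <= st_.loc["x", "ci_hi"]
            ok2 = (
                st_.loc["x^2", "ci_lo"] <= -pg.PUBLISHED_B2 <= st_.loc["x^2", "ci_hi"]
            )
            cover += ok1 and ok2
        assert cover >= 90


class TestOrderSelection:
    def test_quadratic_data_selects_order_2(self, five_puppies_exact):
        fit = pg.select_order(five_puppies_exact)
        assert fit.order == 2
        assert fit.order_comparison is not None
        assert len(fit.order_comparison) == 4

    def test_pure_exponential_selects_order_1(self):
        c = pg.GrowthCoefficients(b1=0.12, b2=0.0)
        rec = make_records(
            {f"P{i}": p for i, p in enumerate([150, 250, 350, 450, 600])},
            coeffs=c, noise_sd=0.02, seed=7,
        )
        assert pg.select_order(rec).order == 1

    def test_max_order_1_returns_order_1(self, five_puppies_exact):
        assert pg.select_order(five_puppies_exact, max_order=1).order == 1

    def test_selection_failure_carries_table(self):
        # pure noise around a constant: no slope is significant
        rng = np.random.default_rng(0)
        rec = make_records({"A": 1.0, "B": 1.0}, days=range(8))
        rec["weight_g"] = np.exp(rng.normal(5.5, 0.001, len(rec)))
        with pytest.raises(SelectionFailureError) as err:
            pg.select_order(rec, max_order=2)
        assert err.value.comparison is not None


class TestResidualDiagnostics:
    def test_noise_free_fit_has_no_flags(self, five_puppies_exact):
        fit = pg.fit_shared_slope_model(five_puppies_exact, 2)
        diag = pg.residual_diagnostics(fit, five_puppies_exact)
        assert diag["n_flagged"] == 0
        for sex_stats in diag["by_sex"].values():
            assert sex_stats["mean"] == pytest.approx(0.0, abs=1e-10)

    def test_alternating_residuals_flagged(self):
        e = 0.05 * np.array([1, -1] * 8)
        ec = e - e.mean()
        r1 = float(np.sum(ec[:-1] * ec[1:]) / np.sum(ec**2))
        assert r1 == pytest.approx(-1.0, abs=0.1)
        # wire the construction through the public API
        fit = pg.fit_shared_slope_model(
            make_records({"A": 200.0, "B": 300.0}, days=range(16)), 2
        )
        fit.residuals["residual"] = np.concatenate([e, e])
        diag = pg.residual_diagnostics(
            fit, make_records({"A": 200.0, "B": 300.0}, days=range(16))
        )
        assert diag["n_flagged"] == 2

    def test_iid_noise_flag_rate_at_most_10pct(self):
        flags = checked = 0
        for s in range(100):
            rec = make_records(
                {f"P{i}": p for i, p in enumerate(range(150, 550, 50))},
                noise_sd=0.03, seed=500 + s,
            )
            fit = pg.fit_shared_slope_model(rec, 2)
            diag = pg.residual_diagnostics(fit, rec)
            flags += diag["n_flagged"]
            checked += diag["n_checked"]
        assert flags / checked <= 0.10

    def test_short_series_skipped(self, five_puppies_exact):
        rec = pd.concat(
            [five_puppies_exact, make_records({"tiny": 200.0}, days=[0, 1, 2])]
        ).reset_index(drop=True)
        fit = pg.fit_shared_slope_model(rec, 2)
        diag = pg.residual_diagnostics(fit, rec)
        assert "tiny" not in set(diag["per_puppy"].get("puppy_id", []))


class TestSexComparison:
    def test_mirrored_groups_give_t0_p1(self):
        males = make_records(
            {f"M{i}": p for i, p in enumerate([200.0, 300.0, 400.0])},
            sex={f"M{i}": "male" for i in range(3)},
        )
        females = males.copy()
        females["puppy_id"] = females["puppy_id"].str.replace("M", "F")
        females["sex"] = "female"
        res = pg.compare_sex_growth_rates(pd.concat([males, females]))
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0, abs=1e-12)

    def test_null_p_values_uniform(self):
        """Equal-mean groups with unequal spread: p ~ U(0,1) over seeds."""
        ps = []
        for s in range(200):
            rng = np.random.default_rng(1000 + s)
            rows = []
            for i in range(20):
                sex = "male" if i < 10 else "female"
                p0 = rng.uniform(200, 500)
                sd = 0.02 if i < 10 else 0.04
                days = np.arange(11.0)
                w = p0 * pg.PUBLISHED_COEFFS.growth_factor(days) * np.exp(
                    rng.normal(0, sd, 11)
                )
                rows += [
                    dict(puppy_id=f"S{s}P{i}", litter_id="L", breed="X",
                         sex=sex, day=int(d), weight_g=float(wd))
                    for d, wd in zip(days, w)
                ]
            ps.append(pg.compare_sex_growth_rates(pd.DataFrame(rows))["p"])
        ks = scipy.stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_single_puppy_group_rejected(self):
        rec = make_records(
            {"M1": 300.0, "M2": 350.0, "F1": 320.0},
            sex={"M1": "male", "M2": "male", "F1": "female"},
        )
        with pytest.raises(InsufficientGroupError):
            pg.compare_sex_growth_rates(rec)
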