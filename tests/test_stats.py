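"""Outcome statistics: odds ratios, Kaplan-Meier/log-rank, Cox hazard
ratios (with a brute-force partial-likelihood oracle), baseline tests and
Benjamini-Hochberg adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from amlmeta.cohort import default_aml_spec, generate_cohort
from amlmeta.stats import (
    bh_adjust,
    compare_baseline,
    cox_hazard_ratio,
    cr_odds_ratio,
    km_and_logrank,
    km_curve,
    outcome_report,
    report_to_frame,
)


def two_group_exponential(n_per_group, median0, median1, seed, censor_frac=0.2):
    """Exponential survival in two groups with per-group exponential
    censoring tuned to the requested censoring fraction."""
    rng = np.random.default_rng(seed)
    lam = np.array([np.log(2) / median0, np.log(2) / median1])
    labels = np.repeat([0, 1], n_per_group)
    t_event = rng.exponential(1.0 / lam[labels])
    mu = lam[labels] * censor_frac / (1 - censor_frac)
    t_cens = rng.exponential(1.0 / mu)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(float)
    return times, events, labels


class TestOddsRatio:
    def test_cross_product_example(self):
        # cluster 30 CR / 20 no-CR, remainder 20 CR / 30 no-CR
        cr = np.array([1.0] * 30 + [0.0] * 20 + [1.0] * 20 + [0.0] * 30)
        labels = np.array([0] * 50 + [1] * 50)
        est = cr_odds_ratio(cr, labels, 0)
        assert est.estimate == pytest.approx(2.25)  # (30*30)/(20*20)
        assert est.ci_low < 2.25 < est.ci_high
        assert est.flag is None

    def test_identical_rates_or_one(self):
        cr = np.array([1.0, 0.0] * 40)
        labels = np.array([0] * 40 + [1] * 40)
        est = cr_odds_ratio(cr, labels, 0)
        assert est.estimate == pytest.approx(1.0)
        assert est.p_value > 0.9

    def test_zero_cell_haldane_correction(self):
        cr = np.array([1.0] * 20 + [1.0] * 15 + [0.0] * 15)
        labels = np.array([0] * 20 + [1] * 30)
        est = cr_odds_ratio(cr, labels, 0)  # cluster has zero non-responders
        assert np.isfinite(est.estimate) and est.estimate > 1
        assert est.flag == "haldane_anscombe"

    def test_missing_cr_dropped(self):
        cr = np.array([1.0, 0.0, np.nan, 1.0, 0.0, np.nan])
        labels = np.array([0, 0, 0, 1, 1, 1])
        est = cr_odds_ratio(cr, labels, 0)
        assert est.estimate == pytest.approx(1.0)

    def test_agrees_with_logistic_regression(self):
        # the 2x2 Wald estimate is the indicator logistic-regression OR
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 300)
        cr = (rng.random(300) < np.where(labels == 0, 0.7, 0.45)).astype(float)
        est = cr_odds_ratio(cr, labels, 0)
        X = sm.add_constant((labels == 0).astype(float))
        fit = sm.Logit(cr, X).fit(disp=0)
        assert est.estimate == pytest.approx(float(np.exp(fit.params[1])), rel=1e-6)


class TestKaplanMeier:
    def test_all_events_at_seven(self):
        times = np.full(30, 7.0)
        events = np.ones(30)
        labels = np.zeros(30, dtype=int)
        labels[:15] = 1
        surv = km_and_logrank(times, events, labels)
        assert surv.medians[0] == 7.0 and surv.medians[1] == 7.0
        curve = km_curve(times, events)
        assert curve.loc[curve["time"] < 7, "survival"].min() == 1.0
        assert curve.loc[curve["time"] >= 7, "survival"].max() == 0.0

    def test_all_censored_median_not_reached(self):
        times = np.linspace(1, 20, 40)
        events = np.zeros(40)
        labels = np.repeat([0, 1], 20)
        surv = km_and_logrank(times, events, labels)
        assert np.isinf(surv.medians[0]) and np.isinf(surv.medians[1])

    def test_km_equals_empirical_without_censoring(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(10, 200)
        curve = km_curve(times, np.ones(200))
        for _, row in curve.iloc[1:].iterrows():
            emp = (times > row["time"]).mean()
            assert row["survival"] == pytest.approx(emp, abs=1e-12)

    def test_exponential_medians_and_logrank(self):
        times, events, labels = two_group_exponential(2000, 12.0, 24.0, seed=0)
        surv = km_and_logrank(times, events, labels)
        assert surv.medians[0] == pytest.approx(12.0, rel=0.1)
        assert surv.medians[1] == pytest.approx(24.0, rel=0.1)
        assert surv.logrank_p < 0.001
        # numbers at risk decrease over the requested time points
        at_risk = surv.at_risk.loc[0].to_numpy()
        assert (np.diff(at_risk) <= 0).all()

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_and_logrank(np.array([-1.0, 2.0]), np.ones(2), np.array([0, 1]))


def cox_partial_loglik(beta, times, events, x):
    """Brute-force Breslow partial log-likelihood (no ties in simulation)."""
    order = np.argsort(times)
    t, e, x = times[order], events[order], x[order]
    ll = 0.0
    for i in np.flatnonzero(e == 1):
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_true_hazard_ratio_recovered(self):
        times, events, labels = two_group_exponential(2000, 12.0, 24.0, seed=1)
        est = cox_hazard_ratio(times, events, labels, 0)  # group 0 has 2x hazard
        assert 1.8 <= est.estimate <= 2.2
        assert est.ci_low < est.estimate < est.ci_high
        assert est.p_value < 1e-6

    def test_identical_groups_hr_near_one(self):
        times, events, labels = two_group_exponential(500, 12.0, 12.0, seed=2)
        est = cox_hazard_ratio(times, events, labels, 0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_matches_partial_likelihood_oracle(self):
        rng = np.random.default_rng(7)
        for seed in range(3):
            times, events, labels = two_group_exponential(9, 5.0, 15.0, seed=seed)
            est = cox_hazard_ratio(times, events, labels, 0)
            x = (labels == 0).astype(float)
            res = minimize_scalar(
                lambda b: -cox_partial_loglik(b, times, events, x),
                bounds=(-5, 5),
                method="bounded",
                options={"xatol": 1e-10},
            )
            assert est.estimate == pytest.approx(float(np.exp(res.x)), abs=1e-3)

    def test_covariate_support(self):
        import pandas as pd

        times, events, labels = two_group_exponential(300, 10.0, 20.0, seed=3)
        cov = pd.DataFrame({"age": np.random.default_rng(8).normal(55, 10, 600)})
        est = cox_hazard_ratio(times, events, labels, 0, covariates=cov)
        assert est.estimate > 1.0


class TestLogrankCalibration:
    def test_null_rejection_rate(self):
        # identical groups: log-rank should reject at alpha=0.05 in ~5% of runs
        rejections = 0
        for rep in range(200):
            times, events, labels = two_group_exponential(50, 12.0, 12.0, seed=1000 + rep)
            surv = km_and_logrank(times, events, labels)
            rejections += surv.logrank_p < 0.05
        assert 0.02 <= rejections / 200 <= 0.08


class TestCompareBaseline:
    def test_rank_identical_groups(self):
        # three groups with identical values {1,2,3}: whichever route the
        # normality gate takes, the contrast is null with p = 1
        values = np.array([1.0, 2.0, 3.0] * 3)
        labels = np.repeat([0, 1, 2], 3)
        test = compare_baseline(values, labels, "continuous")
        assert test.p_value == pytest.approx(1.0)
        # heavily tied groups fail Shapiro-Wilk -> Kruskal-Wallis, H = 0
        values_big = np.tile([1.0, 2.0, 3.0], 60)
        labels_big = np.repeat([0, 1, 2], 60)
        test_big = compare_baseline(values_big, labels_big, "continuous")
        assert test_big.test_name == "kruskal_wallis"
        assert test_big.p_value == pytest.approx(1.0)

    def test_fisher_2x2_enumeration(self):
        # [[5,0],[0,5]]: p = 2/C(10,5) = 2/252
        values = np.array(["x"] * 5 + ["y"] * 5, dtype=object)
        labels = np.array([0] * 5 + [1] * 5)
        test = compare_baseline(values, labels, "categorical")
        assert test.test_name == "fisher_exact"
        assert test.p_value == pytest.approx(2 / 252, rel=1e-9)

    def test_lognormal_routed_to_kw(self):
        rng = np.random.default_rng(9)
        values = np.exp(rng.normal(0, 1.5, 600))
        labels = rng.integers(0, 3, 600)
        test = compare_baseline(values, labels, "continuous")
        assert test.test_name == "kruskal_wallis"

    def test_normal_routed_to_anova(self):
        rng = np.random.default_rng(10)
        values = rng.normal(0, 1, 600)
        labels = rng.integers(0, 3, 600)
        test = compare_baseline(values, labels, "continuous")
        assert test.test_name == "anova"

    def test_constant_variable_flagged(self):
        test = compare_baseline(np.ones(30), np.repeat([0, 1, 2], 10), "continuous")
        assert test.p_value == 1.0 and test.flag == "constant_variable"

    def test_rc_monte_carlo_fisher(self):
        rng = np.random.default_rng(11)
        values = rng.choice(np.array(["a", "b", "c"], dtype=object), 300)
        labels = rng.integers(0, 3, 300)
        test = compare_baseline(values, labels, "categorical", seed=1)
        assert test.test_name == "fisher_exact_mc"
        assert 0.0 < test.p_value <= 1.0
        # seeded: reproducible
        again = compare_baseline(values, labels, "categorical", seed=1)
        assert test.p_value == again.p_value


class TestBHAdjust:
    def test_step_up_worked_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(adj, [0.05] * 5)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.031]), [0.031])

    def test_step_up_formula_oracle(self):
        rng = np.random.default_rng(12)
        p = rng.random(20)
        adj = bh_adjust(p)
        # adj_(i) = min_{j >= i} m * p_(j) / j, capped at 1
        m = len(p)
        order = np.argsort(p)
        raw = m * p[order] / np.arange(1, m + 1)
        adj_sorted = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
        expected = np.empty(m)
        expected[order] = adj_sorted
        np.testing.assert_allclose(adj, expected, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_never_below_raw_and_monotone(self, p):
        p = np.asarray(p)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestOutcomeReport:
    def test_full_report_structure(self):
        cohort = generate_cohort(default_aml_spec(600, seed=20))
        labels = cohort.true_labels
        report = outcome_report(cohort, labels, baseline_variables=["age", "wbc", "NPM1"])
        assert set(report.cluster_sizes) == set(np.unique(labels))
        for k, est in report.cr_odds.items():
            assert est.ci_low <= est.estimate <= est.ci_high
            assert report.cr_adjusted_p[k] >= est.p_value - 1e-12
        assert set(report.survival) == {"efs", "rfs", "os"}
        for b in report.baseline:
            assert b.adjusted_p >= b.p_value - 1e-12
            assert b.adjusted_p <= 1.0
        frame = report_to_frame(report)
        assert len(frame) == len(report.cluster_sizes)
        assert {"cr_or", "os_hr", "os_median"} <= set(frame.columns)
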