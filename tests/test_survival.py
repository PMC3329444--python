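import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from genograde.errors import SurvivalError
from genograde.survival import (ROCResult, auc, cox_fit, hanley_ci,
                                hanley_compare, horizon_labels, km_curve,
                                logrank, within_class_rank_correlation)


class TestHorizonLabels:
    @pytest.mark.parametrize(
        "time, event, expected",
        [(50, True, "positive"), (80, False, "excluded"), (150, False, "negative"),
         (150, True, "negative"),  # event after the horizon: event-free at 10y
         (120, True, "positive"), (120, False, "negative")],
    )
    def test_labeling_rules(self, time, event, expected):
        lab = horizon_labels(pd.Series([time]), pd.Series([event]), horizon=120)
        assert lab.iloc[0] == expected

    def test_bad_horizon_rejected(self):
        with pytest.raises(SurvivalError):
            horizon_labels(pd.Series([1.0]), pd.Series([True]), horizon=0)


def _pair_auc(pos, neg):
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        r = auc(pd.Series([1, 2, 8, 9]), pd.Series([False, False, True, True]))
        assert r.auc == 1.0

    def test_constant_marker_is_chance(self):
        r = auc(pd.Series([5, 5, 5, 5]), pd.Series([True, False, True, False]))
        assert r.auc == 0.5

    def test_small_enumerated_example(self):
        # pos {3, 5} vs neg {1, 4}: wins 3 of 4 pairs
        r = auc(pd.Series([3, 5, 1, 4]), pd.Series([True, True, False, False]))
        assert r.auc == pytest.approx(0.75)

    def test_matches_pair_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 200))
            v = rng.choice(np.round(rng.normal(0, 1, 8), 2), size=n)  # force ties
            lab = rng.random(n) < 0.4
            if lab.all() or not lab.any():
                continue
            r = auc(pd.Series(v), pd.Series(lab))
            assert r.auc == pytest.approx(_pair_auc(v[lab], v[~lab]), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(SurvivalError):
            auc(pd.Series([1, 2]), pd.Series([True, True]))

    def test_excluded_labels_dropped(self):
        r = auc(pd.Series([3, 5, 1, 4, 99]),
                pd.Series(["positive", "positive", "negative", "negative",
                           "excluded"]))
        assert r.auc == pytest.approx(0.75) and (r.n_pos, r.n_neg) == (2, 2)


class TestHanleyCI:
    def test_chance_auc_hand_value(self):
        # A=0.5: Q1 = A/(2-A) = 1/3 and Q2 = 2A^2/(1+A) = 1/3, so with
        # n_pos = n_neg = 10: SE^2 = (1/4 + 9/12 + 9/12)/100 = 0.0175
        (lo, hi), se = hanley_ci(0.5, 10, 10)
        assert se == pytest.approx(math.sqrt(0.0175), abs=1e-12)
        assert (lo, hi) == (pytest.approx(0.5 - 1.96 * se),
                            pytest.approx(0.5 + 1.96 * se))

    def test_se_shrinks_with_sample_size(self):
        ses = [hanley_ci(0.77, n, n)[1] for n in (5, 20, 80, 320)]
        assert ses == sorted(ses, reverse=True)

    def test_formula_arithmetic_at_published_auc(self):
        a = 0.77
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        n_pos, n_neg = 14, 72
        se2 = (a * (1 - a) + (n_pos - 1) * (q1 - a * a)
               + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
        (lo, hi), se = hanley_ci(a, n_pos, n_neg)
        assert se == pytest.approx(math.sqrt(se2), abs=1e-12)
        assert hi - lo < 0.35  # informative interval at this size

    def test_degenerate_auc_warns(self):
        with pytest.warns(UserWarning):
            (lo, hi), se = hanley_ci(1.0, 5, 5)
        assert hi == 1.0

    def test_interval_clipped_to_unit_range(self):
        (lo, hi), _ = hanley_ci(0.95, 3, 3)
        assert 0.0 <= lo and hi <= 1.0


class TestHanleyCompare:
    def _roc(self, a, n_pos=20, n_neg=30):
        (lo, hi), se = hanley_ci(a, n_pos, n_neg)
        return ROCResult(a, (lo, hi), n_pos, n_neg, se)

    def test_equal_aucs_give_null_z(self):
        z, p = hanley_compare(self._roc(0.7), self._roc(0.7), r=0.5)
        assert z == 0.0 and p == 1.0

    def test_zero_correlation_reduces_to_independent_test(self):
        ra, rb = self._roc(0.8), self._roc(0.65)
        z, _ = hanley_compare(ra, rb, r=0.0)
        assert z == pytest.approx((0.8 - 0.65) / math.hypot(ra.se, rb.se))

    def test_hand_computed_correlated_z(self):
        ra, rb = self._roc(0.8), self._roc(0.65)
        z, p = hanley_compare(ra, rb, r=0.5)
        denom = math.sqrt(ra.se**2 + rb.se**2 - 2 * 0.5 * ra.se * rb.se)
        assert z == pytest.approx((0.8 - 0.65) / denom)
        assert 0 < p < 1

    def test_mismatched_sample_sets_rejected(self):
        with pytest.raises(SurvivalError):
            hanley_compare(self._roc(0.7), self._roc(0.7, n_pos=9), r=0.0)

    def test_within_class_correlation_of_identical_markers(self, rng):
        v = pd.Series(rng.normal(size=40))
        lab = pd.Series(rng.random(40) < 0.5)
        assert within_class_rank_correlation(v, v, lab) == pytest.approx(1.0)


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        c = km_curve([5, 10, 15], [False, False, False])
        assert c.survival_at(20) == 1.0

    def test_single_event_among_four(self):
        c = km_curve([10, 12, 14, 16], [True, False, False, False])
        assert c.survival_at(10) == pytest.approx(0.75)
        assert c.survival_at(9.9) == 1.0

    def test_hand_tally_with_censoring(self):
        # times {2,4,6,8}, events {1,0,1,0}: S(6) = (3/4)(1/2) = 0.375
        c = km_curve([2, 4, 6, 8], [True, False, True, False])
        assert c.survival_at(2) == pytest.approx(0.75)
        assert c.survival_at(6) == pytest.approx(0.375)
        assert c.survival_at(100) == pytest.approx(0.375)

    def test_curve_is_nonincreasing_from_one(self, rng):
        t = rng.exponential(50, 100)
        e = rng.random(100) < 0.6
        c = km_curve(t, e)
        assert c.survival_at(0) == 1.0
        assert np.all(np.diff(c.survival) <= 1e-12)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(SurvivalError):
            km_curve([0.0, 5.0], [True, False])


def _logrank_oracle(groups, times, events):
    # O - E tally over pooled event times, two groups
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    gvals = np.unique(groups)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & (groups == gvals[0])).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (groups == gvals[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_are_null(self):
        t = [3, 6, 9, 12]
        e = [True, False, True, False]
        chi2, df, p = logrank(["a"] * 4 + ["b"] * 4, t + t, e + e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_matches_hand_tally_oracle(self, rng):
        for _ in range(10):
            n = 30
            g = rng.choice(["a", "b"], n)
            t = np.round(rng.exponential(20, n), 1) + 0.1
            e = rng.random(n) < 0.7
            if len(np.unique(g)) < 2 or e.sum() == 0:
                continue
            chi2, df, _ = logrank(g, t, e)
            assert chi2 == pytest.approx(_logrank_oracle(g, t, e), rel=1e-6)

    def test_invariant_to_time_scaling(self, rng):
        g = ["a", "a", "a", "b", "b", "b"]
        t = np.array([2.0, 5.0, 7.0, 3.0, 11.0, 13.0])
        e = [True, True, False, True, False, True]
        chi2_1, _, _ = logrank(g, t, e)
        chi2_2, _, _ = logrank(g, 7.3 * t, e)
        assert chi2_1 == pytest.approx(chi2_2, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(SurvivalError):
            logrank(["a", "a"], [1, 2], [True, False])


def _partial_loglik(beta, times, events, x):
    # Breslow/Efron coincide without ties; no ties in the toys below
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = times >= times[i]
            ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def _toy(self):
        times = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0])
        events = np.array([True, True, False, True, True, False])
        x = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        return pd.DataFrame({"time": times, "event": events, "x": x})

    def test_coefficient_matches_numeric_maximizer(self):
        df = self._toy()
        fit = cox_fit(df, covariates=["x"])
        res = minimize_scalar(
            lambda b: -_partial_loglik(b, df["time"].to_numpy(),
                                       df["event"].to_numpy(),
                                       df["x"].to_numpy()),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.coefficients["x"] == pytest.approx(res.x, abs=1e-6)
        assert fit.log_partial_likelihood == pytest.approx(-res.fun, abs=1e-8)

    def test_hr_is_exp_of_coefficient(self):
        fit = cox_fit(self._toy(), covariates=["x"])
        assert fit.hr["x"] == pytest.approx(math.exp(fit.coefficients["x"]))
        lo, hi = fit.hr_ci95.loc["x", "lo"], fit.hr_ci95.loc["x", "hi"]
        assert lo < fit.hr["x"] < hi

    def test_constant_covariate_rejected(self):
        df = self._toy().assign(flat=1.0)
        with pytest.raises(SurvivalError, match="flat"):
            cox_fit(df, covariates=["flat"])

    def test_shift_invariance_of_coefficient(self):
        df = self._toy()
        fit1 = cox_fit(df, covariates=["x"])
        fit2 = cox_fit(df.assign(x=df["x"] + 57.0), covariates=["x"])
        assert fit1.coefficients["x"] == pytest.approx(fit2.coefficients["x"],
                                                       abs=1e-6)

    def test_logrank_equals_cox_score_test_without_ties(self, rng):
        # score statistic U(0)^2 / I(0) for a binary covariate equals the
        # log-rank chi-square when event times are distinct
        n = 40
        t = rng.permutation(np.arange(1, n + 1)).astype(float)
        e = rng.random(n) < 0.6
        x = (rng.random(n) < 0.5).astype(float)
        if e.sum() == 0 or len(np.unique(x)) < 2:
            pytest.skip("degenerate draw")
        u, info = 0.0, 0.0
        for i in np.nonzero(e)[0]:
            risk = t >= t[i]
            xbar = x[risk].mean()
            u += x[i] - xbar
            info += np.mean((x[risk] - xbar) ** 2)
        chi2, _, _ = logrank(x.astype(int), t, e)
        assert chi2 == pytest.approx(u**2 / info, rel=1e-6)

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [True, False],
                           "x": [0.0, 1.0]})
        with pytest.raises(SurvivalError, match="events"):
            cox_fit(df, covariates=["x"])
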