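import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import comb

from metasig.errors import DegenerateInputError, ParameterError, UndefinedTestError
from metasig.survstats import (
    bh_adjust,
    coxph_fit,
    fisher_exact,
    km_fit,
    kruskal_wallis,
    logistic_fit,
    logrank_test,
    schoenfeld_check,
    wilcoxon_rank_sum,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def efron_partial_loglik(beta, time, event, x):
    """Literal Efron partial log-likelihood for one covariate (oracle)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for u in np.unique(time[event == 1]):
        deaths = (time == u) & (event == 1)
        risk = time >= u
        d = int(deaths.sum())
        s_risk = np.exp(beta * x[risk]).sum()
        s_death = np.exp(beta * x[deaths]).sum()
        ll += beta * x[deaths].sum()
        for ell in range(d):
            ll -= math.log(s_risk - (ell / d) * s_death)
    return ll


def brute_force_cox_beta(time, event, x):
    res = minimize_scalar(
        lambda b: -efron_partial_loglik(b, time, event, x), bounds=(-8, 8), method="bounded",
        options={"xatol": 1e-10},
    )
    return res.x


def logrank_oracle(time, event, group):
    """O-E / V tabulation over the pooled event times (oracle)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    o_minus_e = 0.0
    v = 0.0
    for u in np.unique(time[event == 1]):
        risk = time >= u
        n = risk.sum()
        n1 = (risk & (group == 1)).sum()
        d = ((time == u) & (event == 1)).sum()
        d1 = ((time == u) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / v


def wilcoxon_enumeration_p(x, y):
    """Two-sided exact p by full enumeration of group assignments (oracle)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    n2 = len(y)
    center = n1 * n2 / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(combo)]
        ys = np.delete(pooled, list(combo))
        u = sum(1 for xi in xs for yj in ys if xi > yj) + 0.5 * sum(
            1 for xi in xs for yj in ys if xi == yj
        )
        total += 1
        if abs(u - center) >= abs(obs - center) - 1e-12:
            count += 1
    return count / total


def fisher_two_sided_oracle(a, b, c, d):
    """Sum hypergeometric probabilities of tables at most as likely (oracle)."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = stats.hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return total


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


class TestKM:
    def test_hand_product_limit(self):
        fit = km_fit([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert np.allclose(fit.survival, [0.8, 0.6, 0.4, 0.2, 0.0])
        assert fit.median == 3

    def test_single_event(self):
        fit = km_fit([2], [1])
        assert fit.survival_at(2) == 0.0
        assert fit.median == 2

    def test_all_censored_median_not_reached(self):
        fit = km_fit([5, 7, 9], [0, 0, 0])
        assert fit.median is None

    def test_no_censoring_equals_empirical(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 50)
        fit = km_fit(t, np.ones(50, int))
        for u in fit.times:
            assert fit.survival_at(u) == pytest.approx((t > u).mean(), abs=1e-12)

    def test_median_ci_brackets_median(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(20, 200)
        c = rng.uniform(0, 60, 200)
        fit = km_fit(np.minimum(t, c), (t <= c).astype(int))
        lo, hi = fit.median_ci
        assert lo is not None and lo <= fit.median
        assert hi is None or hi >= fit.median


class TestLogrank:
    def test_identical_groups(self):
        t = [1, 3, 5, 7]
        e = [1, 0, 1, 1]
        res = logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_tabulation_oracle(self):
        rng = np.random.default_rng(4)
        ta = rng.exponential(10, 25).round(3)
        tb = rng.exponential(20, 30).round(3)
        ea = np.ones(25, int)
        eb = (rng.random(30) < 0.8).astype(int)
        res = logrank_test(ta, ea, tb, eb)
        oracle = logrank_oracle(
            np.concatenate([ta, tb]), np.concatenate([ea, eb]), np.concatenate([np.zeros(25), np.ones(30)])
        )
        assert res.statistic == pytest.approx(oracle, abs=1e-10)

    def test_empty_group(self):
        with pytest.raises(ParameterError):
            logrank_test([], [], [1], [1])

    def test_zero_events(self):
        with pytest.raises(UndefinedTestError):
            logrank_test([1, 2], [0, 0], [3], [0])


# ---------------------------------------------------------------------------
# Cox PH
# ---------------------------------------------------------------------------

N12_FIXTURE = pd.DataFrame(
    {
        "time": [3.1, 5.2, 7.0, 2.4, 8.8, 1.5, 9.9, 4.4, 6.1, 10.5, 0.7, 12.0],
        "event": [1, 1, 0, 1, 1, 1, 0, 1, 1, 0, 1, 1],
        "x": [1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0],
    }
)


class TestCox:
    def test_beta_matches_brute_force(self):
        fit = coxph_fit(N12_FIXTURE, "time", "event", ["x"])
        oracle = brute_force_cox_beta(N12_FIXTURE["time"], N12_FIXTURE["event"], N12_FIXTURE["x"])
        assert fit.summary.loc["x", "beta"] == pytest.approx(oracle, abs=1e-4)

    def test_beta_matches_brute_force_with_ties(self):
        df = pd.DataFrame(
            {
                "time": [2, 2, 2, 5, 5, 7, 7, 9, 4, 4, 11, 1],
                "event": [1, 1, 0, 1, 1, 1, 0, 1, 1, 1, 0, 1],
                "x": [1.0, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0],
            }
        )
        fit = coxph_fit(df, "time", "event", ["x"])
        oracle = brute_force_cox_beta(df["time"], df["event"], df["x"])
        assert fit.summary.loc["x", "beta"] == pytest.approx(oracle, abs=1e-4)

    def test_matches_lifelines(self, surv_frame):
        from lifelines import CoxPHFitter

        df = surv_frame(n=150, hr=1.8, seed=2)
        fit = coxph_fit(df, "time", "event", ["x"])
        cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        assert fit.summary.loc["x", "beta"] == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.summary.loc["x", "se"] == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_zero_variance_covariate_rejected(self):
        df = N12_FIXTURE.assign(z=1.0)
        with pytest.raises(ParameterError, match="zero-variance"):
            coxph_fit(df, "time", "event", ["z"])

    def test_score_test_equals_logrank_no_ties(self, surv_frame):
        df = surv_frame(n=120, hr=2.5, seed=7)
        assert df["time"].nunique() == len(df)
        fit = coxph_fit(df, "time", "event", ["x"])
        lr = logrank_test(
            df.loc[df.x == 0, "time"],
            df.loc[df.x == 0, "event"],
            df.loc[df.x == 1, "time"],
            df.loc[df.x == 1, "event"],
        )
        assert fit.score_chi2_at_zero == pytest.approx(lr.statistic, abs=1e-8)

    def test_missing_covariates_dropped_and_counted(self):
        df = N12_FIXTURE.copy()
        df.loc[0, "x"] = np.nan
        fit = coxph_fit(df, "time", "event", ["x"])
        assert fit.n_used == 11 and fit.n_dropped_missing == 1

    def test_categorical_dummy_coding(self):
        df = N12_FIXTURE.assign(grp=["a", "b", "c"] * 4)
        fit = coxph_fit(df, "time", "event", ["x", "grp"])
        assert "grp[b]" in fit.summary.index and "grp[c]" in fit.summary.index
        assert "grp[a]" not in fit.summary.index  # reference level

    def test_hr_ci_invariants(self, surv_frame):
        fit = coxph_fit(surv_frame(n=100, hr=2.0, seed=1), "time", "event", ["x"])
        row = fit.summary.loc["x"]
        assert row["hr"] > 0
        assert row["ci_low"] < row["hr"] < row["ci_high"]

    def test_null_coverage_simulation(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 500
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(10, n)
            c = rng.uniform(0, 30, n)
            df = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int), "x": x})
            fit = coxph_fit(df, "time", "event", ["x"])
            row = fit.summary.loc["x"]
            if abs(row["beta"]) < 2 * row["se"]:
                hits += 1
        assert hits >= 93


class TestSchoenfeld:
    def test_null_uniformity(self):
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(10_000 + seed)
            n = 60
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(1.0 / (0.08 * np.exp(0.5 * x)))
            c = rng.uniform(0, 25, n)
            df = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int), "x": x})
            fit = coxph_fit(df, "time", "event", ["x"])
            _, p_global = schoenfeld_check(fit)
            pvals.append(p_global)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_time_varying_effect_detected(self):
        detections = 0
        for seed in range(100):
            rng = np.random.default_rng(20_000 + seed)
            n = 150
            x = rng.integers(0, 2, n).astype(float)
            # effect flips sign at tau: rate r*e^{b} before, r*e^{-b} after (x=1)
            r, b, tau = 0.10, 1.5, 6.0
            u = -np.log(rng.random(n))
            r1 = r * np.exp(b * x)
            r2 = r * np.exp(-b * x)
            t = np.where(u <= r1 * tau, u / r1, tau + (u - r1 * tau) / r2)
            df = pd.DataFrame({"time": t, "event": np.ones(n, int), "x": x})
            fit = coxph_fit(df, "time", "event", ["x"])
            _, p_global = schoenfeld_check(fit)
            if p_global < 0.05:
                detections += 1
        assert detections >= 80

    def test_too_few_events(self):
        df = pd.DataFrame(
            {"time": [1.0, 2, 3, 4, 9, 11], "event": [1, 0, 0, 0, 1, 0], "x": [1.0, 0, 1, 0, 1, 0]}
        )
        fit = coxph_fit(df, "time", "event", ["x"])
        with pytest.raises(UndefinedTestError):
            schoenfeld_check(fit)


class TestLogistic:
    def test_direction_matches_fisher(self):
        # expand [[8, 2], [3, 7]]: outcome ~ exposure
        y = [1] * 8 + [0] * 2 + [1] * 3 + [0] * 7
        x = [1.0] * 10 + [0.0] * 10
        df = pd.DataFrame({"y": y, "x": x})
        table = logistic_fit(df, "y", ["x"])
        fis = fisher_exact([[8, 2], [3, 7]])
        assert (table.loc["x", "or"] > 1) == (fis.effect > 1)

    def test_symmetric_data_beta_zero(self):
        df = pd.DataFrame({"y": [0, 1, 0, 1], "x": [0.0, 0.0, 1.0, 1.0]})
        table = logistic_fit(df, "y", ["x"])
        assert abs(table.loc["x", "beta"]) < 1e-6

    def test_constant_outcome_error(self):
        df = pd.DataFrame({"y": [1, 1, 1, 1], "x": [0.0, 1.0, 0.0, 1.0]})
        with pytest.raises(DegenerateInputError):
            logistic_fit(df, "y", ["x"])


class TestRankTests:
    def test_same_values_center(self):
        res = wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p > 0.9
        assert res.effect == pytest.approx(0.0, abs=1e-12)

    def test_exact_enumeration_123_456(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(0.1, abs=1e-12)
        assert res.p == pytest.approx(wilcoxon_enumeration_p(np.array([1, 2, 3]), np.array([4, 5, 6])))

    def test_exact_matches_enumeration_random(self):
        rng = np.random.default_rng(3)
        x = rng.permutation(20)[:5].astype(float)
        y = rng.permutation(40)[:6].astype(float) + 100 * rng.random(6).round(3)
        if np.unique(np.concatenate([x, y])).size == 11:
            res = wilcoxon_rank_sum(x, y)
            assert res.p == pytest.approx(wilcoxon_enumeration_p(x, y), abs=1e-9)

    def test_kruskal_identical_groups(self):
        res = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == 1.0

    def test_kruskal_three_groups(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.p < 0.05


class TestFisherBH:
    def test_diagonal_table(self):
        res = fisher_exact([[3, 0], [0, 3]])
        assert res.p == pytest.approx(0.1, abs=1e-12)
        assert res.p == pytest.approx(fisher_two_sided_oracle(3, 0, 0, 3), abs=1e-12)

    def test_identical_rows(self):
        res = fisher_exact([[5, 5], [5, 5]])
        assert res.p == 1.0
        assert res.effect == pytest.approx(1.0)

    def test_oracle_agreement_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 8, 4)
            res = fisher_exact([[a, b], [c, d]])
            assert res.p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-9)

    def test_bh_hand_computation(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_unordered_input(self):
        q = bh_adjust([0.04, 0.01, 0.03, 0.02])
        assert np.allclose(sorted(q), [0.04, 0.04, 0.04, 0.04])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_bh_properties(self, pvals):
        q = bh_adjust(pvals)
        assert (q <= 1.0).all() and (q >= np.asarray(pvals) - 1e-15).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
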