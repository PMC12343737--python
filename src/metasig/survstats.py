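"""Survival and association statistics.

The Cox proportional-hazards model (Efron tie handling, Newton-Raphson on
the partial likelihood), Kaplan-Meier estimator, log-rank test and Schoenfeld
proportional-hazards diagnostic are implemented here directly; rank tests and
Fisher's exact test delegate to scipy, logistic regression to statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    ParameterError,
    UndefinedTestError,
)

Z95 = stats.norm.ppf(0.975)


@dataclass
class TestResult:
    statistic: float
    p: float
    effect: Optional[float] = None
    method: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ParameterError(f"p-value {self.p} outside [0, 1]")


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMFit:
    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) just after each event time
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    median: Optional[float]  # None = not reached
    median_ci: tuple[Optional[float], Optional[float]]

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(times: Sequence[float], events: Sequence[int]) -> KMFit:
    """Product-limit estimator with Greenwood log(-log) confidence bands.

    The median is the smallest time with S(t) <= 0.5 (None if never reached);
    its 95% CI inverts the pointwise band (Brookmeyer-Crowley style): all
    times whose band contains 0.5.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ParameterError("need at least one sample")
    if (t < 0).any():
        raise ParameterError("times must be non-negative")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t[e == 1])
    S = 1.0
    var_sum = 0.0
    surv, lo, hi, n_risk, n_ev = [], [], [], [], []
    for u in uniq:
        n_at_risk = int((t >= u).sum())
        d = int(((t == u) & (e == 1)).sum())
        S *= 1.0 - d / n_at_risk
        if n_at_risk > d:
            var_sum += d / (n_at_risk * (n_at_risk - d))
        if 0.0 < S < 1.0:
            se_cll = math.sqrt(var_sum) / abs(math.log(S))
            lo.append(S ** math.exp(Z95 * se_cll))
            hi.append(S ** math.exp(-Z95 * se_cll))
        else:
            lo.append(S)
            hi.append(S)
        surv.append(S)
        n_risk.append(n_at_risk)
        n_ev.append(d)
    surv_a = np.array(surv)
    lo_a = np.array(lo)
    hi_a = np.array(hi)

    med_idx = np.flatnonzero(surv_a <= 0.5)
    median = float(uniq[med_idx[0]]) if med_idx.size else None
    # CI for the median: all event times whose S-band does not exclude 0.5
    in_band = np.flatnonzero((lo_a <= 0.5) & (hi_a >= 0.5))
    if median is None:
        ci = (float(uniq[in_band[0]]) if in_band.size else None, None)
    elif in_band.size:
        upper_open = in_band[-1] == len(uniq) - 1 and surv_a[-1] > 0.5
        ci = (float(uniq[in_band[0]]), None if upper_open else float(uniq[in_band[-1]]))
    else:
        ci = (median, median)
    return KMFit(
        times=uniq,
        survival=surv_a,
        ci_low=lo_a,
        ci_high=hi_a,
        n_risk=np.array(n_risk),
        n_events=np.array(n_ev),
        median=median,
        median_ci=ci,
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> TestResult:
    """Two-group log-rank chi-square test (1 df, two-sided)."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ParameterError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise UndefinedTestError("log-rank undefined with zero events")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size, int), np.ones(tb.size, int)])
    observed_minus_expected = 0.0
    variance = 0.0
    for u in np.unique(t[e == 1]):
        at_risk = t >= u
        n = int(at_risk.sum())
        n1 = int((at_risk & (g == 0)).sum())
        d = int(((t == u) & (e == 1)).sum())
        d1 = int(((t == u) & (e == 1) & (g == 0)).sum())
        observed_minus_expected += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        return TestResult(statistic=0.0, p=1.0, method="logrank")
    chi2 = observed_minus_expected**2 / variance
    return TestResult(statistic=float(chi2), p=float(stats.chi2.sf(chi2, 1)), method="logrank")


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    summary: pd.DataFrame  # index = covariate; beta, se, hr, ci_low, ci_high, p
    log_likelihood: float
    n_used: int
    n_dropped_missing: int
    n_events: int
    score_chi2_at_zero: float
    score_p_at_zero: float
    separation_flags: list[str]
    ph_check: Optional[pd.DataFrame] = None
    ph_global_p: Optional[float] = None
    # fit internals for diagnostics
    _X: np.ndarray = field(default=None, repr=False)
    _times: np.ndarray = field(default=None, repr=False)
    _events: np.ndarray = field(default=None, repr=False)
    _beta: np.ndarray = field(default=None, repr=False)
    _info: np.ndarray = field(default=None, repr=False)
    _names: list[str] = field(default_factory=list, repr=False)

    @property
    def hr(self) -> pd.Series:
        return self.summary["hr"]


def design_matrix(
    data: pd.DataFrame, covariates: Sequence[str], reference_levels: Optional[dict] = None
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Dummy-code categorical covariates against a documented reference level.

    The reference level defaults to the lexicographically smallest observed
    level; override per-column through ``reference_levels``.
    """
    reference_levels = reference_levels or {}
    cols = {}
    refs = {}
    for c in covariates:
        s = data[c]
        if s.dtype.kind in "biufc":
            cols[c] = s.astype(float)
        else:
            levels = sorted(x for x in s.dropna().unique())
            ref = reference_levels.get(c, levels[0] if levels else None)
            refs[c] = ref
            for lev in levels:
                if lev == ref:
                    continue
                col = (s == lev).astype(float)
                col[s.isna()] = np.nan
                cols[f"{c}[{lev}]"] = col
    return pd.DataFrame(cols, index=data.index), refs


def _efron_derivatives(X, times, events, beta):
    """Log partial likelihood, gradient and (negative Hessian) information.

    Subjects must be pre-sorted by descending time so risk sets accumulate.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    theta = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    s0r, s1r, s2r = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        t_cur = times[i]
        j = i
        while j < n and times[j] == t_cur:
            j += 1
        block = slice(i, j)
        xb = X[block]
        thb = theta[block]
        s0r += thb.sum()
        s1r += thb @ xb
        s2r += (xb * thb[:, None]).T @ xb
        ev = events[block].astype(bool)
        d = int(ev.sum())
        if d > 0:
            xd = xb[ev]
            thd = thb[ev]
            s0d = thd.sum()
            s1d = thd @ xd
            s2d = (xd * thd[:, None]).T @ xd
            ll += eta[block][ev].sum()
            for l in range(d):
                f = l / d
                phi = s0r - f * s0d
                u = s1r - f * s1d
                m = s2r - f * s2d
                ll -= math.log(phi)
                grad += -u / phi
                info += m / phi - np.outer(u, u) / phi**2
            grad += xd.sum(axis=0)
        i = j
    return ll, grad, info


def coxph_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    reference_levels: Optional[dict] = None,
    max_iter: int = 60,
    tol: float = 1e-10,
    ph_check: bool = False,
) -> CoxResult:
    """Fit a Cox proportional-hazards model with Efron tie handling.

    Rows with missing duration, event or covariate values are dropped
    (complete-case) and counted in ``n_dropped_missing``. Wald 95% CIs and
    p-values are reported on the hazard-ratio scale; monotone-likelihood
    (separation) covariates are flagged and get unbounded CIs.
    """
    Xdf, _refs = design_matrix(data, covariates, reference_levels)
    work = pd.concat([data[[duration_col, event_col]], Xdf], axis=1)
    n_total = len(work)
    work = work.dropna()
    n_used = len(work)
    if n_used == 0:
        raise DegenerateInputError("no complete-case rows to fit on")
    names = list(Xdf.columns)
    X = work[names].to_numpy(dtype=float)
    t = work[duration_col].to_numpy(dtype=float)
    e = work[event_col].to_numpy(dtype=int)
    n_events = int(e.sum())
    if n_events == 0:
        raise UndefinedTestError("Cox model undefined with zero events")
    if X.shape[1] == 0:
        raise ParameterError("no covariates after coding")
    var = X.var(axis=0)
    if (var == 0).any():
        zero = [names[i] for i in np.flatnonzero(var == 0)]
        raise ParameterError(f"zero-variance covariate(s): {zero}")
    if n_used < X.shape[1] + 1:
        raise DegenerateInputError("fewer complete-case rows than covariates + 1")

    # center for numerical stability; beta is unaffected
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    order = np.argsort(-t, kind="stable")
    Xs, ts, es = Xc[order], t[order], e[order]

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _efron_derivatives(Xs, ts, es, beta)
    score_chi2 = float(grad @ np.linalg.solve(info, grad))
    score_p = float(stats.chi2.sf(score_chi2, p))

    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix", last_estimate=beta) from exc
        # step-halving on likelihood decrease
        factor = 1.0
        for _ in range(30):
            new_beta = beta + factor * step
            new_ll, new_grad, new_info = _efron_derivatives(Xs, ts, es, new_beta)
            if new_ll >= ll - 1e-12:
                break
            factor /= 2
        delta = abs(new_ll - ll)
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if delta < tol and np.max(np.abs(grad)) < 1e-6:
            converged = True
            break
    if not converged and np.max(np.abs(grad)) > 1e-3 and np.max(np.abs(beta)) < 15:
        raise ConvergenceError(f"Newton-Raphson did not converge in {max_iter} iterations", last_estimate=beta)

    cov = np.linalg.inv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    separation = [names[i] for i in range(p) if abs(beta[i]) > 15]
    with np.errstate(over="ignore"):  # separation yields legitimately infinite CI bounds
        ci_low = np.exp(beta - Z95 * se)
        ci_high = np.exp(beta + Z95 * se)
    pvals = 2 * stats.norm.sf(np.abs(beta) / np.where(se > 0, se, np.inf))
    for nm in separation:
        i = names.index(nm)
        ci_low[i], ci_high[i] = 0.0, np.inf
    summary = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": ci_low,
            "ci_high": ci_high,
            "p": pvals,
        },
        index=pd.Index(names, name="covariate"),
    )
    result = CoxResult(
        summary=summary,
        log_likelihood=float(ll),
        n_used=n_used,
        n_dropped_missing=n_total - n_used,
        n_events=n_events,
        score_chi2_at_zero=score_chi2,
        score_p_at_zero=score_p,
        separation_flags=separation,
        _X=Xs,
        _times=ts,
        _events=es,
        _beta=beta,
        _info=info,
        _names=names,
    )
    if ph_check:
        ph = schoenfeld_check(result)
        result.ph_check = ph[0]
        result.ph_global_p = ph[1]
    return result


def schoenfeld_check(fit: CoxResult) -> tuple[pd.DataFrame, float]:
    """Proportional-hazards score test on scaled Schoenfeld residuals.

    Residuals (observed covariate minus risk-set expectation at each event
    time) are correlated with the rank of the event time; per-covariate and
    global chi-square tests follow the standard scaled-residual construction.
    """
    X, t, e, beta, info = fit._X, fit._times, fit._events, fit._beta, fit._info
    d_total = int(e.sum())
    if d_total < 3:
        raise UndefinedTestError("PH check undefined with fewer than 3 events")
    theta = np.exp(np.clip(X @ beta, -500, 500))
    # walk descending times, accumulate risk sums, emit one residual per event
    resid = []
    ev_times = []
    n = len(t)
    s0, s1 = 0.0, np.zeros(X.shape[1])
    i = 0
    while i < n:
        t_cur = t[i]
        j = i
        while j < n and t[j] == t_cur:
            j += 1
        s0 += theta[i:j].sum()
        s1 += theta[i:j] @ X[i:j]
        xbar = s1 / s0
        for idx in range(i, j):
            if e[idx]:
                resid.append(X[idx] - xbar)
                ev_times.append(t_cur)
        i = j
    R = np.asarray(resid)  # d x p
    ev_times = np.asarray(ev_times)
    g = stats.rankdata(ev_times)
    g = g - g.mean()
    gg = float((g**2).sum())
    vinv = np.linalg.inv(info)
    u = d_total * (g @ R) @ vinv  # 1 x p row of weighted scaled residuals
    names = fit._names
    per_p = []
    per_chi = []
    for jdx in range(len(names)):
        chi = u[jdx] ** 2 / (d_total * vinv[jdx, jdx] * gg)
        per_chi.append(chi)
        per_p.append(float(stats.chi2.sf(chi, 1)))
    chi_global = float(u @ info @ u / (d_total * gg))
    p_global = float(stats.chi2.sf(chi_global, len(names)))
    table = pd.DataFrame({"chi2": per_chi, "p": per_p}, index=pd.Index(names, name="covariate"))
    return table, p_global


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------


def logistic_fit(
    data: pd.DataFrame,
    outcome_col: str,
    covariates: Sequence[str],
    reference_levels: Optional[dict] = None,
) -> pd.DataFrame:
    """Maximum-likelihood logistic regression; per-covariate OR with Wald CI.

    Returns a DataFrame (index covariate incl. intercept) with beta, se, or,
    ci_low, ci_high, p and a boolean ``separation`` column.
    """
    import statsmodels.api as sm

    Xdf, _ = design_matrix(data, covariates, reference_levels)
    work = pd.concat([data[[outcome_col]], Xdf], axis=1).dropna()
    y = work[outcome_col].astype(float)
    if y.nunique() < 2:
        raise DegenerateInputError("outcome is constant; logistic model undefined")
    X = sm.add_constant(work[list(Xdf.columns)].astype(float), has_constant="add")
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as exc:  # PerfectSeparationError and kin
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    beta = res.params
    se = res.bse
    out = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "or": np.exp(beta),
            "ci_low": np.exp(beta - Z95 * se),
            "ci_high": np.exp(beta + Z95 * se),
            "p": res.pvalues,
            "separation": (~converged) | (se > 50),
        }
    )
    out.index.name = "covariate"
    return out


# ---------------------------------------------------------------------------
# Rank tests, Fisher, BH
# ---------------------------------------------------------------------------

EXACT_N_MAX = 20  # combined size below which the rank-sum test enumerates exactly


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) with rank-biserial effect.

    Uses exact enumeration when combined n <= 20 and there are no ties,
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= EXACT_N_MAX and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    rank_biserial = 2.0 * u / (x.size * y.size) - 1.0
    return TestResult(statistic=u, p=float(min(res.pvalue, 1.0)), effect=rank_biserial, method=f"wilcoxon-{method}")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups (tie-corrected)."""
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ParameterError("all groups must be non-empty")
    flat = np.concatenate(arrays)
    if np.unique(flat).size == 1:
        return TestResult(statistic=0.0, p=1.0, method="kruskal")
    res = stats.kruskal(*arrays)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), method="kruskal")


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table; sample odds ratio as effect."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ParameterError("table must be a non-negative 2x2 matrix")
    odds, p = stats.fisher_exact(tab, alternative="two-sided")
    return TestResult(statistic=float(odds), p=float(p), effect=float(odds), method="fisher")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1, q >= p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
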