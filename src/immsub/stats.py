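"""Statistical battery used throughout the characterization analyses.

Rank and t tests, exact contingency tests (2x2 closed form, 2xk by
enumeration with a seeded Monte-Carlo fallback, rxc by Monte Carlo),
Spearman correlation with an exact small-n permutation p, one-way ANOVA,
Benjamini-Hochberg FDR, Kaplan-Meier / log-rank survival comparison, and
logistic regression with standardized coefficients.

Conventions: every function is invariant to the ordering of observations;
"greater" always means the FIRST argument tends larger. The choice between
rank and t tests is left to the caller — a Shapiro-Wilk helper is provided
but never invoked implicitly.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    alternative: str
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: time on study and whether the event occurred."""

    sample_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"survival time must be positive (sample {self.sample_id!r})")


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit curve evaluated at the event times."""

    event_times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]

    def __post_init__(self) -> None:
        surv = np.asarray(self.survival)
        if surv.size and (np.diff(surv) > 1e-12).any():
            raise ValueError("survival must be non-increasing")
        if surv.size and surv[0] > 1 + 1e-12:
            raise ValueError("survival cannot exceed 1")


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic regression with standardized coefficients.

    ``standardized_betas[j] = coefficients[j] * SD(predictor j)`` — the
    change in log-odds per predictor standard deviation, comparable across
    predictors on different scales.
    """

    predictor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    standardized_betas: tuple[float, ...]
    p_values: tuple[float, ...]
    intercept: float
    converged: bool
    method: str = "logistic-IRLS"


def _clean_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _check_alternative(alternative: str) -> str:
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}, got {alternative!r}")
    return alternative


# --------------------------------------------------------------------------
# two-sample location tests


def mann_whitney(x, y, alternative: str = "two_sided") -> TestResult:
    """Mann-Whitney U test of x versus y.

    Exact p-value when the combined sample size is <= 12 and there are no
    ties across the pooled data; otherwise the normal approximation with
    continuity and tie correction. ``alternative="greater"`` tests whether
    x tends larger than y.
    """
    alternative = _check_alternative(alternative)
    x = _clean_vector(x, "x")
    y = _clean_vector(y, "y")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        # total tie: no evidence either way under any convention
        return TestResult(statistic=len(x) * len(y) / 2.0, p_value=1.0,
                          alternative=alternative, method="mann-whitney-degenerate")
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and (len(x) + len(y) <= 12)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative.replace("_", "-"),
                           method=method, use_continuity=True)
    return TestResult(statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
                      alternative=alternative, method=f"mann-whitney-{method}")


def t_test(x, y, alternative: str = "two_sided", welch: bool = True) -> TestResult:
    """Two-sample t test (Welch by default; pooled-variance Student optional)."""
    alternative = _check_alternative(alternative)
    x = _clean_vector(x, "x")
    y = _clean_vector(y, "y")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t test requires n >= 2 per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero variance in both groups; t statistic undefined")
    res = sps.ttest_ind(x, y, equal_var=not welch,
                        alternative=alternative.replace("_", "-"))
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      alternative=alternative,
                      method="welch-t" if welch else "student-t")


# --------------------------------------------------------------------------
# exact contingency tests


def _log_factorials(n: int) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])


def _table_log_prob(table: np.ndarray, lf: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of a table with fixed margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    return float(lf[rows].sum() + lf[cols].sum() - lf[n] - lf[table.ravel()].sum())


def _enumerate_2xk(col_totals: np.ndarray, row1_total: int):
    """Yield all first-row fill-ins of a 2xk table with the given margins."""
    k = len(col_totals)

    def rec(j: int, remaining: int, prefix: tuple[int, ...]):
        if j == k - 1:
            if remaining <= col_totals[j]:
                yield prefix + (remaining,)
            return
        tail_cap = int(col_totals[j + 1:].sum())
        lo = max(0, remaining - tail_cap)
        hi = min(col_totals[j], remaining)
        for a in range(lo, hi + 1):
            yield from rec(j + 1, remaining - a, prefix + (a,))

    yield from rec(0, row1_total, ())


def _enumeration_size_bound(col_totals: np.ndarray, row1_total: int) -> float:
    return float(np.prod([min(c, row1_total) + 1.0 for c in col_totals]))


def fisher_exact(table, seed: int = 0, mc_samples: int = 20000,
                 enumeration_budget: float = 2e5) -> TestResult:
    """Fisher's exact test of independence for a 2x2, 2xk or rxc count table.

    2x2 tables use the closed-form hypergeometric two-sided p. 2xk tables
    are enumerated exactly when the number of candidate tables is within
    ``enumeration_budget``, otherwise a seeded Monte-Carlo estimate over
    multivariate-hypergeometric draws is used. Tables with more than two
    rows always use the Monte-Carlo route (label permutation). The method
    string records which path produced the p-value.
    """
    tab = np.asarray(table, dtype=int)
    if tab.ndim != 2 or min(tab.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if (tab < 0).any():
        raise ValueError("table entries must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("every row and column margin must be positive")
    if tab.shape[0] != 2 and tab.shape[1] == 2:
        tab = tab.T  # independence p is orientation-invariant; use the exact 2xk path

    if tab.shape == (2, 2):
        _, p = sps.fisher_exact(tab, alternative="two-sided")
        return TestResult(statistic=float(tab[0, 0]), p_value=float(min(p, 1.0)),
                          alternative="two_sided", method="fisher-exact-2x2")

    n = int(tab.sum())
    lf = _log_factorials(n)
    logp_obs = _table_log_prob(tab, lf)
    tol = 1e-9

    if tab.shape[0] == 2:
        col_totals = tab.sum(axis=0)
        row1 = int(tab.sum(axis=1)[0])
        if _enumeration_size_bound(col_totals, row1) <= enumeration_budget:
            fills = np.array(list(_enumerate_2xk(col_totals, row1)), dtype=int)
            # vectorized log-probability of every candidate table
            lp = (lf[fills].sum(axis=1) + lf[col_totals - fills].sum(axis=1))
            lp = lf[row1] + lf[n - row1] - lf[n] + lf[col_totals].sum() - lp
            total = float(np.exp(lp[lp <= logp_obs + tol]).sum())
            return TestResult(statistic=float(np.exp(logp_obs)),
                              p_value=float(min(total, 1.0)),
                              alternative="two_sided", method="fisher-exact-enumeration")
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_hypergeometric(col_totals, row1, size=mc_samples)
        lp = (lf[draws].sum(axis=1) + lf[col_totals - draws].sum(axis=1))
        lp = lf[row1] + lf[n - row1] - lf[n] + lf[col_totals].sum() - lp
        hits = int((lp <= logp_obs + tol).sum())
        p = (hits + 1) / (mc_samples + 1)
        return TestResult(statistic=float(np.exp(logp_obs)), p_value=float(min(p, 1.0)),
                          alternative="two_sided",
                          method=f"fisher-monte-carlo (B={mc_samples})")

    # r x c: permute one margin's labels against the other
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(tab.shape[0]), tab.sum(axis=1))
    col_labels = np.repeat(np.arange(tab.shape[1]), tab.sum(axis=0))
    hits = 0
    for _ in range(mc_samples):
        perm = rng.permutation(col_labels)
        cand = np.zeros_like(tab)
        np.add.at(cand, (row_labels, perm), 1)
        if _table_log_prob(cand, lf) <= logp_obs + tol:
            hits += 1
    p = (hits + 1) / (mc_samples + 1)
    return TestResult(statistic=float(np.exp(logp_obs)), p_value=float(min(p, 1.0)),
                      alternative="two_sided",
                      method=f"fisher-monte-carlo (B={mc_samples})")


# --------------------------------------------------------------------------
# correlation


def _pearson_of_ranks(xr: np.ndarray, yr: np.ndarray) -> float:
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = math.sqrt(float((xc ** 2).sum() * (yc ** 2).sum()))
    return float((xc * yc).sum() / denom)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a small-sample exact permutation p.

    rho is the Pearson correlation of average ranks. For n <= 10 the
    two-sided p-value is computed by full enumeration of rank pairings;
    for larger n the t approximation is used.
    """
    x = _clean_vector(x, "x")
    y = _clean_vector(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant vector: correlation undefined")
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    rho = _pearson_of_ranks(xr, yr)
    if n <= 10:
        xc = xr - xr.mean()
        yc = yr - yr.mean()
        denom = math.sqrt(float((xc ** 2).sum() * (yc ** 2).sum()))
        target = abs(rho) - 1e-12
        hits = 0
        total = 0
        chunk: list[tuple] = []

        def flush(chunk_list: list[tuple]) -> int:
            perms = np.asarray(chunk_list, dtype=float)
            rhos = perms @ xc / denom
            return int((np.abs(rhos) >= target).sum())

        for perm in itertools.permutations(yc):
            chunk.append(perm)
            total += 1
            if len(chunk) == 100_000:
                hits += flush(chunk)
                chunk = []
        if chunk:
            hits += flush(chunk)
        return rho, hits / total
    # t approximation
    t_stat = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho ** 2))
    p = 2 * sps.t.sf(abs(t_stat), df=n - 2)
    return rho, float(min(p, 1.0))


# --------------------------------------------------------------------------
# ANOVA, FDR


def anova_oneway(groups) -> TestResult:
    """One-way ANOVA F test across two or more groups."""
    arrays = [_clean_vector(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(arrays)
    if np.var(pooled) == 0:
        raise ValueError("all values identical; no variance to partition")
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0:
        # perfect separation: F diverges
        return TestResult(statistic=float("inf"), p_value=0.0,
                          alternative="two_sided",
                          method="anova-oneway (zero within-group variance)")
    res = sps.f_oneway(*arrays)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      alternative="two_sided", method="anova-oneway")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test (a helper; never invoked implicitly)."""
    x = _clean_vector(x, "x")
    if len(x) < 3:
        raise ValueError("shapiro-wilk requires n >= 3")
    res = sps.shapiro(x)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      alternative="two_sided", method="shapiro-wilk")


# --------------------------------------------------------------------------
# survival


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records[["time", "event"]].copy()
        df["time"] = df["time"].astype(float)
        df["event"] = df["event"].astype(bool)
    else:
        rows = list(records)
        if not rows:
            raise ValueError("need at least one survival record")
        df = pd.DataFrame({"time": [r.time for r in rows],
                           "event": [bool(r.event) for r in rows]})
    if df.empty:
        raise ValueError("need at least one survival record")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    return df


def km_estimate(records) -> KMCurve:
    """Kaplan-Meier product-limit survival estimate.

    Accepts an iterable of :class:`SurvivalRecord` or a DataFrame with
    ``time`` and ``event`` columns. The curve is reported at the distinct
    event times; censored times reduce the risk set without a step.
    """
    df = _records_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    event_table = kmf.event_table
    at_event = event_table[event_table["observed"] > 0]
    times = tuple(float(t) for t in at_event.index)
    surv = tuple(float(kmf.survival_function_at_times(t).iloc[0]) for t in times)
    risk = tuple(int(n) for n in at_event["at_risk"])
    return KMCurve(event_times=times, survival=surv, at_risk=risk)


def logrank_test(group_records) -> TestResult:
    """Log-rank test across two or more survival groups (df = groups - 1)."""
    frames = []
    for gi, rec in enumerate(group_records):
        df = _records_frame(rec)
        df["group"] = gi
        frames.append(df)
    if len(frames) < 2:
        raise ValueError("need at least two groups")
    combined = pd.concat(frames, ignore_index=True)
    if not combined["event"].any():
        raise ValueError("no events observed; log-rank test undefined")
    res = multivariate_logrank_test(combined["time"], combined["group"],
                                    combined["event"])
    return TestResult(statistic=float(res.test_statistic),
                      p_value=float(res.p_value),
                      alternative="two_sided",
                      method=f"logrank (df={len(frames) - 1})")


# --------------------------------------------------------------------------
# logistic regression


def logistic_standardized(outcome, predictors: pd.DataFrame,
                          maxiter: int = 200) -> LogisticFit:
    """Logistic regression of a binary outcome with standardized betas.

    Fit by maximum likelihood with an intercept. Standardized coefficients
    multiply each raw coefficient by its predictor's sample SD so that
    effect sizes are comparable across predictors. Perfect or quasi-perfect
    separation is reported via ``converged=False`` rather than silently
    returning diverged estimates.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    X = pd.DataFrame(predictors).astype(float)
    if len(y) != len(X):
        raise ValueError("outcome and predictors must align")
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [0.0, 1.0]):
        raise ValueError("outcome must contain both classes coded 0/1")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    design = sm.add_constant(X, has_constant="add")
    converged = True
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation reported via converged flag
            fit = sm.Logit(y, design).fit(disp=0, maxiter=maxiter, method="newton")
        converged = bool(fit.mle_retvals.get("converged", False))
    except Exception:  # statsmodels raises on hard perfect separation
        fit = None
        converged = False
    if fit is None or not np.isfinite(fit.params).all() or \
            np.abs(np.asarray(fit.params)[1:]).max(initial=0.0) > 1e4:
        converged = False
    if fit is None:
        k = X.shape[1]
        return LogisticFit(predictor_names=tuple(X.columns),
                           coefficients=(float("nan"),) * k,
                           standardized_betas=(float("nan"),) * k,
                           p_values=(1.0,) * k, intercept=float("nan"),
                           converged=False)
    params = np.asarray(fit.params, dtype=float)
    pvals = np.asarray(fit.pvalues, dtype=float)
    sds = X.std(ddof=1).to_numpy()
    betas = params[1:] * sds
    pv = tuple(float(min(max(p, 0.0), 1.0)) if np.isfinite(p) else 1.0
               for p in pvals[1:])
    return LogisticFit(predictor_names=tuple(X.columns),
                       coefficients=tuple(float(c) for c in params[1:]),
                       standardized_betas=tuple(float(b) for b in betas),
                       p_values=pv, intercept=float(params[0]),
                       converged=converged)


def median_split(values) -> tuple[pd.Series, list]:
    """Dichotomize at the median with strict inequalities.

    Returns ``(labels, dropped)`` where labels are 1 for values strictly
    above the median and 0 for values strictly below; observations exactly
    at the median are excluded and their index labels reported.
    """
    ser = pd.Series(values, dtype=float)
    if ser.size < 2:
        raise ValueError("median split requires n >= 2")
    if ser.nunique() == 1:
        raise ValueError("all values equal; median split undefined")
    med = float(ser.median())
    labels = pd.Series(np.where(ser > med, 1, 0), index=ser.index)
    at_median = ser == med
    dropped = list(ser.index[at_median])
    return labels[~at_median], dropped
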