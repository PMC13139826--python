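"""Group-level inference: Welch t-tests from summaries, power, FDR,
group models with an age covariate, covariate associations, and optimal
age matching of cases to a control pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import InsufficientDataError, SeparationError, ValidationError


@dataclass(frozen=True)
class SummaryStats:
    """Mean, SD and n of one group on one variable."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.n < 2:
            raise ValidationError("n must be >= 2")


@dataclass(frozen=True)
class GroupStatResult:
    """One group contrast: estimate (mean difference or log-odds), test
    statistic, p, optional FDR q, and 95% Wald CI."""

    name: str
    estimate: float
    stat: float
    p: float
    ci_low: float
    ci_high: float
    df: float | None = None
    odds_ratio: float | None = None
    q: float | None = None


@dataclass(frozen=True)
class MatchResult:
    pairs: tuple[tuple[int, int], ...]  # (case index, control-pool index)
    total_abs_age_diff: float
    max_abs_age_diff: float


def welch_t(a: SummaryStats, b: SummaryStats) -> tuple[float, float, float]:
    """Welch's t-test from group summaries.

    t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom and a two-sided p.
    """
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    if va + vb == 0:
        raise ValidationError("both groups have zero variance; t undefined")
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def power_two_sample(d: float, n_per_group: int, alpha: float = 0.05,
                     sided: str = "one") -> float:
    """Power of a two-sample t-test at effect size Cohen's d.

    Noncentral t with ncp = d * sqrt(n/2) and df = 2n - 2. One-sided by
    default.
    """
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    if sided not in ("one", "two"):
        raise ValidationError("sided must be 'one' or 'two'")
    df = 2 * n_per_group - 2
    ncp = d * np.sqrt(n_per_group / 2.0)
    if sided == "one":
        crit = sps.t.ppf(1 - alpha, df)
        return float(sps.nct.sf(crit, df, ncp))
    crit = sps.t.ppf(1 - alpha / 2.0, df)
    return float(sps.nct.sf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_indicator(group) -> np.ndarray:
    g = np.asarray(group)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValidationError(f"exactly two groups required, got {list(levels)}")
    # patient group (AN) coded 1 when present; otherwise second level
    one = "AN" if "AN" in levels else levels[1]
    return (g == one).astype(float)


def _design(group, age) -> tuple[np.ndarray, bool]:
    """Intercept + group indicator (+ age unless constant). Returns the
    design matrix and whether age was retained."""
    ind = _group_indicator(group)
    cols = [np.ones_like(ind), ind]
    age_used = False
    if age is not None:
        a = np.asarray(age, dtype=float)
        if np.ptp(a) == 0:
            warnings.warn("age covariate is constant; dropped from the model")
        else:
            cols.append(a)
            age_used = True
    return np.column_stack(cols), age_used


def binomial_group_model(successes, totals, group, age=None,
                         name: str = "binomial") -> GroupStatResult:
    """Logistic regression of per-subject success counts on group + age.

    Subject-level aggregation: each subject contributes (successes, totals).
    Reports the group odds ratio with a 95% Wald CI.
    """
    s = np.asarray(successes, dtype=float)
    t = np.asarray(totals, dtype=float)
    if np.any(s < 0) or np.any(t < s):
        raise ValidationError("require 0 <= successes <= totals")
    X, _ = _design(group, age)
    endog = np.column_stack([s, t - s])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8)
    except PerfectSeparationError as e:
        raise SeparationError(f"perfect separation in {name}: {e}") from e
    coef, se = fit.params[1], fit.bse[1]
    if not np.isfinite(se) or abs(coef) > 20:
        raise SeparationError(
            f"{name}: group log-odds {coef:.2f} (se {se:.2f}) indicates separation")
    z = coef / se
    p = 2.0 * sps.norm.sf(abs(z))
    lo, hi = coef - 1.959963984540054 * se, coef + 1.959963984540054 * se
    return GroupStatResult(name=name, estimate=float(coef), stat=float(z),
                           p=float(p), ci_low=float(lo), ci_high=float(hi),
                           odds_ratio=float(np.exp(coef)))


def gaussian_group_model(y, group, age=None, name: str = "glm") -> GroupStatResult:
    """OLS of a per-subject measure on group + age; group effect reported."""
    yv = np.asarray(y, dtype=float)
    X, _ = _design(group, age)
    if len(yv) < X.shape[1] + 1:
        raise InsufficientDataError("too few subjects for the design")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("collinear design matrix")
    fit = sm.OLS(yv, X).fit()
    coef, se, df = fit.params[1], fit.bse[1], fit.df_resid
    t = coef / se if se > 0 else 0.0
    p = 2.0 * sps.t.sf(abs(t), df) if se > 0 else 1.0
    tcrit = sps.t.ppf(0.975, df)
    return GroupStatResult(name=name, estimate=float(coef), stat=float(t),
                           p=float(p), df=float(df),
                           ci_low=float(coef - tcrit * se),
                           ci_high=float(coef + tcrit * se))


def covariate_association(y, x) -> tuple[float, float, float]:
    """Simple linear association of a measure on a clinical covariate
    within one group: (slope, t, p)."""
    yv = np.asarray(y, dtype=float)
    xv = np.asarray(x, dtype=float)
    if len(yv) < 3:
        raise InsufficientDataError("need >= 3 subjects")
    if np.ptp(xv) == 0:
        raise ValidationError("covariate has zero variance")
    res = sps.linregress(xv, yv)
    t = res.slope / res.stderr if res.stderr > 0 else 0.0
    return float(res.slope), float(t), float(res.pvalue)


def match_pairs(case_ages, control_pool_ages) -> MatchResult:
    """Optimal one-to-one age matching of cases to a larger control pool.

    Solves the assignment problem minimizing the total absolute age
    difference across pairs (Hungarian algorithm).
    """
    cases = np.asarray(case_ages, dtype=float)
    pool = np.asarray(control_pool_ages, dtype=float)
    if cases.size == 0:
        return MatchResult(pairs=(), total_abs_age_diff=0.0, max_abs_age_diff=0.0)
    if pool.size < cases.size:
        raise ValidationError(
            f"control pool ({pool.size}) smaller than case list ({cases.size})")
    cost = np.abs(cases[:, None] - pool[None, :])
    rows, cols = linear_sum_assignment(cost)
    diffs = cost[rows, cols]
    return MatchResult(
        pairs=tuple((int(r), int(c)) for r, c in zip(rows, cols)),
        total_abs_age_diff=float(diffs.sum()),
        max_abs_age_diff=float(diffs.max()),
    )
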