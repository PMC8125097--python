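"""Correlation and group-comparison statistics for the index/risk-factor grid.

Thin, explicitly-conventioned wrappers around scipy/statsmodels plus the
few pieces they do not provide directly: age-partial Pearson
correlations, the Meng–Rosenthal–Rubin test for two overlapping
correlated correlations, age-adjusted standardized regression slopes,
the single-pass SD-score outlier screen, and a lognormality check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CorrelatedCorrelationTest",
    "pearson",
    "partial_pearson",
    "correlation_matrix",
    "fisher_z",
    "compare_correlated",
    "standardized_beta",
    "welch_t",
    "anova_bonferroni",
    "screen_outliers",
    "lognormality_ks",
]


def _clean_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation and two-sided p (t distribution, n−2 df)."""
    x, y = _clean_pair(x, y)
    if len(x) < 4:
        raise ValueError("need n >= 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def partial_pearson(x, y, covariate) -> tuple[float, float]:
    """Pearson correlation of x and y with the covariate partialled out.

    Uses the residual identity
    r_xy·c = (r_xy − r_xc·r_yc) / √((1−r_xc²)(1−r_yc²)),
    with the two-sided p from a t distribution on n−3 df.  A constant
    covariate partials out nothing: the plain Pearson r is returned
    (still on n−3 df).
    """
    x, y = _clean_pair(x, y)
    c = np.asarray(covariate, dtype=float)
    if c.shape != x.shape:
        raise ValueError("covariate must match x and y in length")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r_xy = np.corrcoef(x, y)[0, 1]
    if np.std(c) == 0:
        r = r_xy
    else:
        r_xc = np.corrcoef(x, c)[0, 1]
        r_yc = np.corrcoef(y, c)[0, 1]
        denom = math.sqrt((1.0 - r_xc**2) * (1.0 - r_yc**2))
        if denom == 0:
            raise ValueError("covariate is collinear with an input")
        r = (r_xy - r_xc * r_yc) / denom
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(abs(t), df)
    return float(r), float(p)


def correlation_matrix(
    table: pd.DataFrame, *, partial_on: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise (optionally covariate-partial) Pearson matrix with p-values.

    Returns ``(r, p)`` DataFrames over the numeric columns of ``table``
    (excluding ``partial_on`` itself).
    """
    cols = [c for c in table.columns if c != partial_on]
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    cov = table[partial_on].to_numpy(dtype=float) if partial_on else None
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if cov is None:
                rr, pp = pearson(table[a], table[b])
            else:
                rr, pp = partial_pearson(table[a], table[b], cov)
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p


def fisher_z(r: float) -> float:
    """Fisher variance-stabilizing transform z = atanh(r)."""
    if abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1, got {r!r}")
    return float(np.arctanh(r))


@dataclass
class CorrelatedCorrelationTest:
    """Two correlations sharing one variable, compared on the same sample."""

    r_xa: float
    r_xb: float
    r_ab: float
    n: int
    z: float
    p: float


def compare_correlated(
    r_xa: float, r_xb: float, r_ab: float, n: int
) -> CorrelatedCorrelationTest:
    """Meng–Rosenthal–Rubin z-test for two overlapping correlations.

    Tests r(x,a) = r(x,b) when a and b are measured on the same subjects
    with inter-correlation r_ab, via Fisher-transformed correlations:

        z = (z_xa − z_xb) · √((n−3) / (2(1−r_ab)·h)),
        h = (1 − f·r̄²)/(1 − r̄²),  f = min(1, (1−r_ab)/(2(1−r̄²))),
        r̄² = (r_xa² + r_xb²)/2.
    """
    for name, r in (("r_xa", r_xa), ("r_xb", r_xb), ("r_ab", r_ab)):
        if abs(r) >= 1.0:
            raise ValueError(f"|{name}| must be < 1, got {r!r}")
    if n < 10:
        raise ValueError(f"need n >= 10, got {n}")
    rbar2 = (r_xa**2 + r_xb**2) / 2.0
    f = min(1.0, (1.0 - r_ab) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (fisher_z(r_xa) - fisher_z(r_xb)) * math.sqrt(
        (n - 3) / (2.0 * (1.0 - r_ab) * h)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelatedCorrelationTest(r_xa, r_xb, r_ab, n, float(z), float(p))


def standardized_beta(
    outcome, predictor, covariate=None
) -> tuple[float, tuple[float, float], float]:
    """Standardized slope of outcome on predictor, optionally age-adjusted.

    All variables are z-scored; the model is OLS of the standardized
    outcome on the standardized predictor (plus the standardized
    covariate when given).  Returns ``(beta_std, ci95, r_squared)`` where
    ``r_squared`` is the full-model R².
    """
    y, x = _clean_pair(outcome, predictor)
    if len(y) < 10:
        raise ValueError("need n >= 10 observations")

    def zscore(v):
        s = np.std(v, ddof=1)
        if s == 0:
            raise ValueError("zero-variance input")
        return (v - v.mean()) / s

    cols = [zscore(x)]
    if covariate is not None:
        c = np.asarray(covariate, dtype=float)
        if abs(np.corrcoef(x, c)[0, 1]) > 0.999:
            raise ValueError("predictor and covariate are collinear (|r| > 0.999)")
        cols.append(zscore(c))
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(zscore(y), X).fit()
    lo, hi = fit.conf_int()[1]
    return float(fit.params[1]), (float(lo), float(hi)), float(fit.rsquared)


def welch_t(a, b) -> tuple[float, float]:
    """Welch's two-sided t-test (unequal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def anova_bonferroni(groups) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus Bonferroni-adjusted pairwise Welch comparisons.

    Pairwise p-values are multiplied by the number of pairs and capped at
    1.  Returns ``(F, p, pairwise)`` with one row per group pair.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
    F, p = stats.f_oneway(*groups)
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            t, praw = welch_t(groups[i], groups[j])
            rows.append({
                "group_a": i,
                "group_b": j,
                "t": t,
                "p_raw": praw,
                "p_bonferroni": min(1.0, praw * n_pairs),
            })
    return float(F), float(p), pd.DataFrame(rows)


def screen_outliers(
    values, ids=None, *, cutoff: float = 4.5
) -> tuple[np.ndarray, list]:
    """Single-pass SD-score outlier screen.

    Excludes observations with |value − mean| / SD > ``cutoff`` (default
    4.5 SD).  The screen is applied once — mean and SD are not
    recomputed after exclusion.  Returns ``(retained_values,
    excluded_ids)``; with zero SD nothing is excluded and a warning is
    emitted.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need n >= 3 observations")
    idx = np.arange(len(v)) if ids is None else np.asarray(ids)
    sd = np.std(v, ddof=1)
    if sd == 0:
        warnings.warn("zero standard deviation: outlier screen skipped", stacklevel=2)
        return v, []
    z = np.abs(v - v.mean()) / sd
    keep = z <= cutoff
    return v[keep], list(idx[~keep])


def lognormality_ks(values, *, lilliefors: bool = False) -> tuple[float, float]:
    """Kolmogorov–Smirnov check that ln(values) is plausibly normal.

    By default the asymptotic KS p-value is computed against a normal
    with mean and SD estimated from the same data; because parameters
    are estimated, this p is conservative (biased high) — the Lilliefors
    correction is available with ``lilliefors=True``.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 20:
        raise ValueError("need n >= 20 observations")
    if np.any(v <= 0):
        raise ValueError("values must be positive for a lognormality test")
    logv = np.log(v)
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf
        d, p = _lf(logv, dist="norm")
    else:
        d, p = stats.kstest(logv, "norm", args=(logv.mean(), logv.std(ddof=1)))
    return float(d), float(p)
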