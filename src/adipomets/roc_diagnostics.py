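"""ROC analysis, DeLong AUC inference, Youden cutoffs, diagnostic metrics.

Conventions
-----------
* Higher score ⇒ higher risk, for every index uniformly (including the
  fat-free-mass index).
* A subject is test-positive iff ``score >= threshold``; candidate
  thresholds are the unique observed score values.
* AUC is the trapezoidal area of that ROC, which equals the tie-corrected
  Mann–Whitney statistic  U/(n₊·n₋)  with ½ credit for tied pairs.
* AUC variance, 95% CI, and paired comparisons between two scores on the
  same subjects use the DeLong structural components (placements), the
  standard nonparametric treatment of correlated ROC curves.
* The Youden operating point maximizes J = sensitivity + specificity − 1;
  ties are broken toward the smallest cutoff (the more sensitive test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .age_reference import AgeReferenceModel, ThresholdCurve, threshold_curve

__all__ = [
    "ROCCurve",
    "DiagnosticMetrics",
    "AUCComparison",
    "IndexEvaluation",
    "roc_curve",
    "delong_placements",
    "delong_paired_test",
    "youden_cutoff",
    "diagnostic_metrics",
    "evaluate_index",
]


def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    uniq = np.unique(y)
    if not np.isin(uniq, [0, 1, False, True]).all():
        raise ValueError("labels must be binary (0/1)")
    y = y.astype(bool)
    if y.all() or (~y).all():
        raise ValueError("labels must contain at least one positive and one negative")
    return s, y


@dataclass
class ROCCurve:
    """Empirical ROC of one score: per-threshold sens/spec and DeLong AUC CI.

    ``thresholds`` are the unique score values in ascending order;
    ``sens[k]``/``spec[k]`` are sensitivity and specificity of the test
    "positive iff score ≥ thresholds[k]".
    """

    index_name: str
    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    auc_var: float
    auc_ci95: tuple[float, float]
    n_pos: int
    n_neg: int


@dataclass
class DiagnosticMetrics:
    """Prevalence-dependent diagnostic summary at one operating point."""

    sensitivity: float
    specificity: float
    prevalence: float
    ppv: float
    npv: float
    plr: float
    nlr: float
    cutoff: float | None
    flagged_fraction: float


@dataclass
class AUCComparison:
    """DeLong paired comparison of two correlated AUCs."""

    index_a: str
    index_b: str
    auc_a: float
    auc_b: float
    delta_auc: float
    variance: float
    z: float
    p: float


def delong_placements(scores, labels):
    """DeLong structural components (midrank form).

    Returns ``(auc, v10, v01)`` where ``v10[i]`` is the placement of
    positive subject i among the negatives and ``v01[j]`` the complement
    placement of negative j among the positives; ``mean(v10) = mean(v01)
    = auc`` (tie-corrected Mann–Whitney).
    """
    s, y = _check_scores_labels(scores, labels)
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = float(v10.mean())
    return auc, v10, v01


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_curve(scores, labels, *, index_name: str = "score") -> ROCCurve:
    """Empirical ROC with trapezoidal AUC and DeLong 95% CI."""
    s, y = _check_scores_labels(scores, labels)
    m = int(y.sum())
    n = int((~y).sum())
    uniq = np.unique(s)
    pos_counts = np.bincount(np.searchsorted(uniq, s[y]), minlength=len(uniq))
    neg_counts = np.bincount(np.searchsorted(uniq, s[~y]), minlength=len(uniq))
    # sens at threshold t: positives with score >= t; spec: negatives < t
    sens = pos_counts[::-1].cumsum()[::-1] / m
    spec = (neg_counts.cumsum() - neg_counts) / n

    auc, v10, v01 = delong_placements(s, y)
    var = _delong_variance(v10, v01)
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return ROCCurve(
        index_name=index_name,
        thresholds=uniq,
        sens=sens,
        spec=spec,
        auc=auc,
        auc_var=var,
        auc_ci95=ci,
        n_pos=m,
        n_neg=n,
    )


def delong_paired_test(
    scores_a, scores_b, labels, *, name_a: str = "a", name_b: str = "b"
) -> AUCComparison:
    """Paired DeLong z-test for ΔAUC of two scores on the same subjects.

    The covariance between the two AUC estimates is taken over the shared
    structural components, so the test respects the pairing.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise ValueError("paired scores must be measured on the same subjects")
    auc_a, v10a, v01a = delong_placements(sa, labels)
    auc_b, v10b, v01b = delong_placements(sb, labels)
    m, n = len(v10a), len(v01a)
    cov10 = np.cov(v10a, v10b, ddof=1)[0, 1] if m > 1 else 0.0
    cov01 = np.cov(v01a, v01b, ddof=1)[0, 1] if n > 1 else 0.0
    var = (
        _delong_variance(v10a, v01a)
        + _delong_variance(v10b, v01b)
        - 2.0 * (cov10 / m + cov01 / n)
    )
    delta = auc_a - auc_b
    if var <= 0:
        z = 0.0 if delta == 0 else math.copysign(math.inf, delta)
    else:
        z = delta / math.sqrt(var)
    p = 1.0 if not math.isfinite(z) and delta == 0 else 2.0 * stats.norm.sf(abs(z))
    return AUCComparison(
        index_a=name_a,
        index_b=name_b,
        auc_a=auc_a,
        auc_b=auc_b,
        delta_auc=delta,
        variance=float(max(var, 0.0)),
        z=float(z),
        p=float(min(p, 1.0)),
    )


def youden_cutoff(scores, labels) -> tuple[float, float, float, float]:
    """Cutoff maximizing J = sens + spec − 1 over the observed thresholds.

    Returns ``(cutoff, J, sens, spec)`` at the maximizer; ties are broken
    toward the smallest cutoff.
    """
    roc = roc_curve(scores, labels)
    j = roc.sens + roc.spec - 1.0
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return (
        float(roc.thresholds[best]),
        float(j[best]),
        float(roc.sens[best]),
        float(roc.spec[best]),
    )


def diagnostic_metrics(
    se: float, sp: float, prevalence: float, *, cutoff: float | None = None
) -> DiagnosticMetrics:
    """Predictive values and likelihood ratios at (se, sp, prevalence).

    PPV, NPV and the flagged fraction follow Bayes' rule; PLR = se/(1−sp)
    and NLR = (1−se)/sp are prevalence-free.  Degenerate specificity is
    signalled as ``inf`` (sp = 1 ⇒ PLR undefined; sp = 0 ⇒ NLR undefined)
    rather than silently clipped.
    """
    for name, v in (("se", se), ("sp", sp), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    pi = prevalence
    tp = se * pi
    fp = (1.0 - sp) * (1.0 - pi)
    tn = sp * (1.0 - pi)
    fn = (1.0 - se) * pi
    flagged = tp + fp
    ppv = tp / flagged if flagged > 0 else math.nan
    npv = tn / (tn + fn) if (tn + fn) > 0 else math.nan
    plr = se / (1.0 - sp) if sp < 1.0 else math.inf
    nlr = (1.0 - se) / sp if sp > 0.0 else math.inf
    return DiagnosticMetrics(
        sensitivity=se,
        specificity=sp,
        prevalence=pi,
        ppv=ppv,
        npv=npv,
        plr=plr,
        nlr=nlr,
        cutoff=cutoff,
        flagged_fraction=flagged,
    )


@dataclass
class IndexEvaluation:
    """Full diagnostic work-up of one index against the MetS label."""

    index_name: str
    roc: ROCCurve
    z_star: float
    youden_j: float
    metrics: DiagnosticMetrics
    flagged_fraction_identity: float
    flagged_fraction_empirical: float
    threshold_curve: ThresholdCurve | None = None
    standardized: np.ndarray = field(default=None, repr=False)


def evaluate_index(
    values,
    ages,
    labels,
    model: AgeReferenceModel,
    *,
    age_grid=None,
) -> IndexEvaluation:
    """Standardize an index for age, then run the full diagnostic suite.

    The score entering the ROC is the age-adjusted standardized index
    ``z``; the Youden-optimal ``z*`` becomes the operating cutoff, and
    (if ``age_grid`` is given) the corresponding raw-scale threshold
    curve ``exp(median_fit(age) + z*·s)`` is attached.

    The flagged fraction (share of the cohort testing positive) is
    reported twice: via the identity se·π + (1−sp)(1−π) and as the
    empirical count of subjects with z ≥ z*.  The two agree exactly
    before rounding; published tables that round se/sp first can differ
    in the last digit.
    """
    z = model.standardize(values, ages)
    y = np.asarray(labels).astype(bool)
    roc = roc_curve(z, y, index_name=model.index_name)
    z_star, j, se, sp = youden_cutoff(z, y)
    pi = float(y.mean())
    metrics = diagnostic_metrics(se, sp, pi, cutoff=z_star)
    curve = None
    if age_grid is not None:
        curve = threshold_curve(model, z_star, age_grid, cohort_ages=ages)
    return IndexEvaluation(
        index_name=model.index_name,
        roc=roc,
        z_star=z_star,
        youden_j=j,
        metrics=metrics,
        flagged_fraction_identity=metrics.flagged_fraction,
        flagged_fraction_empirical=float(np.mean(z >= z_star)),
        threshold_curve=curve,
        standardized=z,
    )
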