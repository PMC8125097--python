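"""Age-standardization of adiposity indexes by median (quantile) regression.

Reference-curve construction is the usual LMS problem — an age-varying
location and spread for a positive, right-skewed measurement.  Here the
location is a median regression of the log-index on a sparse polynomial
age basis, and the spread is a single global scale of the log-residuals:

    ln v = β₀ + β₃·a³ + β₄·a⁴ + ε,      a = age / age_scale,

fitted at the τ = 0.5 quantile by minimizing the pinball loss
ρ_τ(u) = u·(τ − 1[u<0]).  The age-adjusted standardized index is

    z(v, age) = (ln v − median_fit(age)) / s,

with ``s`` the standard deviation of the median-fit residuals (a robust
quantile-spread alternative, (q₀.₇₅ − q₀.₂₅)/1.349, is available via
``scale_estimator="iqr"``).  Because exp and the affine map are strictly
increasing, z is a monotone transform of the raw value at every fixed
age, so within-age ranks — and hence within-age ROC behaviour — are
preserved.

The default basis {1, a³, a⁴} is deliberately sparse: over an adult age
span the two high-order terms give a slowly varying, late-accelerating
median curve with only three parameters.  The full quartic
{1, a, a², a³, a⁴} can be requested with ``basis="full_quartic"``.
Rescaling age (default divisor 100) keeps the design matrix
well-conditioned: raw age⁴ would reach ~5·10⁷ at age 83 and dominate
every other column.

The pinball loss is minimized by iteratively reweighted least squares on
an ε-smoothed loss (ε = 1e-6): each iteration solves a weighted least
squares with weights |τ − 1[r<0]| / max(|r|, ε).  For n up to a few
thousand this converges in a handful of iterations; solutions are
checked in the test-suite against the combinatorial characterization of
quantile-regression fits (an optimal fit with p free parameters
interpolates p data points).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AgeReferenceModel",
    "ThresholdCurve",
    "fit_median_curve",
    "pinball_loss",
    "threshold_curve",
]

_BASES = {
    "cubic": (0, 3),              # exponents of a = age/age_scale
    "cubic_quartic": (0, 3, 4),
    "full_quartic": (0, 1, 2, 3, 4),
}


def _design(ages: np.ndarray, basis: str, age_scale: float) -> np.ndarray:
    try:
        powers = _BASES[basis]
    except KeyError:
        raise ValueError(f"unknown basis {basis!r}; expected one of {sorted(_BASES)}")
    a = np.asarray(ages, dtype=float) / age_scale
    return np.column_stack([a**p for p in powers])


def pinball_loss(residuals: np.ndarray, tau: float = 0.5) -> float:
    """Mean pinball (check) loss ρ_τ(u) = u·(τ − 1[u<0])."""
    r = np.asarray(residuals, dtype=float)
    return float(np.mean(r * (tau - (r < 0))))


@dataclass
class AgeReferenceModel:
    """Fitted median curve of one log-index plus a residual scale.

    ``coefficients`` are ordered as the exponents of the chosen basis
    (default: intercept, a³, a⁴ with a = age/age_scale).
    """

    index_name: str
    coefficients: np.ndarray
    residual_scale: float
    age_scale: float = 100.0
    basis: str = "cubic_quartic"
    tau: float = 0.5
    scale_estimator: str = "sd"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not self.residual_scale > 0:
            raise ValueError(f"residual_scale must be > 0, got {self.residual_scale!r}")

    def median_log(self, ages) -> np.ndarray:
        """Fitted median of the log-index at the given ages."""
        return _design(np.atleast_1d(ages), self.basis, self.age_scale) @ self.coefficients

    def median(self, ages) -> np.ndarray:
        """Fitted median on the raw index scale."""
        return np.exp(self.median_log(ages))

    def standardize(self, values, ages) -> np.ndarray:
        """Age-adjusted standardized score z = (ln v − median_fit(age)) / s."""
        v = np.asarray(values, dtype=float)
        if np.any(~np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("index values must be positive and finite")
        return (np.log(v) - self.median_log(ages)) / self.residual_scale

    def inverse_standardize(self, z, ages) -> np.ndarray:
        """Raw index value whose standardized score at ``ages`` equals ``z``."""
        z = np.asarray(z, dtype=float)
        return np.exp(self.median_log(ages) + z * self.residual_scale)

    # -- serialization -------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "index_name": self.index_name,
            "coefficients": self.coefficients.tolist(),
            "residual_scale": self.residual_scale,
            "age_scale": self.age_scale,
            "basis": self.basis,
            "tau": self.tau,
            "scale_estimator": self.scale_estimator,
            "diagnostics": self.diagnostics,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AgeReferenceModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        return cls(**doc)


@dataclass
class ThresholdCurve:
    """Age-specific raw-scale cutoffs exp(median_fit(age) + z*·s)."""

    index_name: str
    z_star: float
    ages: np.ndarray
    cutoffs: np.ndarray
    mean_cutoff: float


def fit_median_curve(
    values,
    ages,
    tau: float = 0.5,
    *,
    index_name: str = "index",
    basis: str = "cubic_quartic",
    age_scale: float = 100.0,
    scale_estimator: str = "sd",
    eps: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> AgeReferenceModel:
    """Fit the τ-quantile regression of ln(values) on the age basis.

    Parameters
    ----------
    values, ages
        Positive index values and ages in years.  At least as many
        subjects as basis functions are required (tiny fits are allowed
        for oracle checks; meaningful reference curves need far more).
    tau
        Quantile level; 0.5 gives the median reference curve.
    scale_estimator
        ``"sd"`` (default): residual_scale = sample SD (ddof=1) of the
        log-residuals.  ``"iqr"``: (q₀.₇₅ − q₀.₂₅)/1.349 of the
        log-residuals, robust to heavy tails.

    Non-convergence within ``max_iter`` is flagged in
    ``diagnostics["converged"]``; the best iterate is still returned.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if v.shape != a.shape or v.ndim != 1:
        raise ValueError("values and ages must be 1-D arrays of equal length")
    n_params = len(_BASES.get(basis, ()))
    if len(v) < max(n_params, 3):
        raise ValueError(
            f"need at least {max(n_params, 3)} subjects to fit basis {basis!r}, "
            f"got {len(v)}"
        )
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("index values must be positive and finite")
    if np.any(a < 18.0) or np.any(a > 100.0):
        raise ValueError("ages must lie within [18, 100] years")
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau!r}")

    y = np.log(v)
    X = _design(a, basis, age_scale)
    # OLS start, then IRLS with ε annealed down to its target value --
    # starting smooth avoids stalling at a point that is stationary for
    # one ε but not for the exact pinball loss
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    converged = False
    it = 0
    eps_schedule = [e for e in (1e-2, 1e-4) if e > eps] + [eps]
    for eps_k in eps_schedule:
        for _ in range(max_iter - it):
            it += 1
            r = y - X @ beta
            w = np.where(r >= 0, tau, 1.0 - tau) / np.maximum(np.abs(r), eps_k)
            Xw = X * w[:, None]
            try:
                beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
            except np.linalg.LinAlgError:
                break
            delta = np.max(np.abs(beta_new - beta))
            beta = beta_new
            if delta < tol:
                converged = eps_k == eps
                break
    beta = _interpolation_polish(X, y, beta, tau)

    resid = y - X @ beta
    if scale_estimator == "sd":
        s = float(np.std(resid, ddof=1))
    elif scale_estimator == "iqr":
        q25, q75 = np.quantile(resid, [0.25, 0.75])
        s = float((q75 - q25) / 1.349)
    else:
        raise ValueError(f"unknown scale_estimator {scale_estimator!r}")
    if s <= 0:  # degenerate (constant) data: scale is arbitrary, pick 1
        s = 1.0

    model = AgeReferenceModel(
        index_name=index_name,
        coefficients=beta,
        residual_scale=s,
        age_scale=age_scale,
        basis=basis,
        tau=tau,
        scale_estimator=scale_estimator,
        diagnostics={
            "iterations": it,
            "converged": bool(converged),
            "pinball_loss": pinball_loss(resid, tau),
            "n": int(len(v)),
            "frac_resid_nonpositive": float(np.mean(resid <= 0)),
        },
    )
    return model


def _interpolation_polish(X, y, beta, tau, max_rounds: int = 50):
    """Descend to an interpolatory optimum of the exact pinball loss.

    A quantile-regression minimizer with p free parameters passes through
    p data points, i.e. sits at a vertex of the LP feasible region.  From
    the IRLS iterate, snap to the vertex through the p smallest-|residual|
    points, then (for modest n, where it is cheap) walk to better adjacent
    vertices by single-point exchanges until none improves — the descent
    the simplex method performs.  For large n the IRLS solution is already
    at optimum to well below estimation error and only the snap is applied.
    """
    n, p = X.shape
    best_loss = pinball_loss(y - X @ beta, tau)
    active = np.argsort(np.abs(y - X @ beta))[:p]
    Xs = X[active]
    if abs(np.linalg.det(Xs)) > 1e-12:
        cand = np.linalg.solve(Xs, y[active])
        loss = pinball_loss(y - X @ cand, tau)
        if loss <= best_loss:
            beta, best_loss = cand, loss
    if n > 500:
        return beta
    active = list(active)
    for _ in range(max_rounds):
        improved = False
        for slot in range(p):
            for j in range(n):
                if j in active:
                    continue
                trial = list(active)
                trial[slot] = j
                Xs = X[trial]
                if abs(np.linalg.det(Xs)) < 1e-12:
                    continue
                cand = np.linalg.solve(Xs, y[trial])
                loss = pinball_loss(y - X @ cand, tau)
                if loss < best_loss - 1e-15:
                    beta, best_loss, active = cand, loss, trial
                    improved = True
        if not improved:
            break
    return beta


def threshold_curve(
    model: AgeReferenceModel,
    z_star: float,
    ages,
    cohort_ages=None,
) -> ThresholdCurve:
    """Raw-scale decision threshold as a function of age.

    ``cutoff(age) = exp(median_fit(age) + z*·s)``: the raw index value at
    which the age-adjusted standardized score equals the operating cutoff
    ``z_star``.  ``mean_cutoff`` averages the per-subject cutoffs over
    ``cohort_ages`` (the grid is used when no cohort is given), giving a
    single summary number per index.
    """
    grid = np.atleast_1d(np.asarray(ages, dtype=float))
    if grid.size == 0:
        raise ValueError("age grid must be non-empty")
    cutoffs = model.inverse_standardize(z_star, grid)
    ref = grid if cohort_ages is None else np.asarray(cohort_ages, dtype=float)
    mean_cutoff = float(np.mean(model.inverse_standardize(z_star, ref)))
    return ThresholdCurve(
        index_name=model.index_name,
        z_star=float(z_star),
        ages=grid,
        cutoffs=cutoffs,
        mean_cutoff=mean_cutoff,
    )
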