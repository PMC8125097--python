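"""Synthetic cohorts of women with obesity for pipeline testing.

The generator emulates the statistical structure the downstream analysis
assumes — not any real patient: an adult female cohort with BMI ≥ 30, an
age-dependent central-adiposity distribution, metabolic-syndrome
components whose risk rises with an age-adjusted waist-to-height signal,
and medication flags nested inside their component.

Construction, per subject (all randomness from one seeded
:class:`numpy.random.Generator`):

1. age ~ truncated normal (50.8 ± 14, range 18–83); height ~ normal;
   BMI = 30 + shifted lognormal (mean excess 13.35, SD 5.9), so the
   obesity inclusion criterion holds by construction; weight back-solved.
2. waist = affine(BMI, height) + noise, multiplied by an age factor
   exp(w₃a³ + w₄a⁴) on the log scale (a = age/100) and floored at
   80.1 cm — every subject satisfies central obesity.
3. FM% ~ normal (50.8 ± 5.35) clipped to (25, 70); FFM% = 100 − FM%.
4. The latent risk axis z is the standardized age-detrended ln(WtHR)
   (the generator knows the age trend it imposed, so no fitting is
   involved).  Each of the four non-anthropometric components is drawn
   from a logistic model  P = expit(α + β·z + γ·age_std + δ·u)  where u
   is a shared frailty factor independent of the anthropometry — it
   clusters the components (setting the MetS prevalence) without adding
   discriminability to any index.  Each intercept α is calibrated by
   bisection so the cohort-mean probability hits the configured
   prevalence exactly.
5. Medication flags are drawn only inside their positive component, at
   the rate that reproduces the configured cohort-level treatment rates.
6. Continuous BP/TG/HDL/glucose values are drawn from truncated normals
   on the side of the clinical cutoff dictated by the component
   indicator (treated subjects may sit on either side), so the rule
   engine reproduces the generated component labels exactly.

Default prevalences (BP 72.3%, TG 33.4%, low HDL 54.0%, glucose 33.0%),
medication rates (54.5 / 7.9 / 16.7%), and cohort moments are the study
conditions this package is designed around; the default association
slopes are calibrated so the age-standardized WtHR discriminates MetS
with AUC ≈ 0.66 and overall MetS prevalence ≈ 60%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .indices import COHORT_COLUMNS

__all__ = ["CohortConfig", "generate", "fixture_small", "lognormal_index_sample"]

_COMPONENTS = ("high_bp", "high_tg", "low_hdl", "high_glucose")


@dataclass
class CohortConfig:
    """Generator configuration; defaults encode the emulated study cohort."""

    n: int = 1528
    seed: int = 0

    # demographics / anthropometry
    age_mean: float = 50.8
    age_sd: float = 14.0
    age_range: tuple[float, float] = (18.0, 83.0)
    height_mean: float = 161.5
    height_sd: float = 6.5
    bmi_floor: float = 30.0
    bmi_excess_mean: float = 13.35   # E[BMI] ≈ 43.35
    bmi_excess_sd: float = 5.9
    fm_mean: float = 50.8
    fm_sd: float = 5.35
    fm_range: tuple[float, float] = (25.0, 70.0)

    # waist model: wc = (c0 + c1·bmi + c2·height + noise)·exp(g(age) − g(ref))
    wc_intercept: float = -10.0
    wc_bmi_slope: float = 1.6
    wc_height_slope: float = 0.35
    wc_noise_sd: float = 6.0
    wc_floor: float = 80.1
    wc_age_coeffs: tuple[float, float] = (0.4, -0.25)  # (a³, a⁴), a = age/100
    wc_age_ref: float = 50.8

    # component models: P = expit(α + β·z + γ·age_std), α calibrated
    component_prevalence: dict = field(default_factory=lambda: {
        "high_bp": 0.723, "high_tg": 0.334, "low_hdl": 0.540, "high_glucose": 0.330,
    })
    assoc_slopes: dict = field(default_factory=lambda: {
        "high_bp": 0.70, "high_tg": 0.70, "low_hdl": 0.70, "high_glucose": 0.70,
    })
    age_slopes: dict = field(default_factory=lambda: {
        "high_bp": 0.55, "high_tg": 0.15, "low_hdl": 0.05, "high_glucose": 0.55,
    })
    #: slope on a shared frailty factor u ~ N(0,1), independent of the
    #: anthropometry: it clusters the components (setting the MetS
    #: prevalence) without making any index more discriminative
    frailty_slope: float = 1.4
    association_scale: float = 1.0   # multiplies every assoc slope (0 ⇒ null)

    # cohort-level medication rates (flags drawn inside positive components)
    med_rates: dict = field(default_factory=lambda: {
        "bp": 0.545, "lipid": 0.079, "glucose": 0.167,
    })

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for name, p in {**self.component_prevalence, **self.med_rates}.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"probability {name!r} must be in (0,1), got {p}")
        for name in _COMPONENTS:
            if name not in self.component_prevalence:
                raise ValueError(f"missing prevalence target for {name!r}")
        comp_to_med = {"high_bp": "bp", "high_tg": "lipid", "high_glucose": "glucose"}
        for comp, med in comp_to_med.items():
            if self.med_rates[med] >= self.component_prevalence[comp]:
                raise ValueError(
                    f"medication rate {med!r} ({self.med_rates[med]}) must be below "
                    f"the {comp!r} prevalence ({self.component_prevalence[comp]}): "
                    "flags are only assigned inside the positive component"
                )


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _age_log_factor(ages: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    w3, w4 = cfg.wc_age_coeffs
    a = ages / 100.0
    ref = cfg.wc_age_ref / 100.0
    g = w3 * a**3 + w4 * a**4
    return g - (w3 * ref**3 + w4 * ref**4)


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Bisection for α with mean(expit(α + eta)) = target."""
    lo, hi = -30.0, 30.0
    if not (expit(lo + eta).mean() < target < expit(hi + eta).mean()):
        raise ValueError(
            f"prevalence target {target} is infeasible for the given linear predictor"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(mid + eta).mean() < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-13:
            break
    return 0.5 * (lo + hi)


def generate(config: CohortConfig | None = None, *, with_truth: bool = False):
    """Draw a synthetic cohort as a DataFrame in the standard CSV schema.

    With ``with_truth=True`` also returns a dict of generator-level truth
    (imposed age-trend coefficients, calibrated intercepts, latent z and
    component draws) for recovery tests.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    age = _truncnorm(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range, size=n)
    height = np.clip(rng.normal(cfg.height_mean, cfg.height_sd, size=n), 140.0, 195.0)
    bmi = cfg.bmi_floor + _shifted_lognormal(rng, cfg.bmi_excess_mean, cfg.bmi_excess_sd, n)
    weight = bmi * (height / 100.0) ** 2

    wc_core = (
        cfg.wc_intercept
        + cfg.wc_bmi_slope * bmi
        + cfg.wc_height_slope * height
        + rng.normal(0.0, cfg.wc_noise_sd, size=n)
    )
    waist = np.maximum(wc_core * np.exp(_age_log_factor(age, cfg)), cfg.wc_floor)

    fm = np.clip(rng.normal(cfg.fm_mean, cfg.fm_sd, size=n), *cfg.fm_range)
    ffm = 100.0 - fm

    # latent risk axis: standardized age-detrended ln(WtHR)
    lw = np.log(waist / height) - _age_log_factor(age, cfg)
    z = (lw - lw.mean()) / lw.std(ddof=0)
    age_std = (age - age.mean()) / age.std(ddof=0)

    frailty = rng.normal(size=n)
    comp = {}
    intercepts = {}
    for name in _COMPONENTS:
        beta = cfg.assoc_slopes[name] * cfg.association_scale
        eta = beta * z + cfg.age_slopes[name] * age_std + cfg.frailty_slope * frailty
        alpha = _calibrate_intercept(eta, cfg.component_prevalence[name])
        comp[name] = rng.uniform(size=n) < expit(alpha + eta)
        intercepts[name] = alpha

    # medication flags, nested inside their positive component
    def med_flag(comp_name, med_name):
        rate = cfg.med_rates[med_name] / cfg.component_prevalence[comp_name]
        flag = np.zeros(n, dtype=bool)
        pos = comp[comp_name]
        flag[pos] = rng.uniform(size=int(pos.sum())) < rate
        return flag

    on_bp = med_flag("high_bp", "bp")
    on_lipid = med_flag("high_tg", "lipid")
    on_glucose = med_flag("high_glucose", "glucose")

    sbp, dbp = _draw_bp(rng, comp["high_bp"], on_bp, n)
    tg = _draw_two_sided(rng, comp["high_tg"], on_lipid, n,
                         lo_mean=105, lo_sd=30, lo_rng=(30, 149.9),
                         hi_mean=190, hi_sd=55, hi_rng=(150, 700),
                         any_mean=160, any_sd=60, any_rng=(40, 700))
    hdl = _draw_two_sided(rng, comp["low_hdl"], np.zeros(n, bool), n,
                          lo_mean=58, lo_sd=9, lo_rng=(50, 120),
                          hi_mean=43, hi_sd=6, hi_rng=(15, 49.9),
                          any_mean=50, any_sd=12, any_rng=(15, 120))
    glucose = _draw_two_sided(rng, comp["high_glucose"], on_glucose, n,
                              lo_mean=87, lo_sd=8, lo_rng=(50, 99.9),
                              hi_mean=120, hi_sd=30, hi_rng=(100, 400),
                              any_mean=130, any_sd=45, any_rng=(60, 400))
    z50 = np.clip(rng.normal(480.0, 50.0, size=n), 350.0, 650.0)

    df = pd.DataFrame({
        "id": [f"S{i + 1:05d}" for i in range(n)],
        "age": age,
        "height": height,
        "weight": weight,
        "waist": waist,
        "fm_pct": fm,
        "ffm_pct": ffm,
        "sbp": sbp,
        "dbp": dbp,
        "tg": tg,
        "hdl": hdl,
        "glucose": glucose,
        "on_bp_meds": on_bp,
        "on_lipid_meds": on_lipid,
        "on_glucose_meds": on_glucose,
        "z50": z50,
    })[list(COHORT_COLUMNS)]

    if not with_truth:
        return df
    truth = {
        "config": asdict(cfg),
        "wc_age_coeffs": list(cfg.wc_age_coeffs),
        "intercepts": intercepts,
        "component_prevalence_targets": dict(cfg.component_prevalence),
        "latent_z": z,
        "components": {k: v.copy() for k, v in comp.items()},
    }
    return df, truth


def _shifted_lognormal(rng, mean, sd, size):
    """Lognormal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _draw_bp(rng, high, treated, n):
    """SBP/DBP consistent with the BP component: untreated positives exceed
    a cutoff, negatives sit strictly below both, treated may be controlled."""
    sbp = np.empty(n)
    dbp = np.empty(n)
    neg = ~high
    sbp[neg] = _truncnorm(rng, 121, 8, 85, 129.9, int(neg.sum()))
    dbp[neg] = _truncnorm(rng, 74, 6, 50, 84.9, int(neg.sum()))
    pos_rx = high & treated
    sbp[pos_rx] = _truncnorm(rng, 128, 13, 85, 200, int(pos_rx.sum()))
    dbp[pos_rx] = _truncnorm(rng, 77, 8, 50, 130, int(pos_rx.sum()))
    pos_un = high & ~treated
    sbp[pos_un] = _truncnorm(rng, 138, 10, 130, 210, int(pos_un.sum()))
    dbp[pos_un] = _truncnorm(rng, 81, 7, 50, 130, int(pos_un.sum()))
    return np.round(sbp, 1), np.round(dbp, 1)


def _draw_two_sided(rng, positive, treated, n, *, lo_mean, lo_sd, lo_rng,
                    hi_mean, hi_sd, hi_rng, any_mean, any_sd, any_rng):
    """Continuous value on the component-consistent side of its cutoff."""
    out = np.empty(n)
    neg = ~positive
    out[neg] = _truncnorm(rng, lo_mean, lo_sd, *lo_rng, size=int(neg.sum()))
    pos_rx = positive & treated
    out[pos_rx] = _truncnorm(rng, any_mean, any_sd, *any_rng, size=int(pos_rx.sum()))
    pos_un = positive & ~treated
    out[pos_un] = _truncnorm(rng, hi_mean, hi_sd, *hi_rng, size=int(pos_un.sum()))
    return np.round(out, 1)


def lognormal_index_sample(
    n: int,
    *,
    beta0: float,
    beta3: float,
    beta4: float,
    sigma: float,
    seed: int,
    age_scale: float = 100.0,
    age_range: tuple[float, float] = (18.0, 83.0),
):
    """Index values with a known log-scale median curve, for recovery tests.

    ages ~ uniform on ``age_range``; values = exp(β₀ + β₃a³ + β₄a⁴ + σ·N)
    with a = age/age_scale.  Returns ``(values, ages)``.
    """
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*age_range, size=n)
    a = ages / age_scale
    values = np.exp(beta0 + beta3 * a**3 + beta4 * a**4 + sigma * rng.normal(size=n))
    return values, ages


def fixture_small() -> pd.DataFrame:
    """Deterministic 12-subject table covering every MetS rule branch.

    Each row carries its expected classification in the
    ``expected_n_components`` / ``expected_mets`` columns: every
    component is individually decisive somewhere, every medication
    override appears, and row F01 sits exactly on the non-qualifying
    side of all five cutoffs.  MetS prevalence is 6/12 by construction.
    """
    base = dict(height=160.0, weight=90.0, fm_pct=50.0, ffm_pct=50.0, z50=480.0)
    rows = [
        # id, age, waist, sbp, dbp, tg, hdl, glu, bp_rx, lip_rx, glu_rx, n_comp, mets
        ("F01", 35, 79.9, 129, 84, 149, 50.0, 99, 0, 0, 0, 0, False),  # all boundaries, none qualify
        ("F02", 52, 80.0, 130, 84, 150, 49.9, 100, 0, 0, 0, 5, True),  # all boundaries qualify
        ("F03", 28, 70.0, 120, 85, 100, 60.0, 90, 0, 0, 0, 1, False),  # DBP alone triggers BP
        ("F04", 44, 95.0, 120, 80, 100, 60.0, 90, 0, 0, 0, 1, False),  # central obesity only
        ("F05", 61, 85.0, 120, 80, 200, 60.0, 105, 0, 0, 0, 3, True),  # waist+TG+glucose
        ("F06", 39, 70.0, 120, 80, 100, 40.0, 90, 0, 0, 0, 1, False),  # low HDL only
        ("F07", 47, 70.0, 120, 80, 100, 60.0, 120, 0, 0, 0, 1, False), # glucose only
        ("F08", 66, 85.0, 110, 70, 160, 60.0, 90, 1, 0, 0, 3, True),   # BP via meds override
        ("F09", 58, 90.0, 120, 80, 80, 60.0, 110, 0, 1, 0, 3, True),   # TG via meds override
        ("F10", 71, 90.0, 120, 80, 100, 40.0, 85, 0, 0, 1, 3, True),   # glucose via meds override
        ("F11", 33, 85.0, 120, 80, 100, 45.0, 90, 0, 0, 0, 2, False),  # exactly two → not MetS
        ("F12", 76, 70.0, 110, 70, 80, 70.0, 80, 1, 1, 1, 3, True),    # all meds, low values
    ]
    records = []
    for (sid, age, waist, sbp, dbp, tg, hdl, glu,
         bp_rx, lip_rx, glu_rx, n_comp, mets) in rows:
        records.append({
            "id": sid, "age": float(age), "waist": float(waist),
            "sbp": float(sbp), "dbp": float(dbp), "tg": float(tg),
            "hdl": float(hdl), "glucose": float(glu),
            "on_bp_meds": bool(bp_rx), "on_lipid_meds": bool(lip_rx),
            "on_glucose_meds": bool(glu_rx),
            **base,
            "expected_n_components": n_comp,
            "expected_mets": mets,
        })
    df = pd.DataFrame(records)
    return df[list(COHORT_COLUMNS) + ["expected_n_components", "expected_mets"]]
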