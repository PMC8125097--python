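# Methods

`adipomets` evaluates how well simple adiposity / body-composition
indexes identify metabolic syndrome (MetS) in adult women with obesity,
and derives age-specific screening thresholds for each index. This note
documents the statistical machinery, the choices made where the design
was genuinely open, and what the synthetic cohort generator does and
does not emulate.

## Indexes

Six indexes are computed from height (cm), weight (kg), waist
circumference WC (cm) and bioimpedance-derived fat-mass percentage FM%:
BMI = weight/height², TMI = weight/height³, WtHR = WC/height,
FMI = BMI·FM%/100, FFMI = BMI·FFM%/100, and BMFI = BMI·(FM%/100)·(WC in
metres). For BMFI the fat-mass percentage enters as a *fraction*:
dimensional analysis (kg/m² × 1 × m = kg/m) and the physiological
magnitude of the index (tens of kg/m, not thousands) both force this
reading of the formula. Heights are accepted in centimetres only;
conversion to metres is internal, so there is exactly one unit
convention at the API surface. The impedance index ZI₅₀ = height²/Z₅₀
is exposed for completeness but the pipeline takes FM%/FFM% as inputs —
estimating body composition from raw impedance is out of scope.

A FM% + FFM% mismatch beyond 0.1 percentage points triggers a warning,
not an error: both quantities are reported rounded by BIA software and
small inconsistencies are measurement artefacts, not data corruption.

## MetS rule engine

The five components use the IDF-style operational thresholds for adult
women: WC ≥ 80 cm; SBP ≥ 130 and/or DBP ≥ 85 mmHg or antihypertensive
treatment; TG ≥ 150 mg/dL or lipid-lowering treatment; HDL-C < 50 mg/dL;
fasting glucose ≥ 100 mg/dL or antidiabetic treatment. Comparisons use
exactly this inclusivity with no tolerance band — HDL-C = 50.0 is *not*
low — because a screening rule must be bit-reproducible. Lipid-lowering
treatment counts toward the triglyceride component only; the HDL rule
has no treatment override. The overall label is **any 3 of 5**
components. The strict IDF aggregation (central obesity mandatory plus
2 of the remaining 4) is available as `require_central_obesity=True`,
default off; in a cohort where every subject is centrally obese the two
rules coincide anyway.

## Age-standardization (quantile-regression reference curves)

Reference-curve construction treats each index as a positive,
right-skewed measurement whose location drifts with age — the classic
LMS setting. Instead of a full Box–Cox LMS fit, the median of the
log-index is modelled by quantile regression:

    ln v = β₀ + β₃·a³ + β₄·a⁴ + ε,   a = age/100,  τ = 0.5,

and the age-adjusted standardized score is z = (ln v − fit(age))/s with
s the SD of the log-residuals. Design choices:

* **Basis.** The default basis is the sparse {1, a³, a⁴}: two high-order
  terms give a slowly varying, late-accelerating median over the adult
  span with only three parameters. The full quartic
  {1, a, a², a³, a⁴} and a two-parameter {1, a³} basis are available via
  `basis=`. Note that a³ and a⁴ are nearly collinear over ages 18–83,
  so the *individual* coefficients are weakly identified (sampling SD
  ≈ 0.1 at n = 5000, σ = 0.1) even though the fitted *curve* is stable;
  downstream results depend only on the curve.
* **Age rescaling** by 100 before powering keeps the design conditioned
  (raw age⁴ ≈ 5·10⁷ at age 83 would dominate every column).
* **Scale.** "Standardized residuals" uses the global residual SD
  (ddof = 1) from the τ = 0.5 fit, so a cohort standardized against its
  own fit has SD exactly 1. A robust quantile-spread scale
  (q₀.₇₅ − q₀.₂₅)/1.349 is available via `scale_estimator="iqr"`.
* **Solver.** The pinball loss is minimized by iteratively reweighted
  least squares on an ε-smoothed loss, with ε annealed 1e-2 → 1e-4 →
  1e-6 (tolerance 1e-8, ≤ 200 iterations), then snapped onto the
  interpolatory vertex an LP solver would return (a quantile-regression
  optimum with p free parameters passes through p data points; for
  n ≤ 500 single-point vertex exchanges are applied until no adjacent
  vertex improves). The solver is validated in the test-suite against
  brute-force enumeration of all interpolants on small instances and
  against `statsmodels` QuantReg on larger ones. Non-convergence is
  flagged in the diagnostics; the best iterate is still returned.

Because exp and the affine map are strictly increasing, standardization
preserves within-age ranks, so ROC analysis on z equals ROC analysis on
raw values within any single-age stratum (tested).

The age-specific screening threshold for an index is the raw-scale
preimage of the Youden-optimal standardized cutoff z*:
cutoff(age) = exp(fit(age) + z*·s). The reported `mean_cutoff` averages
the per-subject cutoffs over the cohort's own age distribution.

## ROC, DeLong, Youden, diagnostic metrics

Orientation is *higher score ⇒ higher risk* for every index uniformly,
including FFMI; a subject is test-positive iff score ≥ threshold, and
candidate thresholds are the unique observed scores. The trapezoidal
AUC then equals the tie-corrected Mann–Whitney statistic (½ credit for
tied pairs), asserted to 1e-12 in the tests. AUC variance, 95% CIs and
paired comparisons between indexes on the same subjects use the DeLong
structural components (midrank form); bootstrap CIs were deliberately
not used so that single-curve inference and paired comparisons share
one variance model. Pairwise p-values are reported raw (a Bonferroni
option exists, default off), matching common practice for descriptive
AUC tables.

The Youden cutoff maximizes J = se + sp − 1 over observed thresholds,
with ties broken toward the *smallest* cutoff — deterministic, and the
more sensitive operating point, which is the right bias for a screening
instrument. PPV, NPV and the flagged fraction follow Bayes' rule at the
cohort prevalence; PLR = se/(1−sp), NLR = (1−se)/sp, with degenerate
specificity signalled as `inf` rather than clipped. The flagged
fraction is reported both via the identity se·π + (1−sp)(1−π) and as
the empirical count of subjects above the cutoff; the two agree exactly
before rounding, but tables that round se/sp first can disagree in the
last digit — published screening tables show exactly this artefact, so
both numbers are kept.

## Association statistics

Pearson and age-partial correlations (partial r via the standard
residual identity, p on n−3 df), standardized regression slopes
(all variables z-scored, OLS with the age covariate, coefficient CI and
model R² both reported — summary tables are ambiguous about which of
r or R² they print, so the package labels both explicitly), Welch
t-tests, one-way ANOVA with Bonferroni-adjusted pairwise comparisons,
and a Kolmogorov–Smirnov lognormality screen. The KS p-value is
asymptotic with parameters estimated from the data, hence conservative;
a Lilliefors-corrected p is available behind a flag. Two correlations
sharing a variable (two indexes against one risk factor) are compared
with the Meng–Rosenthal–Rubin overlapping-correlations z-test on
Fisher-transformed values — the cited "Fisher transformation" approach
does not pin down a variant, and this is the standard one for
overlapping designs. The outlier screen excludes observations beyond
4.5 SD in a single pass (mean and SD are not recomputed after
exclusion), mirroring one-shot data-cleaning practice.

## Synthetic cohort generator

The generator emulates the *structure the analysis assumes*, not any
real patient population: an adult female cohort (ages truncated normal
50.8 ± 14 on 18–83), universal obesity (BMI = 30 + shifted lognormal
with mean excess 13.35 and SD 5.9), universal central obesity (waist
floored at 80.1 cm), FM% normal 50.8 ± 5.35, and component prevalences
BP 72.3%, TG 33.4%, low HDL 54.0%, glucose 33.0% with medication rates
54.5 / 7.9 / 16.7% nested inside their positive component.

Waist is an affine function of BMI and height plus noise, times a
log-scale age factor exp(0.4a³ − 0.25a⁴) (a = age/100) that raises
central adiposity by ≈ 10% from age 20 to 80. The latent risk axis z is
the standardized age-detrended ln(WtHR) — known to the generator
exactly, no fitting. Each component is Bernoulli with
P = expit(α + β·z + γ·age_std + δ·u), where u is a shared "frailty"
factor independent of the anthropometry. The frailty term exists
because dependence and discriminability must be controlled separately:
the components need enough mutual correlation to pull the 3-of-5 MetS
prevalence down to 60% (independent components at the stated marginals
would give ≈ 67%), but that correlation must not flow through z or
every index would become unrealistically discriminative. Intercepts α
are calibrated by bisection so the cohort-mean probability hits each
prevalence target exactly; Bernoulli noise is then the only source of
calibration error (SD ≈ 0.3% at n = 20 000).

Continuous BP/TG/HDL/glucose values are drawn from truncated normals on
the side of the clinical cutoff dictated by the component indicator
(treated subjects may sit on either side), so the rule engine
reproduces the generated component labels exactly — label/value
consistency is a generator invariant, not a statistical accident.

Default slopes (β = 0.70 per component, δ = 1.4, γ = 0.55/0.15/0.05/0.55)
were calibrated once, by grid search at n = 100 000, to the study
conditions the package is designed around: age-standardized WtHR
discriminating MetS with AUC ≈ 0.66 and overall MetS prevalence ≈ 60%.
Under these defaults every index lands in the 0.5–0.7 AUC band with
WtHR the strongest — WtHR is strongest *by construction*, since the
latent axis is built from it; the generator makes the pipeline
testable, it does not re-derive which index is best.

What the generator does **not** emulate: the real covariance of waist
with BMI and height (the affine+noise form is a documented
approximation), menopause biology (age enters only through smooth
trends), BMI-class substructure, and the joint distribution of the
laboratory values beyond their component-consistent marginals. Passing
tests therefore demonstrate that the *pipeline* recovers known
structure; they say nothing about which index is best in real cohorts.

## Problem sizes and determinism

Tests and the acceptance script use n = 2 000–20 000 synthetic subjects
(20 000 where calibration targets are checked, 5 000 for parameter and
AUC recovery — the scale at which Monte-Carlo error, ≈ 0.008 in AUC, is
comfortably below the tolerances), 2 000 replicates for type-I-error
calibration, and 100–500 random instances for oracle equivalences. All
randomness flows from explicit seeds through `numpy.random.Generator`;
same seed ⇒ byte-identical cohorts and byte-identical report CSVs (the
run manifest stores no timestamps for this reason).

## Known limitations

* The β₃/β₄ coefficients of the default basis are individually
  ill-conditioned (see above); interpret the fitted curve, not the
  coefficients.
* DeLong inference is asymptotic; for very small strata (tens of
  subjects) its CIs can undercover.
* The KS lognormality p-value without the Lilliefors correction is
  conservative by construction.
* The generator's medication model never treats component-negative
  subjects, a simplification (real cohorts contain treated, controlled
  patients whose component is positive *only because* of the flag —
  here such subjects exist for BP/TG/glucose via the "treated, any
  value" branch, but no one is treated without their component).
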