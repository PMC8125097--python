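"""End-to-end analysis runs: configuration, cohort IO, report assembly.

``run_analyze`` ties the stages together: validate the cohort CSV,
compute the six indexes, classify MetS, fit one age-reference model per
index on the whole cohort, then evaluate each index (whole cohort and
per age stratum) and write the report bundle:

* ``descriptives_by_mets.csv`` — mean ± SD of every variable for all /
  MetS− / MetS+ with Welch-t p-values
* ``association_report.csv``  — age-partial correlations and age-adjusted
  standardized betas (with CI and model R²) per index × risk factor
* ``diagnostics.csv``          — AUC (DeLong CI), Youden cutoff, sens,
  spec, PPV, NPV, PLR, NLR, flagged fractions, per index × stratum
* ``auc_comparisons.csv``      — pairwise DeLong tests per stratum
* ``threshold_curves.csv``     — age-specific raw-scale cutoffs per index
* ``roc_coordinates.csv``      — ROC points for plotting
* ``mets_summary.csv``         — component counts and prevalences
* ``manifest.json``            — seed, config hash, library versions

Outputs are deterministic: given (seed, config, input) every byte of
every CSV is reproducible (the manifest carries no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .indices import COHORT_COLUMNS, INDEX_NAMES, compute_index_table
from .mets_rules import classify_mets_table, cohort_mets_summary
from .age_reference import fit_median_curve
from .roc_diagnostics import delong_paired_test, diagnostic_metrics, evaluate_index
from .assoc_stats import partial_pearson, standardized_beta, welch_t
from .synthetic_cohort import CohortConfig, generate

__all__ = [
    "AnalysisConfig", "DataError", "ConfigError",
    "read_cohort_csv", "run_analyze", "run_simulate",
]

RISK_FACTORS = ("sbp", "dbp", "hdl", "glucose", "tg")
DESCRIPTIVE_VARS = (
    "age", "sbp", "dbp", "tg", "hdl", "glucose",
    "bmi", "wthr", "fmi", "ffmi", "tmi", "bmfi", "waist", "fm_pct", "ffm_pct",
)


class DataError(ValueError):
    """Malformed input data (CLI exit code 1)."""


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


@dataclass
class AnalysisConfig:
    """Options for one analysis run.

    ``age_strata`` are half-open ``[lo, hi)`` intervals; 44.9 years falls
    in the first default stratum, 45.0 in the second.  A stratum with
    fewer than ``min_stratum_n`` subjects is skipped with a warning.
    """

    input: str | Path = ""
    outdir: str | Path = "results"
    age_strata: tuple = ((18.0, 45.0), (45.0, 55.0), (55.0, float("inf")))
    indexes: tuple = INDEX_NAMES
    basis: str = "cubic_quartic"
    scale_estimator: str = "sd"
    min_stratum_n: int = 30
    seed: int = 0
    require_central_obesity: bool = False

    def validate(self) -> None:
        if not self.indexes:
            raise ConfigError("at least one index must be selected")
        unknown = set(self.indexes) - set(INDEX_NAMES)
        if unknown:
            raise ConfigError(f"unknown indexes: {sorted(unknown)}")
        strata = sorted(self.age_strata)
        for (lo, hi) in strata:
            if not lo < hi:
                raise ConfigError(f"empty stratum [{lo}, {hi})")
        for (_, hi), (lo2, _) in zip(strata, strata[1:]):
            if hi != lo2:
                raise ConfigError("age strata must be contiguous and non-overlapping")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        try:
            doc = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "age_strata" in doc:
            doc["age_strata"] = tuple(
                (float(lo), float("inf") if hi in (None, ".inf", "inf") else float(hi))
                for lo, hi in doc["age_strata"]
            )
        if "indexes" in doc:
            doc["indexes"] = tuple(doc["indexes"])
        return cls(**doc)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV against the standard schema.

    Schema violations raise :class:`DataError` with row numbers (1-based,
    excluding the header).  ``z50`` is optional; medication flags accept
    0/1 or true/false.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc
    required = [c for c in COHORT_COLUMNS if c != "z50"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"missing required columns: {missing}")
    if "z50" not in df.columns:
        df["z50"] = np.nan
    problems = []
    for col in ("age", "height", "weight", "waist", "fm_pct", "ffm_pct",
                "sbp", "dbp", "tg", "hdl", "glucose"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if col != "age":
            bad |= vals <= 0
        for row in df.index[bad][:20]:
            problems.append(f"row {row + 1}: invalid {col} = {df.loc[row, col]!r}")
        df[col] = vals
    bad_age = (df["age"] < 18) | (df["age"] > 100)
    for row in df.index[bad_age][:20]:
        problems.append(f"row {row + 1}: age {df.loc[row, 'age']} outside [18, 100]")
    for col in ("on_bp_meds", "on_lipid_meds", "on_glucose_meds"):
        mapped = df[col].map(
            {True: True, False: False, 1: True, 0: False, "1": True, "0": False,
             "true": True, "false": False, "True": True, "False": False}
        )
        for row in df.index[mapped.isna()][:20]:
            problems.append(f"row {row + 1}: invalid flag {col} = {df.loc[row, col]!r}")
        df[col] = mapped.astype(bool)
    if problems:
        raise DataError("cohort validation failed:\n  " + "\n  ".join(problems))
    return df[list(COHORT_COLUMNS)]


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def _stratum_label(lo: float, hi: float) -> str:
    return f"{lo:g}-{hi:g}" if np.isfinite(hi) else f"{lo:g}+"


def run_analyze(config: AnalysisConfig, *, verbose: bool = False) -> dict:
    """Run the full analysis; writes the report bundle and returns it in
    memory as ``{artifact_name: DataFrame | dict}``."""
    config.validate()
    cohort = read_cohort_csv(config.input)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    idx = compute_index_table(cohort)
    mets = classify_mets_table(
        cohort, require_central_obesity=config.require_central_obesity
    )
    data = pd.concat([cohort, idx, mets[["n_components", "mets"]]], axis=1)
    labels = data["mets"].to_numpy(dtype=bool)
    ages = data["age"].to_numpy(dtype=float)

    # Table-1 analogue: descriptives by MetS status
    rows = []
    for var in DESCRIPTIVE_VARS:
        v = data[var].to_numpy(dtype=float)
        a, b = v[~labels], v[labels]
        t, p = welch_t(a, b) if min(len(a), len(b)) >= 2 else (np.nan, np.nan)
        rows.append({
            "variable": var,
            "mean_all": v.mean(), "sd_all": v.std(ddof=1),
            "mean_mets_neg": a.mean(), "sd_mets_neg": a.std(ddof=1),
            "mean_mets_pos": b.mean(), "sd_mets_pos": b.std(ddof=1),
            "welch_t": t, "p": p,
        })
    descriptives = pd.DataFrame(rows)

    # Table-2 analogue: age-partial correlations + standardized betas
    rows = []
    for index_name in config.indexes:
        x = data[index_name].to_numpy(dtype=float)
        for rf in RISK_FACTORS:
            y = data[rf].to_numpy(dtype=float)
            r, pr = partial_pearson(y, x, ages)
            beta, (lo, hi), r2 = standardized_beta(y, x, ages)
            rows.append({
                "index": index_name, "risk_factor": rf,
                "partial_r": r, "partial_p": pr,
                "beta_std": beta, "beta_lo95": lo, "beta_hi95": hi,
                "model_r2": r2,
            })
    associations = pd.DataFrame(rows)

    # age-reference models fitted on the whole cohort, one per index
    models = {
        name: fit_median_curve(
            data[name].to_numpy(dtype=float), ages,
            index_name=name, basis=config.basis,
            scale_estimator=config.scale_estimator,
        )
        for name in config.indexes
    }

    age_grid = np.arange(18.0, 84.0)
    strata: list[tuple[str, np.ndarray]] = [("all", np.ones(len(data), dtype=bool))]
    for lo, hi in config.age_strata:
        mask = (ages >= lo) & (ages < hi)
        label = _stratum_label(lo, hi)
        if mask.sum() < config.min_stratum_n:
            if verbose:
                print(f"warning: stratum {label} has {int(mask.sum())} subjects; skipped")
            continue
        strata.append((label, mask))

    diag_rows, roc_rows, cmp_rows, curve_rows = [], [], [], []
    evaluations: dict[tuple[str, str], object] = {}
    for label, mask in strata:
        y = labels[mask]
        if y.all() or (~y).all():
            continue
        for name in config.indexes:
            ev = evaluate_index(
                data.loc[mask, name].to_numpy(dtype=float), ages[mask], y,
                models[name], age_grid=age_grid if label == "all" else None,
            )
            evaluations[(label, name)] = ev
            m = ev.metrics
            diag_rows.append({
                "stratum": label, "index": name, "n": int(mask.sum()),
                "prevalence": m.prevalence,
                "auc": ev.roc.auc,
                "auc_lo95": ev.roc.auc_ci95[0], "auc_hi95": ev.roc.auc_ci95[1],
                "cutoff_z": ev.z_star, "youden_j": ev.youden_j,
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "ppv": m.ppv, "npv": m.npv, "plr": m.plr, "nlr": m.nlr,
                "flagged_identity": ev.flagged_fraction_identity,
                "flagged_empirical": ev.flagged_fraction_empirical,
            })
            for t, se, sp in zip(ev.roc.thresholds, ev.roc.sens, ev.roc.spec):
                roc_rows.append({
                    "stratum": label, "index": name,
                    "threshold_z": t, "sensitivity": se, "fpr": 1.0 - sp,
                })
            if ev.threshold_curve is not None:
                for a, c in zip(ev.threshold_curve.ages, ev.threshold_curve.cutoffs):
                    curve_rows.append({
                        "index": name, "age": a, "cutoff": c,
                        "mean_cutoff": ev.threshold_curve.mean_cutoff,
                    })
        for i, a_name in enumerate(config.indexes):
            for b_name in config.indexes[i + 1:]:
                cmp_ = delong_paired_test(
                    evaluations[(label, a_name)].standardized,
                    evaluations[(label, b_name)].standardized,
                    y, name_a=a_name, name_b=b_name,
                )
                cmp_rows.append({
                    "stratum": label, "index_a": a_name, "index_b": b_name,
                    "auc_a": cmp_.auc_a, "auc_b": cmp_.auc_b,
                    "delta_auc": cmp_.delta_auc, "z": cmp_.z, "p": cmp_.p,
                })

    diagnostics = pd.DataFrame(diag_rows)
    # self-consistency audit: Bayes identities must close on every row
    _audit_bayes(diagnostics)
    comparisons = pd.DataFrame(cmp_rows)
    curves = pd.DataFrame(curve_rows)
    roc_coords = pd.DataFrame(roc_rows)
    summary = cohort_mets_summary(mets)

    manifest = {
        "adipomets_version": __version__,
        "seed": config.seed,
        "n_subjects": int(len(data)),
        "config": _jsonable(config),
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable(config), sort_keys=True).encode()
        ).hexdigest(),
        "versions": _library_versions(),
        "artifacts": [
            "descriptives_by_mets.csv", "association_report.csv",
            "diagnostics.csv", "auc_comparisons.csv",
            "threshold_curves.csv", "roc_coordinates.csv", "mets_summary.csv",
        ],
    }

    _fmt(descriptives, outdir / "descriptives_by_mets.csv")
    _fmt(associations, outdir / "association_report.csv")
    _fmt(diagnostics, outdir / "diagnostics.csv")
    _fmt(comparisons, outdir / "auc_comparisons.csv")
    _fmt(curves, outdir / "threshold_curves.csv")
    _fmt(roc_coords, outdir / "roc_coordinates.csv")
    _fmt(summary, outdir / "mets_summary.csv")
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    for name, model in models.items():
        model.to_json(outdir / f"age_model_{name}.json")

    return {
        "descriptives": descriptives, "associations": associations,
        "diagnostics": diagnostics, "comparisons": comparisons,
        "threshold_curves": curves, "roc_coordinates": roc_coords,
        "mets_summary": summary, "manifest": manifest, "models": models,
    }


def _audit_bayes(diagnostics: pd.DataFrame, atol: float = 1e-9) -> None:
    for _, row in diagnostics.iterrows():
        m = diagnostic_metrics(row["sensitivity"], row["specificity"], row["prevalence"])
        for col, val in (("ppv", m.ppv), ("npv", m.npv), ("plr", m.plr),
                         ("nlr", m.nlr), ("flagged_identity", m.flagged_fraction)):
            lhs = row[col]
            if np.isfinite(val) and abs(lhs - val) > atol:
                raise AssertionError(
                    f"Bayes identity audit failed for {row['index']} "
                    f"({row['stratum']}): {col} = {lhs} vs {val}"
                )


def _jsonable(config) -> dict:
    doc = dataclasses.asdict(config)
    for k, v in doc.items():
        if isinstance(v, Path):
            doc[k] = str(v)
        if isinstance(v, tuple):
            doc[k] = json.loads(json.dumps(v))
    return doc


def _library_versions() -> dict:
    import scipy
    import statsmodels
    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def run_simulate(
    config: CohortConfig,
    out_csv: str | Path,
    truth_json: str | Path | None = None,
) -> pd.DataFrame:
    """Generate a cohort CSV plus an optional sidecar of generator truth."""
    config.validate()
    df, truth = generate(config, with_truth=True)
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_csv, index=False, float_format="%.6g")
    if truth_json is not None:
        doc = {
            "config": truth["config"],
            "intercepts": truth["intercepts"],
            "component_prevalence_targets": truth["component_prevalence_targets"],
            "component_counts": {
                k: int(v.sum()) for k, v in truth["components"].items()
            },
        }
        Path(truth_json).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return df
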