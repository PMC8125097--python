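"""Rule-based metabolic-syndrome (MetS) classification.

The five component rules follow the IDF operational thresholds as applied
in adult screening practice:

* central obesity:      waist circumference ≥ 80 cm
* raised blood pressure: SBP ≥ 130 mmHg and/or DBP ≥ 85 mmHg, or
  antihypertensive treatment
* raised triglycerides: TG ≥ 150 mg/dL, or lipid-lowering treatment
* reduced HDL-C:        HDL-C < 50 mg/dL (female cutoff; no treatment
  override — lipid-lowering therapy counts toward the TG component only)
* raised fasting glucose: ≥ 100 mg/dL (5.6 mmol/L), or antidiabetic
  treatment

The overall label is *any three of the five* components.  The strict IDF
variant — central obesity mandatory plus two of the remaining four — is
available via ``require_central_obesity=True`` but is off by default.
All cutoff comparisons use exactly the stated inclusivity; there is no
tolerance band (HDL-C = 50.0 is *not* low).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import SubjectRecord

__all__ = [
    "MetSResult",
    "COMPONENT_NAMES",
    "classify_mets",
    "classify_mets_table",
    "cohort_mets_summary",
]

COMPONENT_NAMES = (
    "central_obesity", "high_bp", "high_tg", "low_hdl", "high_glucose",
)

# (cutoffs; all inclusive as documented above)
WAIST_CUTOFF = 80.0
SBP_CUTOFF = 130.0
DBP_CUTOFF = 85.0
TG_CUTOFF = 150.0
HDL_CUTOFF = 50.0   # exclusive: low iff hdl < 50
GLUCOSE_CUTOFF = 100.0


@dataclass(frozen=True)
class MetSResult:
    """Per-subject component indicators and the overall MetS label."""

    central_obesity: bool
    high_bp: bool
    high_tg: bool
    low_hdl: bool
    high_glucose: bool
    n_components: int
    mets: bool


def _require(subject: SubjectRecord, name: str) -> float:
    v = getattr(subject, name)
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        raise ValueError(f"required field {name!r} is missing for subject {subject.id!r}")
    return v


def classify_mets(
    subject: SubjectRecord, *, require_central_obesity: bool = False
) -> MetSResult:
    """Apply the five component rules and the 3-of-5 aggregation.

    With ``require_central_obesity=True`` the strict IDF aggregation is
    used instead: central obesity mandatory plus ≥2 of the other four.
    """
    for name in ("waist", "sbp", "dbp", "tg", "hdl", "glucose",
                 "on_bp_meds", "on_lipid_meds", "on_glucose_meds"):
        _require(subject, name)
    central = subject.waist >= WAIST_CUTOFF
    high_bp = (
        subject.sbp >= SBP_CUTOFF
        or subject.dbp >= DBP_CUTOFF
        or bool(subject.on_bp_meds)
    )
    high_tg = subject.tg >= TG_CUTOFF or bool(subject.on_lipid_meds)
    low_hdl = subject.hdl < HDL_CUTOFF
    high_glucose = subject.glucose >= GLUCOSE_CUTOFF or bool(subject.on_glucose_meds)
    n = int(central) + int(high_bp) + int(high_tg) + int(low_hdl) + int(high_glucose)
    if require_central_obesity:
        mets = central and (n - 1) >= 2
    else:
        mets = n >= 3
    return MetSResult(central, high_bp, high_tg, low_hdl, high_glucose, n, mets)


def classify_mets_table(
    cohort: pd.DataFrame, *, require_central_obesity: bool = False
) -> pd.DataFrame:
    """Vectorized :func:`classify_mets` over a cohort table.

    Returns a DataFrame (aligned on the input index) with the five
    component booleans, ``n_components`` and ``mets`` — the standard
    per-subject output CSV layout.
    """
    required = ("waist", "sbp", "dbp", "tg", "hdl", "glucose",
                "on_bp_meds", "on_lipid_meds", "on_glucose_meds")
    for name in required:
        if name not in cohort.columns:
            raise ValueError(f"cohort table is missing column {name!r}")
        if cohort[name].isna().any():
            rows = cohort.index[cohort[name].isna()][:5].tolist()
            raise ValueError(f"column {name!r} has missing values (rows {rows})")
    central = cohort["waist"] >= WAIST_CUTOFF
    high_bp = (
        (cohort["sbp"] >= SBP_CUTOFF)
        | (cohort["dbp"] >= DBP_CUTOFF)
        | cohort["on_bp_meds"].astype(bool)
    )
    high_tg = (cohort["tg"] >= TG_CUTOFF) | cohort["on_lipid_meds"].astype(bool)
    low_hdl = cohort["hdl"] < HDL_CUTOFF
    high_glucose = (
        (cohort["glucose"] >= GLUCOSE_CUTOFF)
        | cohort["on_glucose_meds"].astype(bool)
    )
    out = pd.DataFrame(
        {
            "central_obesity": central,
            "high_bp": high_bp,
            "high_tg": high_tg,
            "low_hdl": low_hdl,
            "high_glucose": high_glucose,
        },
        index=cohort.index,
    )
    out["n_components"] = out[list(COMPONENT_NAMES)].sum(axis=1).astype(int)
    if require_central_obesity:
        out["mets"] = central & ((out["n_components"] - central.astype(int)) >= 2)
    else:
        out["mets"] = out["n_components"] >= 3
    return out


def cohort_mets_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Counts and prevalences (percent, 1 decimal) per component and overall.

    ``results`` may be either a cohort table (classified on the fly) or
    the output of :func:`classify_mets_table`.
    """
    if len(results) == 0:
        raise ValueError("cannot summarize an empty cohort")
    if "mets" not in results.columns:
        results = classify_mets_table(results)
    n = len(results)
    rows = []
    for name in (*COMPONENT_NAMES, "mets"):
        count = int(results[name].sum())
        rows.append({
            "component": name,
            "count": count,
            "n": n,
            "prevalence_pct": round(100.0 * count / n, 1),
        })
    return pd.DataFrame(rows)
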