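"""Adiposity and body-composition indexes.

Six indexes are computed from raw anthropometry and bioimpedance-derived
body composition:

=====  =======  =====================================================
name   unit     formula
=====  =======  =====================================================
BMI    kg/m²    weight / height²
TMI    kg/m³    weight / height³  (tri-ponderal mass index)
WtHR   —        waist / height    (both in cm)
FMI    kg/m²    fat mass / height²        = BMI · FM%/100
FFMI   kg/m²    fat-free mass / height²   = BMI · FFM%/100
BMFI   kg/m     BMI · fat-mass fraction · waist in metres
=====  =======  =====================================================

Heights are accepted in centimetres only; conversion to metres is
internal.  BMFI applies the fat-mass percentage as a fraction (÷100):
dimensional analysis (kg/m² × 1 × m = kg/m) and the physiological
magnitude of the index (tens, not thousands) both require it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "IndexPanel",
    "INDEX_NAMES",
    "COHORT_COLUMNS",
    "compute_indexes",
    "compute_index_table",
    "records_from_dataframe",
    "impedance_index",
]

#: canonical order of the six indexes in every tabular output
INDEX_NAMES = ("bmi", "bmfi", "fmi", "ffmi", "tmi", "wthr")

#: CSV schema for a cohort file (header names exactly as the field names);
#: ``z50`` is optional.
COHORT_COLUMNS = (
    "id", "age", "height", "weight", "waist", "fm_pct", "ffm_pct",
    "sbp", "dbp", "tg", "hdl", "glucose",
    "on_bp_meds", "on_lipid_meds", "on_glucose_meds", "z50",
)


@dataclass(frozen=True)
class SubjectRecord:
    """One woman's raw measurements and medication flags.

    Units: ``age`` years, ``height``/``waist`` cm, ``weight`` kg,
    ``fm_pct``/``ffm_pct`` percent of body weight, ``sbp``/``dbp`` mmHg,
    ``tg``/``hdl``/``glucose`` mg/dL, ``z50`` Ω (whole-body impedance at
    50 kHz, optional).
    """

    id: str
    age: float
    height: float
    weight: float
    waist: float
    fm_pct: float
    ffm_pct: float
    sbp: float
    dbp: float
    tg: float
    hdl: float
    glucose: float
    on_bp_meds: bool = False
    on_lipid_meds: bool = False
    on_glucose_meds: bool = False
    z50: float | None = None

    def __post_init__(self) -> None:
        _require_positive("height", self.height)
        _require_positive("weight", self.weight)
        _require_positive("waist", self.waist)
        if not 18.0 <= self.age <= 100.0:
            raise ValueError(f"age must be in [18, 100], got {self.age!r}")
        if not 100.0 < self.height < 220.0:
            raise ValueError(f"height must be in (100, 220) cm, got {self.height!r}")
        for name in ("sbp", "dbp", "tg", "hdl", "glucose"):
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")
        if self.z50 is not None and not np.isnan(self.z50) and self.z50 <= 0:
            raise ValueError(f"z50 must be positive, got {self.z50!r}")
        if _present(self.fm_pct) and _present(self.ffm_pct):
            if abs(self.fm_pct + self.ffm_pct - 100.0) > 0.1:
                # measurement rounding tolerance; larger gaps are suspicious
                # but not fatal
                warnings.warn(
                    f"fm_pct + ffm_pct = {self.fm_pct + self.ffm_pct:.3f} "
                    f"for subject {self.id!r} (expected 100 ± 0.1)",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class IndexPanel:
    """The six computed indexes for one subject (units in class docs above)."""

    bmi: float
    bmfi: float
    fmi: float
    ffmi: float
    tmi: float
    wthr: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _present(v) -> bool:
    return v is not None and np.isfinite(v)


def _require_positive(name: str, value) -> None:
    if value is None or not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a positive number, got {value!r}")


def compute_indexes(subject: SubjectRecord) -> IndexPanel:
    """Compute the six-index panel for a single subject.

    Raises :class:`ValueError` naming the offending field when an
    anthropometric input is missing or non-positive.
    """
    for name in ("height", "weight", "waist", "fm_pct", "ffm_pct"):
        _require_positive(name, getattr(subject, name))
    h_m = subject.height / 100.0
    bmi = subject.weight / h_m**2
    fm_frac = subject.fm_pct / 100.0
    return IndexPanel(
        bmi=bmi,
        bmfi=bmi * fm_frac * (subject.waist / 100.0),
        fmi=bmi * fm_frac,
        ffmi=bmi * subject.ffm_pct / 100.0,
        tmi=subject.weight / h_m**3,
        wthr=subject.waist / subject.height,
    )


def compute_index_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`compute_indexes` over a cohort table.

    Parameters
    ----------
    cohort
        DataFrame with at least the columns ``height``, ``weight``,
        ``waist``, ``fm_pct``, ``ffm_pct`` (the cohort CSV schema).

    Returns
    -------
    DataFrame with columns :data:`INDEX_NAMES`, aligned on the input index.
    """
    for name in ("height", "weight", "waist", "fm_pct", "ffm_pct"):
        if name not in cohort.columns:
            raise ValueError(f"cohort table is missing column {name!r}")
        col = cohort[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(col) & (col > 0)):
            bad = cohort.index[~(np.isfinite(col) & (col > 0))][:5].tolist()
            raise ValueError(
                f"column {name!r} has missing or non-positive values "
                f"(first offending rows: {bad})"
            )
    h_m = cohort["height"] / 100.0
    bmi = cohort["weight"] / h_m**2
    fm_frac = cohort["fm_pct"] / 100.0
    out = pd.DataFrame(
        {
            "bmi": bmi,
            "bmfi": bmi * fm_frac * (cohort["waist"] / 100.0),
            "fmi": bmi * fm_frac,
            "ffmi": bmi * cohort["ffm_pct"] / 100.0,
            "tmi": cohort["weight"] / h_m**3,
            "wthr": cohort["waist"] / cohort["height"],
        },
        index=cohort.index,
    )
    return out[list(INDEX_NAMES)]


def records_from_dataframe(cohort: pd.DataFrame) -> list[SubjectRecord]:
    """Row-wise conversion of a cohort table into validated records."""
    out = []
    for _, row in cohort.iterrows():
        z50 = row.get("z50")
        out.append(SubjectRecord(
            id=str(row["id"]),
            age=float(row["age"]),
            height=float(row["height"]),
            weight=float(row["weight"]),
            waist=float(row["waist"]),
            fm_pct=float(row["fm_pct"]),
            ffm_pct=float(row["ffm_pct"]),
            sbp=float(row["sbp"]),
            dbp=float(row["dbp"]),
            tg=float(row["tg"]),
            hdl=float(row["hdl"]),
            glucose=float(row["glucose"]),
            on_bp_meds=bool(row["on_bp_meds"]),
            on_lipid_meds=bool(row["on_lipid_meds"]),
            on_glucose_meds=bool(row["on_glucose_meds"]),
            z50=None if z50 is None or pd.isna(z50) else float(z50),
        ))
    return out


def impedance_index(height: float, z50: float) -> float:
    """Impedance index ZI₅₀ = height(cm)² / Z₅₀(Ω), in cm²/Ω.

    ZI₅₀ is the standard bioimpedance predictor of fat-free mass; it is
    exposed for completeness (the pipeline takes FM%/FFM% as inputs).
    """
    _require_positive("height", height)
    if z50 is None or not np.isfinite(z50) or z50 <= 0:
        raise ValueError(f"z50 must be positive, got {z50!r}")
    return height**2 / z50
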