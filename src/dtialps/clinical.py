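"""Deterministic clinical classifications and derived covariates.

Implements the cohort's rule-based labels — metabolic syndrome (≥ 3 of 5
criteria with sex-specific waist and HDL cutoffs), chronic kidney disease
(eGFR or proteinuria), overweight (BMI ≥ 25) — and the derived laboratory
ratios (Tchol/HDL, BUN/Cr, estimated anion gap Na − (Cl + HCO₃)).

Missing-data semantics are explicit: a classification whose decidable
inputs cannot force the outcome returns ``None`` (indeterminate), never a
silent False; derived quantities with missing inputs are NaN, never 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "DerivedFlags",
    "metabolic_syndrome",
    "classify_ckd",
    "derive_covariates",
    "derive_table",
]


def _get(record: Mapping, key: str) -> float | None:
    """Fetch a numeric field, mapping absent/NaN/None to None."""
    v = record.get(key)
    if v is None:
        return None
    try:
        v = float(v)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


@dataclass(frozen=True)
class DerivedFlags:
    bmi: float
    overweight: bool | None
    metabolic_syndrome: bool | None
    criteria_met: int
    ckd: bool | None
    tchol_hdl_ratio: float
    bun_cr_ratio: float
    anion_gap_est: float


def _sexed_cutoff(record: Mapping, male_cut: float, female_cut: float) -> float | None:
    sex = record.get("sex")
    if sex in ("male", "m", "M", 0):
        return male_cut
    if sex in ("female", "f", "F", 1):
        return female_cut
    return None


def metabolic_syndrome(record: Mapping) -> tuple[bool | None, int]:
    """Metabolic syndrome: at least three of five criteria positive.

    Criteria (boundaries exactly as defined): waist ≥ 90 cm (male) /
    ≥ 80 cm (female); SBP ≥ 130 or DBP ≥ 85 mmHg; fasting glucose
    ≥ 100 mg/dL; HDL < 40 (male) / < 50 (female) mg/dL; TG ≥ 150 mg/dL.

    Returns ``(status, criteria_met)`` where ``criteria_met`` counts the
    definitely-positive criteria.  When some criteria are unevaluable
    (missing inputs) and the decidable ones cannot force the outcome
    either way, ``status`` is ``None`` (indeterminate).
    """
    waist_cut = _sexed_cutoff(record, 90.0, 80.0)
    hdl_cut = _sexed_cutoff(record, 40.0, 50.0)

    waist = _get(record, "waist")
    sbp = _get(record, "systolic_bp")
    dbp = _get(record, "diastolic_bp")
    glucose = _get(record, "fasting_glucose")
    hdl = _get(record, "hdl")
    tg = _get(record, "tg")

    criteria: list[bool | None] = [
        None if (waist is None or waist_cut is None) else waist >= waist_cut,
        None if (sbp is None and dbp is None)
        else ((sbp is not None and sbp >= 130.0) or (dbp is not None and dbp >= 85.0)),
        None if glucose is None else glucose >= 100.0,
        None if (hdl is None or hdl_cut is None) else hdl < hdl_cut,
        None if tg is None else tg >= 150.0,
    ]
    # blood-pressure criterion: one missing arm can only force a positive
    if criteria[1] is False and (sbp is None or dbp is None):
        criteria[1] = None

    n_pos = sum(1 for c in criteria if c is True)
    n_unknown = sum(1 for c in criteria if c is None)
    if n_pos >= 3:
        return True, n_pos
    if n_pos + n_unknown < 3:
        return False, n_pos
    return None, n_pos


def classify_ckd(record: Mapping) -> bool | None:
    """Chronic kidney disease: eGFR < 60, or proteinuria by urine protein
    grade ≥ 1+, albumin–creatinine ratio ≥ 30, or protein–creatinine ratio
    ≥ 150.  Any positive criterion decides True; all-negative available
    evidence decides False; no defining input at all is indeterminate."""
    egfr = _get(record, "egfr")
    upg = _get(record, "urine_protein_grade")
    acr = _get(record, "albumin_creatinine_ratio")
    pcr = _get(record, "protein_creatinine_ratio")
    inputs = (egfr, upg, acr, pcr)
    if all(v is None for v in inputs):
        return None
    if egfr is not None and egfr < 60.0:
        return True
    if upg is not None and upg >= 1.0:
        return True
    if acr is not None and acr >= 30.0:
        return True
    if pcr is not None and pcr >= 150.0:
        return True
    return False


def derive_covariates(record: Mapping) -> DerivedFlags:
    """Derived covariates for one subject.

    BMI = weight / height² (kg/m²; overweight at BMI ≥ 25),
    Tchol/HDL ratio, BUN/Cr ratio, and estimated anion gap
    Na − (Cl + HCO₃) in mEq/L.  Missing inputs propagate as NaN (flags as
    ``None``); a nonpositive height is rejected.
    """
    height = _get(record, "height")
    weight = _get(record, "weight")
    if height is not None and height <= 0:
        raise ValueError(f"nonpositive height {height}")
    bmi = weight / height**2 if (height is not None and weight is not None) else math.nan
    overweight = None if math.isnan(bmi) else bmi >= 25.0

    tchol, hdl = _get(record, "tchol"), _get(record, "hdl")
    tchol_hdl = tchol / hdl if (tchol is not None and hdl not in (None, 0.0)) else math.nan

    bun, cr = _get(record, "bun"), _get(record, "creatinine")
    bun_cr = bun / cr if (bun is not None and cr not in (None, 0.0)) else math.nan

    na, cl, hco3 = _get(record, "sodium"), _get(record, "chloride"), _get(record, "bicarbonate")
    anion = na - (cl + hco3) if None not in (na, cl, hco3) else math.nan

    ms, n_met = metabolic_syndrome(record)
    return DerivedFlags(
        bmi=bmi,
        overweight=overweight,
        metabolic_syndrome=ms,
        criteria_met=n_met,
        ckd=classify_ckd(record),
        tchol_hdl_ratio=tchol_hdl,
        bun_cr_ratio=bun_cr,
        anion_gap_est=anion,
    )


def derive_table(df: pd.DataFrame, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Apply :func:`derive_covariates` row-wise to a participant table.

    ``column_map`` renames table columns to the canonical field names
    (e.g. ``{"hgt_m": "height"}``).  Indeterminate classifications come
    back as pandas NA so the stats layer treats them as missing.
    """
    if column_map:
        df = df.rename(columns=dict(column_map))
    rows = []
    for _, row in df.iterrows():
        flags = derive_covariates(row.to_dict())
        rows.append(
            {
                "bmi": flags.bmi,
                "overweight": flags.overweight,
                "metabolic_syndrome": flags.metabolic_syndrome,
                "criteria_met": flags.criteria_met,
                "ckd": flags.ckd,
                "tchol_hdl_ratio": flags.tchol_hdl_ratio,
                "bun_cr_ratio": flags.bun_cr_ratio,
                "anion_gap_est": flags.anion_gap_est,
            }
        )
    out = pd.DataFrame(rows, index=df.index)
    for col in ("overweight", "metabolic_syndrome", "ckd"):
        out[col] = out[col].astype("boolean")
    return pd.concat([df, out], axis=1)
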