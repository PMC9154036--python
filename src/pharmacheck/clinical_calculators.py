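"""Renal-function and body-weight calculators used as rule triggers and context.

The trigger quantity for all renal rules is the Cockcroft–Gault creatinine
clearance (ClCG) computed on the *dosing weight* — the lower of measured and
ideal body weight — not the laboratory-reported eGFR.  CKD-EPI eGFR and the
percent change between the last two eGFR values are computed as decision
context.

All results are carried at full floating precision; rounding to 0.1 happens
only at display time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import datetime
from typing import Optional

from .ehr_model import (
    Analyte,
    EhrStore,
    PatientRecord,
    Sex,
    DEFAULT_LAB_WINDOW_DAYS,
    last_two_values,
    recent_labs,
)

#: Cockcroft–Gault SI-unit sex constants (creatinine in µmol/L).
CG_K = {Sex.male: 1.23, Sex.female: 1.04}

#: CKD-EPI 2009 constants (creatinine in mg/dL), without race coefficient.
_CKDEPI_KAPPA = {Sex.male: 0.9, Sex.female: 0.7}
_CKDEPI_ALPHA = {Sex.male: -0.411, Sex.female: -0.329}

CREATININE_MGDL_TO_UMOLL = 88.4


def ideal_body_weight(height_cm: Optional[float], sex: Sex) -> Optional[float]:
    """Devine ideal body weight (kg); None when height is unknown.

    50 kg (male) / 45.5 kg (female) + 0.9 kg per cm above 152 cm, floored
    at zero for very short heights.
    """
    if height_cm is None:
        return None
    if height_cm <= 0:
        raise ValueError("height_cm must be > 0")
    base = 50.0 if sex is Sex.male else 45.5
    return max(base + 0.9 * (height_cm - 152.0), 0.0)


def dosing_weight(
    weight_measured_kg: Optional[float], weight_ideal_kg: Optional[float]
) -> Optional[float]:
    """Lowest of measured and ideal body weight; None when neither is known."""
    weights = [w for w in (weight_measured_kg, weight_ideal_kg) if w is not None]
    return min(weights) if weights else None


def cockcroft_gault(
    age_years: float, weight_kg: float, creatinine_umol_l: float, sex: Sex
) -> float:
    """Cockcroft–Gault creatinine clearance (mL/min), SI form.

    ``(140 − age) × weight × k / creatinine`` with k = 1.23 (male) or
    1.04 (female); clamped at 0 for ages above 140.  Restricted to adults.
    """
    if age_years < 18:
        raise ValueError("Cockcroft-Gault restricted to adults (age >= 18)")
    if weight_kg <= 0:
        raise ValueError("weight_kg must be > 0")
    if creatinine_umol_l <= 0:
        raise ValueError("creatinine_umol_l must be > 0")
    return max((140.0 - age_years) * weight_kg * CG_K[sex] / creatinine_umol_l, 0.0)


def ckd_epi(creatinine_umol_l: float, age_years: float, sex: Sex) -> float:
    """CKD-EPI 2009 eGFR (mL/min/1.73 m²), race-free.

    Two-arm spline in creatinine (mg/dL) around the sex-specific knot κ,
    with sex exponents α below the knot and −1.209 above, age decay
    0.993^age and a 1.018 female factor.
    """
    if age_years < 18:
        raise ValueError("CKD-EPI restricted to adults (age >= 18)")
    if creatinine_umol_l <= 0:
        raise ValueError("creatinine_umol_l must be > 0")
    scr = creatinine_umol_l / CREATININE_MGDL_TO_UMOLL
    kappa = _CKDEPI_KAPPA[sex]
    alpha = _CKDEPI_ALPHA[sex]
    egfr = (
        141.0
        * min(scr / kappa, 1.0) ** alpha
        * max(scr / kappa, 1.0) ** -1.209
        * 0.993**age_years
    )
    if sex is Sex.female:
        egfr *= 1.018
    return egfr


def delta_egfr_percent(previous: float, latest: float) -> Optional[float]:
    """Signed percent change between the last two eGFR values.

    Returns None (with a warning) when the previous value is non-positive.
    """
    if previous <= 0:
        warnings.warn("previous eGFR <= 0; delta-eGFR undefined", stacklevel=2)
        return None
    return 100.0 * (latest - previous) / previous


def convert_creatinine(value: float, unit: str) -> float:
    """Harmonise a creatinine value to µmol/L (accepts µmol/L or mg/dL)."""
    if unit in ("umol/L", "µmol/L"):
        return value
    if unit == "mg/dL":
        return value * CREATININE_MGDL_TO_UMOLL
    raise ValueError(f"unknown creatinine unit {unit!r}")


@dataclass
class RenalAssessment:
    """Bundle of renal-function values displayed with (and triggering) alerts."""

    creatinine_umol_l: float
    creatinine_published_at: datetime
    weight_measured_kg: Optional[float]
    weight_ideal_kg: Optional[float]
    weight_selected_kg: float
    clcg_ml_min: float
    egfr_ml_min_173: float
    delta_egfr_pct: Optional[float] = None
    previous_creatinine_umol_l: list[float] | None = None


def assess_renal(
    patient: PatientRecord,
    store: EhrStore,
    as_of: datetime,
    window_days: float = DEFAULT_LAB_WINDOW_DAYS,
) -> Optional[RenalAssessment]:
    """Full renal work-up for one patient, or None when it cannot be computed.

    Abstains (returns None) when there is no in-window creatinine, no usable
    weight, or the patient is outside the adult scope — renal rules then
    skip the patient rather than alerting on missing data.
    """
    labs = recent_labs(store, patient.patient_id, Analyte.creatinine, window_days, as_of)
    if not labs or patient.age < 18:
        return None
    ibw = ideal_body_weight(patient.height_cm, patient.sex)
    selected = dosing_weight(patient.weight_measured_kg, ibw)
    if selected is None:
        return None
    latest = labs[0]
    if latest.value <= 0:
        return None
    clcg = cockcroft_gault(patient.age, selected, latest.value, patient.sex)
    egfr = ckd_epi(latest.value, patient.age, patient.sex)

    delta: Optional[float] = None
    prev_egfr, last_egfr = last_two_values(
        store, patient.patient_id, Analyte.egfr_ckdepi, as_of, window_days
    )
    if prev_egfr is not None and last_egfr is not None:
        delta = delta_egfr_percent(prev_egfr.value, last_egfr.value)
    elif len(labs) > 1 and labs[1].value > 0:
        # fall back to eGFR recomputed from the last two creatinine values
        delta = delta_egfr_percent(
            ckd_epi(labs[1].value, patient.age, patient.sex), egfr
        )
    return RenalAssessment(
        creatinine_umol_l=latest.value,
        creatinine_published_at=latest.published_at,
        weight_measured_kg=patient.weight_measured_kg,
        weight_ideal_kg=ibw,
        weight_selected_kg=selected,
        clcg_ml_min=clcg,
        egfr_ml_min_173=egfr,
        delta_egfr_pct=delta,
        previous_creatinine_umol_l=[lab.value for lab in labs[1:]],
    )
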