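"""Clinical derived variables and 10-year cardiovascular risk scores.

Implements Friedewald LDL, the 2021 race-free CKD-EPI eGFR, SCORE2 /
SCORE2-OP (moderate-risk-region calibration by default), the Framingham
general-CVD risk function, and AHI-based OSA severity classes.
Coefficient tables live as versioned JSON data files with provenance
headers so they can be audited against the cited publications.

Subjects ineligible for a score (diabetes for SCORE2, age or SBP outside
the algorithm range, missing lipids) receive a :class:`NotApplicable`
value carrying the reason, never a silent NaN.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Union

from .synth import FEMALE, MALE, SubjectProfile

MGDL_PER_MMOL = 38.67           # cholesterol unit conversion
UMOL_PER_MGDL_CREA = 88.4       # creatinine unit conversion
FRAMINGHAM_CAP_PCT = 31.0       # display cap applied above 30 %


@dataclass(frozen=True)
class NotApplicable:
    """Marker for a score that cannot be computed, with the reason why."""

    reason: str

    def __bool__(self) -> bool:
        return False


RiskValue = Union[float, NotApplicable]


def _load(name: str) -> dict:
    with resources.files("nocturne.data").joinpath(name).open() as fh:
        return json.load(fh)


_SCORE2 = _load("score2.json")
_SCORE2OP = _load("score2op.json")
_FRAMINGHAM = _load("framingham.json")


# --------------------------------------------------------------------------
# derived laboratory variables
# --------------------------------------------------------------------------

def friedewald_ldl(tc: float, hdl: float, tg: float) -> RiskValue:
    """LDL cholesterol (mmol/l) by Friedewald: TC - HDL - TG/2.2.

    Invalid above 4.5 mmol/l triglycerides (the conventional bound for
    the formula's VLDL approximation).
    """
    if tc < 0 or hdl < 0 or tg < 0:
        raise ValueError("lipid inputs must be non-negative")
    if tg > 4.5:
        return NotApplicable("hypertriglyceridemia")
    return tc - hdl - tg / 2.2


def egfr_ckdepi2021(creatinine_umol: float, age: float, sex: str) -> float:
    """eGFR (ml/min/1.73 m^2) by the 2021 race-free CKD-EPI equation."""
    if creatinine_umol <= 0:
        raise ValueError("creatinine must be positive")
    if age < 18:
        raise ValueError("equation is defined for adults (age >= 18)")
    scr = creatinine_umol / UMOL_PER_MGDL_CREA     # mg/dl
    female = sex == FEMALE
    kappa = 0.7 if female else 0.9
    alpha = -0.241 if female else -0.302
    egfr = (142.0
            * min(scr / kappa, 1.0) ** alpha
            * max(scr / kappa, 1.0) ** -1.200
            * 0.9938 ** age)
    if female:
        egfr *= 1.012
    return egfr


def classify_osa(ahi: float) -> str:
    """OSA severity from the apnoea--hypopnea index (events/h)."""
    if ahi < 0:
        raise ValueError("AHI must be non-negative")
    if ahi < 5:
        return "none"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


# --------------------------------------------------------------------------
# SCORE2 / SCORE2-OP
# --------------------------------------------------------------------------

def _calibrate(uncal: float, scale: list) -> float:
    return 1.0 - math.exp(-math.exp(scale[0] + scale[1] * math.log(-math.log(1.0 - uncal))))


def _score2_young(subject: SubjectProfile, region: str) -> float:
    tab = _SCORE2
    c = tab["coefficients"][subject.sex]
    cen = tab["centering"]
    cage = (subject.age - cen["age"][0]) / cen["age"][1]
    csbp = (subject.office_sbp - cen["sbp"][0]) / cen["sbp"][1]
    ctc = (subject.total_cholesterol - cen["total_cholesterol"][0])
    chdl = (subject.hdl - cen["hdl"][0]) / cen["hdl"][1]
    smoke = 1.0 if subject.current_smoking else 0.0
    lp = (c["age"] * cage + c["smoking"] * smoke + c["sbp"] * csbp
          + c["total_cholesterol"] * ctc + c["hdl"] * chdl
          + c["smoking_x_age"] * smoke * cage
          + c["sbp_x_age"] * csbp * cage
          + c["total_cholesterol_x_age"] * ctc * cage
          + c["hdl_x_age"] * chdl * cage)
    uncal = 1.0 - tab["baseline_survival"][subject.sex] ** math.exp(lp)
    return _calibrate(uncal, tab["calibration_scales"][region][subject.sex])


def _score2_op(subject: SubjectProfile, region: str) -> float:
    tab = _SCORE2OP
    c = tab["coefficients"][subject.sex]
    cen = tab["centering"]
    cage = subject.age - cen["age"][0]
    csbp = subject.office_sbp - cen["sbp"][0]
    ctc = subject.total_cholesterol - cen["total_cholesterol"][0]
    chdl = subject.hdl - cen["hdl"][0]
    smoke = 1.0 if subject.current_smoking else 0.0
    diab = 1.0 if subject.diabetes else 0.0
    lp = (c["age"] * cage + c["diabetes"] * diab + c["smoking"] * smoke
          + c["sbp"] * csbp + c["total_cholesterol"] * ctc + c["hdl"] * chdl
          + c["diabetes_x_age"] * diab * cage
          + c["smoking_x_age"] * smoke * cage
          + c["sbp_x_age"] * csbp * cage
          + c["total_cholesterol_x_age"] * ctc * cage
          + c["hdl_x_age"] * chdl * cage)
    uncal = 1.0 - tab["baseline_survival"][subject.sex] ** math.exp(
        lp - tab["mean_linear_predictor"][subject.sex])
    return _calibrate(uncal, tab["calibration_scales"][region][subject.sex])


def score2(subject: SubjectProfile, region: str = "moderate") -> RiskValue:
    """SCORE2 (ages 40-69) / SCORE2-OP (70-89) 10-year CVD risk, %.

    Eligibility mirrors the usual study exclusions: prevalent diabetes,
    age outside 40-89, missing lipid status, or systolic pressure outside
    the algorithm's 100-179 mmHg range yield :class:`NotApplicable`.
    """
    if subject.diabetes:
        return NotApplicable("diabetes")
    if subject.age < 40 or subject.age > 89:
        return NotApplicable("age_range")
    for v in (subject.total_cholesterol, subject.hdl):
        if v is None or not math.isfinite(v):
            return NotApplicable("missing_lipids")
    lo, hi = _SCORE2["sbp_range"]
    if not (lo <= subject.office_sbp <= hi):
        return NotApplicable("sbp_range")
    if subject.age < 70:
        return 100.0 * _score2_young(subject, region)
    return 100.0 * _score2_op(subject, region)


# --------------------------------------------------------------------------
# Framingham general CVD risk
# --------------------------------------------------------------------------

def framingham(subject: SubjectProfile) -> RiskValue:
    """Framingham general-CVD 10-year risk, % (lipid-based Cox model)."""
    needed = (subject.age, subject.total_cholesterol, subject.hdl,
              subject.office_sbp)
    if any(v is None or not math.isfinite(v) or v <= 0 for v in needed):
        return NotApplicable("missing_input")
    tab = _FRAMINGHAM
    c = tab["coefficients"][subject.sex]
    tc_mgdl = subject.total_cholesterol * MGDL_PER_MMOL
    hdl_mgdl = subject.hdl * MGDL_PER_MMOL
    sbp_coef = (c["ln_sbp_treated"] if subject.antihypertensive_treatment
                else c["ln_sbp_untreated"])
    lp = (c["ln_age"] * math.log(subject.age)
          + c["ln_total_cholesterol"] * math.log(tc_mgdl)
          + c["ln_hdl"] * math.log(hdl_mgdl)
          + sbp_coef * math.log(subject.office_sbp)
          + c["smoking"] * (1.0 if subject.current_smoking else 0.0)
          + c["diabetes"] * (1.0 if subject.diabetes else 0.0))
    risk = 1.0 - tab["baseline_survival"][subject.sex] ** math.exp(
        lp - tab["mean_linear_predictor"][subject.sex])
    return 100.0 * risk


def cap_framingham(risk_pct: float) -> float:
    """Display cap: values above 30 % are approximated to 31 %."""
    return FRAMINGHAM_CAP_PCT if risk_pct > 30.0 else risk_pct


# --------------------------------------------------------------------------
# aggregate
# --------------------------------------------------------------------------

@dataclass
class RiskResult:
    score2_pct: RiskValue
    framingham_pct: RiskValue
    framingham_capped_pct: RiskValue
    egfr: float
    ldl: RiskValue
    osa_class: str


def assess(subject: SubjectProfile, region: str = "moderate") -> RiskResult:
    """All derived clinical variables and risk scores for one subject."""
    fram = framingham(subject)
    return RiskResult(
        score2_pct=score2(subject, region),
        framingham_pct=fram,
        framingham_capped_pct=(cap_framingham(fram)
                               if isinstance(fram, float) else fram),
        egfr=egfr_ckdepi2021(subject.creatinine, subject.age, subject.sex),
        ldl=friedewald_ldl(subject.total_cholesterol, subject.hdl,
                           subject.triglycerides),
        osa_class=classify_osa(subject.ahi),
    )
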