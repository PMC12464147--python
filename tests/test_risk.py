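"""Risk scores and derived labs against published oracles."""

import dataclasses

import pytest

import nocturne as nt
from nocturne.risk import NotApplicable


def profile(**kw):
    base = dict(id="X", age=55.0, sex="male", height=175.0, weight=86.0,
                bmi=28.1, smoking_history=False, current_smoking=False,
                diabetes=False, antihypertensive_treatment=False,
                total_cholesterol=5.5, hdl=1.3, triglycerides=1.5,
                creatinine=80.0, ahi=8.0, office_sbp=140.0, office_dbp=85.0)
    base.update(kw)
    return nt.SubjectProfile(**base)


# --------------------------------------------------------------------------
# Friedewald LDL
# --------------------------------------------------------------------------

def test_friedewald():
    assert nt.friedewald_ldl(5.30, 1.32, 1.54) == pytest.approx(3.28, abs=0.001)
    assert nt.friedewald_ldl(5.0, 1.2, 0.0) == pytest.approx(3.8)
    na = nt.friedewald_ldl(5.0, 1.2, 5.0)
    assert isinstance(na, NotApplicable) and na.reason == "hypertriglyceridemia"
    with pytest.raises(ValueError):
        nt.friedewald_ldl(-1.0, 1.0, 1.0)


# --------------------------------------------------------------------------
# CKD-EPI 2021 eGFR
# --------------------------------------------------------------------------

def test_egfr_reference_values():
    # reference calculator values for Scr 0.70 / 0.90 mg/dl at age 50
    assert nt.egfr_ckdepi2021(61.9, 50.0, "female") == pytest.approx(105.0, abs=1.0)
    assert nt.egfr_ckdepi2021(79.6, 50.0, "male") == pytest.approx(104.0, abs=1.0)


def test_egfr_monotone_in_creatinine():
    for sex in ("male", "female"):
        vals = [nt.egfr_ckdepi2021(c, 60.0, sex) for c in (40, 60, 90, 130, 200)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


# --------------------------------------------------------------------------
# SCORE2 / SCORE2-OP
# --------------------------------------------------------------------------

def test_score2_eligibility_rules():
    assert nt.score2(profile(diabetes=True)).reason == "diabetes"
    assert nt.score2(profile(age=39.0)).reason == "age_range"
    assert nt.score2(profile(age=90.0)).reason == "age_range"
    assert nt.score2(profile(office_sbp=95.0)).reason == "sbp_range"
    assert nt.score2(profile(total_cholesterol=float("nan"))).reason == "missing_lipids"


def test_score2_chart_cells():
    # moderate-risk-region chart cells (published charts print integers)
    male50 = profile(age=50.0, current_smoking=True, smoking_history=True,
                     total_cholesterol=6.3, hdl=1.4, office_sbp=140.0)
    assert nt.score2(male50) == pytest.approx(8.0, abs=1.0)
    female65 = profile(age=65.0, sex="female", total_cholesterol=5.0,
                       hdl=1.5, office_sbp=120.0)
    assert nt.score2(female65) == pytest.approx(5.0, abs=1.0)


def test_score2_op_branch_is_used_and_plausible():
    older = profile(age=75.0, office_sbp=150.0, total_cholesterol=5.9, hdl=1.4)
    risk = nt.score2(older)
    assert isinstance(risk, float)
    # published older-person charts put a 75-y non-smoking male around 15-25 %
    assert 10.0 < risk < 30.0
    # continuity: just below the age split the younger algorithm applies
    younger = nt.score2(dataclasses.replace(older, age=69.0))
    assert isinstance(younger, float) and younger < risk


@pytest.mark.parametrize("field,low,high", [
    ("age", 45.0, 60.0),
    ("office_sbp", 110.0, 170.0),
])
def test_risk_monotone_in_age_and_sbp(field, low, high):
    lo = nt.score2(profile(**{field: low}))
    hi = nt.score2(profile(**{field: high}))
    assert hi >= lo
    flo = nt.framingham(profile(**{field: low}))
    fhi = nt.framingham(profile(**{field: high}))
    assert fhi >= flo


def test_smoking_increases_both_scores():
    s = profile(current_smoking=True, smoking_history=True)
    n = profile()
    assert nt.score2(s) > nt.score2(n)
    assert nt.framingham(s) > nt.framingham(n)


# --------------------------------------------------------------------------
# Framingham general CVD
# --------------------------------------------------------------------------

def test_framingham_published_worked_example():
    # 61-y woman, TC 180 mg/dl, HDL 47 mg/dl, untreated SBP 124, smoker,
    # no diabetes -> 10.48 % in the source publication
    mgdl = 38.67
    subj = profile(age=61.0, sex="female", total_cholesterol=180.0 / mgdl,
                   hdl=47.0 / mgdl, office_sbp=124.0,
                   current_smoking=True, smoking_history=True)
    assert nt.framingham(subj) == pytest.approx(10.48, abs=0.1)


def test_framingham_missing_input_and_cap():
    na = nt.framingham(profile(total_cholesterol=float("nan")))
    assert isinstance(na, NotApplicable) and na.reason == "missing_input"
    assert nt.cap_framingham(34.0) == 31.0
    assert nt.cap_framingham(nt.cap_framingham(34.0)) == 31.0   # idempotent
    assert nt.cap_framingham(30.0) == 30.0
    assert nt.cap_framingham(12.3) == 12.3


# --------------------------------------------------------------------------
# OSA classes
# --------------------------------------------------------------------------

@pytest.mark.parametrize("ahi,cls", [
    (0.0, "none"), (4.9, "none"), (5.0, "mild"), (14.9, "mild"),
    (15.0, "moderate"), (29.9, "moderate"), (30.0, "severe"), (80.0, "severe"),
])
def test_osa_classes_partition(ahi, cls):
    assert nt.classify_osa(ahi) == cls


def test_osa_negative_rejected():
    with pytest.raises(ValueError):
        nt.classify_osa(-0.1)


def test_assess_aggregates(subject):
    p, _ = subject
    rr = nt.assess(p)
    assert rr.egfr > 0
    assert rr.osa_class in {"none", "mild", "moderate", "severe"}
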