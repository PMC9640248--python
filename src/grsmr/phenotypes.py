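"""Derivation of analysis-ready exposures and kidney outcomes.

Blood pressure is the mean of the two seated readings taken at recruitment,
with +15 mmHg (systolic) or +10 mmHg (diastolic) added for participants on
antihypertensive medication — the conventional correction that approximately
restores the underlying untreated pressure.

Kidney function is the CKD-EPI estimated glomerular filtration rate computed
from both serum creatinine and serum cystatin C (eGFRcys-cr).  Clinical
categories follow standard cut-points: eGFR on {<45 or kidney replacement
therapy, 45–60, 60–90 (reference), 90–120, >=120} mL/min/1.73m2, with
>=120 taken as evidence of glomerular hyperfiltration; uACR on {<3
(reference), 3–30, >=30} mg/mmol.  Chronic kidney disease (CKD) is the
composite of kidney replacement therapy, eGFR<60, or uACR>=3.  All interval
cut-points are closed on the left (>=) and open on the right.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "process_bp",
    "egfr_cr_cys",
    "egfr_cr",
    "creatinine_cystatin_for_egfr",
    "classify_egfr",
    "classify_uacr",
    "ckd_composite",
    "derive_outcomes",
    "EGFR_CATEGORIES",
    "UACR_CATEGORIES",
    "EGFR_REFERENCE",
    "UACR_REFERENCE",
]

EGFR_CATEGORIES = ["KRT_or_lt45", "45to60", "60to90_ref", "90to120", "ge120"]
UACR_CATEGORIES = ["lt3_ref", "3to30", "ge30"]
EGFR_REFERENCE = "60to90_ref"
UACR_REFERENCE = "lt3_ref"

# Treatment corrections, mmHg added to measured values of treated participants.
TREATED_OFFSET = {"SBP": 15.0, "DBP": 10.0}

# CKD-EPI creatinine–cystatin C equation (combined eGFRcys-cr).
# kappa: sex-specific creatinine knot (mg/dL); alpha: sex-specific exponent
# below the knot.  Cystatin knot 0.8 mg/L.  Race coefficient intentionally
# omitted (single-ancestry cohort).
_EGFR_SCALE = 135.0
_KAPPA = {0: 0.7, 1: 0.9}  # 0 = female, 1 = male
_ALPHA = {0: -0.248, 1: -0.207}
_CR_HIGH_EXP = -0.601
_CYS_KNOT = 0.8
_CYS_LOW_EXP = -0.375
_CYS_HIGH_EXP = -0.711
_AGE_FACTOR = 0.995
_FEMALE_MULT = 0.969


def process_bp(reading1, reading2, treated, trait: str):
    """Mean of the two BP readings, +15/+10 mmHg if on antihypertensives.

    Parameters are scalars or aligned arrays; ``trait`` is ``"SBP"`` or
    ``"DBP"``.  Non-positive or missing readings raise ``ValueError`` for
    scalars; for arrays they yield NaN (the participant is excluded
    downstream).
    """
    if trait not in TREATED_OFFSET:
        raise ValueError(f"trait must be 'SBP' or 'DBP', got {trait!r}")
    r1 = np.asarray(reading1, dtype=float)
    r2 = np.asarray(reading2, dtype=float)
    tr = np.asarray(treated, dtype=bool)
    bad = ~(np.nan_to_num(r1, nan=-1) > 0) | ~(np.nan_to_num(r2, nan=-1) > 0)
    if bad.ndim == 0:
        if bad:
            raise ValueError("BP readings must be positive and non-missing")
        return float((r1 + r2) / 2.0 + TREATED_OFFSET[trait] * tr)
    out = (r1 + r2) / 2.0 + TREATED_OFFSET[trait] * tr
    out = np.where(bad, np.nan, out)
    return out


def egfr_cr_cys(scr, scys, age, sex):
    """CKD-EPI eGFR from serum creatinine (mg/dL) and cystatin C (mg/L).

    ``sex`` is coded 0 = female, 1 = male.  Returns mL/min/1.73m2.
    Strictly decreasing in creatinine, cystatin C and age.
    """
    scr = np.asarray(scr, dtype=float)
    scys = np.asarray(scys, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if np.any(np.nan_to_num(scr, nan=-1) <= 0) or np.any(np.nan_to_num(scys, nan=-1) <= 0):
        raise ValueError("serum creatinine and cystatin C must be positive")
    male = np.asarray(sex, dtype=float) >= 0.5
    kappa = np.where(male, _KAPPA[1], _KAPPA[0])
    alpha = np.where(male, _ALPHA[1], _ALPHA[0])
    cr = scr / kappa
    cys = scys / _CYS_KNOT
    egfr = (
        _EGFR_SCALE
        * np.minimum(cr, 1.0) ** alpha
        * np.maximum(cr, 1.0) ** _CR_HIGH_EXP
        * np.minimum(cys, 1.0) ** _CYS_LOW_EXP
        * np.maximum(cys, 1.0) ** _CYS_HIGH_EXP
        * _AGE_FACTOR ** age
        * np.where(male, 1.0, _FEMALE_MULT)
    )
    if egfr.ndim == 0:
        return float(egfr)
    return egfr


def egfr_cr(scr, age, sex):
    """CKD-EPI eGFR from serum creatinine alone (mg/dL), mL/min/1.73m2.

    Secondary equation; the primary analysis uses the combined
    creatinine–cystatin form.  Race term omitted.
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(np.nan_to_num(scr, nan=-1) <= 0):
        raise ValueError("serum creatinine must be positive")
    male = np.asarray(sex, dtype=float) >= 0.5
    kappa = np.where(male, 0.9, 0.7)
    alpha = np.where(male, -0.411, -0.329)
    cr = scr / kappa
    egfr = (
        141.0
        * np.minimum(cr, 1.0) ** alpha
        * np.maximum(cr, 1.0) ** -1.209
        * 0.993 ** age
        * np.where(male, 1.0, 1.018)
    )
    if egfr.ndim == 0:
        return float(egfr)
    return egfr


def creatinine_cystatin_for_egfr(egfr, age, sex):
    """Invert the eGFR equation along the ray scr = kappa*t, scys = 0.8*t.

    Produces a (creatinine, cystatin) pair whose eGFR equals the requested
    value for the given age and sex.  Used by the synthetic cohort generator;
    the parametrization keeps both analytes on the same relative displacement
    from their knots so the inverse is closed-form and unique.
    """
    egfr = np.asarray(egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    male = np.asarray(sex, dtype=float) >= 0.5
    if np.any(egfr <= 0):
        raise ValueError("eGFR must be positive")
    kappa = np.where(male, _KAPPA[1], _KAPPA[0])
    alpha = np.where(male, _ALPHA[1], _ALPHA[0])
    c = _EGFR_SCALE * _AGE_FACTOR ** age * np.where(male, 1.0, _FEMALE_MULT)
    v = egfr / c
    # t <= 1 branch: egfr = c * t^(alpha + cys_low_exp)  (v >= 1)
    # t >= 1 branch: egfr = c * t^(cr_high + cys_high)   (v <= 1)
    low_exp = alpha + _CYS_LOW_EXP
    high_exp = _CR_HIGH_EXP + _CYS_HIGH_EXP
    with np.errstate(invalid="ignore"):
        t = np.where(v >= 1.0, v ** (1.0 / low_exp), v ** (1.0 / high_exp))
    scr = kappa * t
    scys = _CYS_KNOT * t
    return scr, scys


def classify_egfr(egfr, krt):
    """Assign the clinical eGFR category; KRT overrides into the lowest.

    Missing eGFR without KRT yields the missing marker ``None`` (participant
    flagged for exclusion upstream).
    """
    egfr = np.asarray(egfr, dtype=float)
    krt = np.asarray(krt, dtype=bool)
    scalar = egfr.ndim == 0
    egfr = np.atleast_1d(egfr)
    krt = np.atleast_1d(krt)
    cat = np.full(egfr.shape, None, dtype=object)
    cat[(egfr >= 120)] = "ge120"
    cat[(egfr >= 90) & (egfr < 120)] = "90to120"
    cat[(egfr >= 60) & (egfr < 90)] = "60to90_ref"
    cat[(egfr >= 45) & (egfr < 60)] = "45to60"
    cat[(egfr < 45)] = "KRT_or_lt45"
    cat[krt] = "KRT_or_lt45"
    if scalar:
        return cat[0]
    return pd.Categorical(cat, categories=EGFR_CATEGORIES)


def classify_uacr(uacr):
    """Assign the uACR category (mg/mmol); cut-points at 3 and 30, closed-left."""
    uacr = np.asarray(uacr, dtype=float)
    if np.any(np.nan_to_num(uacr, nan=0.0) < 0):
        raise ValueError("uACR must be non-negative")
    scalar = uacr.ndim == 0
    uacr = np.atleast_1d(uacr)
    cat = np.full(uacr.shape, None, dtype=object)
    cat[uacr < 3.0] = "lt3_ref"
    cat[(uacr >= 3.0) & (uacr < 30.0)] = "3to30"
    cat[uacr >= 30.0] = "ge30"
    cat[np.isnan(uacr)] = None
    if scalar:
        return cat[0]
    return pd.Categorical(cat, categories=UACR_CATEGORIES)


def ckd_composite(egfr, uacr, krt):
    """CKD flag: kidney replacement therapy, eGFR<60, or uACR>=3."""
    egfr = np.asarray(egfr, dtype=float)
    uacr = np.asarray(uacr, dtype=float)
    krt = np.asarray(krt, dtype=bool)
    out = krt | (egfr < 60.0) | (uacr >= 3.0)
    if out.ndim == 0:
        return bool(out)
    return out


def derive_outcomes(pheno: pd.DataFrame, equation: str = "cr_cys") -> pd.DataFrame:
    """Derive adjusted BP, eGFR and categorical kidney outcomes for a cohort.

    ``pheno`` is a raw phenotype table (one row per participant) with the
    column dictionary produced by the synthetic generator (or equivalent real
    data).  Returns a new frame indexed like ``pheno`` with: sbp_adj,
    dbp_adj, egfr, egfr_category, uacr_category, ckd, aki and an
    ``exclude`` flag for rows with missing required inputs.

    ``equation`` selects the eGFR formula: ``"cr_cys"`` (combined
    creatinine–cystatin, the primary choice) or ``"cr"`` (creatinine only).
    """
    if equation not in ("cr_cys", "cr"):
        raise ValueError(f"unknown eGFR equation {equation!r}")
    out = pd.DataFrame(index=pheno.index)
    treated = pheno["on_antihypertensive"].astype(bool).to_numpy()
    out["sbp_adj"] = process_bp(
        pheno["sbp_reading1"].to_numpy(), pheno["sbp_reading2"].to_numpy(), treated, "SBP"
    )
    out["dbp_adj"] = process_bp(
        pheno["dbp_reading1"].to_numpy(), pheno["dbp_reading2"].to_numpy(), treated, "DBP"
    )
    if equation == "cr_cys":
        out["egfr"] = egfr_cr_cys(
            pheno["serum_creatinine"].to_numpy(),
            pheno["serum_cystatin_c"].to_numpy(),
            pheno["age"].to_numpy(),
            pheno["sex"].to_numpy(),
        )
    else:
        out["egfr"] = egfr_cr(
            pheno["serum_creatinine"].to_numpy(),
            pheno["age"].to_numpy(),
            pheno["sex"].to_numpy(),
        )
    krt = pheno["krt"].astype(bool).to_numpy()
    out["egfr_category"] = classify_egfr(out["egfr"].to_numpy(), krt)
    out["uacr_category"] = classify_uacr(pheno["uacr"].to_numpy())
    out["ckd"] = ckd_composite(out["egfr"].to_numpy(), pheno["uacr"].to_numpy(), krt)
    out["aki"] = pheno["aki_hosp"].astype(bool).to_numpy()
    out["exclude"] = (
        out["sbp_adj"].isna()
        | out["dbp_adj"].isna()
        | (out["egfr_category"].isna() & ~krt)
        | out["uacr_category"].isna()
        | pheno[["age", "sex", "bmi"]].isna().any(axis=1)
    )
    return out
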