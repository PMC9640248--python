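"""Conventional cross-sectional associations of measured BP with kidney outcomes.

Binary (and multinomial) logistic regressions of each outcome on measured,
treatment-adjusted BP, adjusted for the standard confounder set: age, sex,
region, education, deprivation (fifths), smoking, alcohol use, physical
activity, diabetes, and BMI (fifths).  Because a single clinic measurement
is a noisy proxy for usual BP, the fitted log-odds per mmHg are corrected
for regression dilution by dividing the estimate and its confidence limits
by the regression-dilution ratio (RDR) — the slope of a resurvey
measurement on the baseline measurement among resurveyed participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .onesample import MREstimate

__all__ = [
    "RegressionDilution",
    "confounder_design",
    "fit_conventional",
    "estimate_rdr",
    "correct_dilution",
]

CATEGORICAL_CONFOUNDERS = ("region", "education", "alcohol", "physical_activity")
BINARY_CONFOUNDERS = ("sex", "smoking", "diabetes")
FIFTH_CONFOUNDERS = ("townsend", "bmi")


@dataclass
class RegressionDilution:
    trait: str
    ratio: float
    n_resurvey: int

    def __post_init__(self):
        if not np.isfinite(self.ratio):
            raise ValueError("regression-dilution ratio must be finite")
        if self.ratio >= 1.05:
            warnings.warn(f"implausible regression-dilution ratio {self.ratio:.3f} (>= 1.05)",
                          RuntimeWarning)


def confounder_design(pheno: pd.DataFrame) -> pd.DataFrame:
    """Confounder design matrix (no constant): age, dummies for categorical
    confounders, fifths for deprivation and BMI."""
    cols = {"age": pheno["age"].astype(float)}
    for b in BINARY_CONFOUNDERS:
        cols[b] = pheno[b].astype(float)
    out = pd.DataFrame(cols, index=pheno.index)
    for cat in CATEGORICAL_CONFOUNDERS:
        d = pd.get_dummies(pheno[cat].astype("category"), prefix=cat, drop_first=True)
        out = pd.concat([out, d.astype(float)], axis=1)
    for col in FIFTH_CONFOUNDERS:
        fifths = pd.qcut(pheno[col].rank(method="first"), 5, labels=False)
        d = pd.get_dummies(fifths, prefix=f"{col}_fifth", drop_first=True)
        out = pd.concat([out, d.astype(float)], axis=1)
    return out


def fit_conventional(
    outcome,
    measured_bp,
    confounders: pd.DataFrame,
    *,
    trait: str = "sbp",
    unit: float = 10.0,
    outcome_name: str = "outcome",
) -> MREstimate:
    """Confounder-adjusted logistic regression of a binary outcome on
    measured BP; returns the estimate on the per-``unit``-mmHg scale."""
    y = np.asarray(outcome, dtype=float)
    bp = np.asarray(measured_bp, dtype=float)
    x = np.column_stack([np.ones_like(bp), bp, np.asarray(confounders, dtype=float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, x).fit(disp=0, maxiter=100)
    return MREstimate(
        method="conventional",
        outcome=outcome_name,
        trait=trait,
        unit=unit,
        beta=float(res.params[1] * unit),
        se=float(res.bse[1] * unit),
        n=len(y),
        n_cases=int(y.sum()),
    )


def fit_conventional_multinomial(
    category,
    measured_bp,
    confounders: pd.DataFrame,
    *,
    reference: str,
    trait: str = "sbp",
    unit: float = 10.0,
    outcome_name: str = "category",
) -> dict[str, MREstimate]:
    """Multinomial analogue mirroring the genetic category/reference scheme."""
    cat = pd.Categorical(category)
    levels = [c for c in cat.categories if (cat == c).sum() > 0]
    ordered = [reference] + [c for c in levels if c != reference]
    codes = pd.Categorical(cat, categories=ordered).codes
    keep = codes >= 0
    bp = np.asarray(measured_bp, dtype=float)
    x = np.column_stack([np.ones(keep.sum()), bp[keep], np.asarray(confounders, dtype=float)[keep]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MNLogit(codes[keep], x).fit(disp=0, maxiter=200, method="newton")
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    out = {}
    for k, name in enumerate(ordered[1:]):
        out[name] = MREstimate(
            method="conventional_multinomial",
            outcome=f"{outcome_name}:{name} vs {reference}",
            trait=trait,
            unit=unit,
            beta=float(params[1, k] * unit),
            se=float(bse[1, k] * unit),
            n=int(keep.sum()),
            n_cases=int((cat == name).sum()),
        )
    return out


def estimate_rdr(baseline, resurvey, *, trait: str = "sbp", min_pairs: int = 50) -> RegressionDilution:
    """Slope of resurvey BP on baseline BP among participants with both."""
    b = np.asarray(baseline, dtype=float)
    r = np.asarray(resurvey, dtype=float)
    ok = np.isfinite(b) & np.isfinite(r)
    if ok.sum() < min_pairs:
        raise ValueError(f"need >= {min_pairs} paired observations, got {int(ok.sum())}")
    x = sm.add_constant(b[ok])
    fit = sm.OLS(r[ok], x).fit()
    return RegressionDilution(trait=trait, ratio=float(fit.params[1]), n_resurvey=int(ok.sum()))


def correct_dilution(estimate: MREstimate, rdr: RegressionDilution) -> MREstimate:
    """Divide the log-odds estimate (and hence both CI limits) by the RDR."""
    if not rdr.ratio > 0:
        raise ValueError("regression-dilution ratio must be positive for correction")
    corrected = MREstimate(
        method=estimate.method + "+dilution_corrected",
        outcome=estimate.outcome,
        trait=estimate.trait,
        unit=estimate.unit,
        beta=estimate.beta / rdr.ratio,
        se=estimate.se / rdr.ratio,
        n=estimate.n,
        n_cases=estimate.n_cases,
        diagnostics={**estimate.diagnostics, "rdr": rdr.ratio, "n_resurvey": rdr.n_resurvey},
    )
    return corrected
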