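"""One-sample GRS Mendelian randomization on individual-level data.

The causal effect of BP on a binary kidney outcome is estimated by the
standard two-stage ratio construction: a logistic regression of the outcome
on the genetic risk score (with covariates age, age^2, sex, BMI, top 18
principal components and genotyping array) gives log-odds per score unit;
an internal linear calibration regression of the measured
(treatment-adjusted) exposure on the same score and covariates gives mmHg
per score unit; their ratio, scaled to 10 mmHg systolic or 5 mmHg
diastolic, is the reported log-odds ratio.  Categorical eGFR and uACR
outcomes use multinomial logistic regression against fixed reference
categories (eGFR 60–90, uACR <3).

The scaled standard error ignores first-stage sampling error by default
(appropriate for strong instruments; t-statistics of the calibration slope
are routinely in the hundreds here).  A delta-method option is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .grs import GRSResult

__all__ = [
    "MREstimate",
    "CovariateSet",
    "default_covariates",
    "calibrate_score",
    "fit_grs_outcome",
    "scale_to_exposure_units",
    "multinomial_mr",
    "multivariable_adjusted_mr",
    "subgroup_mr",
    "residualize_characteristic",
    "snp_exclusion_filter",
]

WEAK_CALIBRATION_T = 10.0


@dataclass
class MREstimate:
    """A causal-effect estimate on the odds-ratio scale."""

    method: str
    outcome: str
    trait: str
    unit: float                 # mmHg per reported contrast (10 SBP / 5 DBP)
    beta: float                 # log-odds per `unit` mmHg
    se: float
    n: int
    n_cases: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        lo = self.beta - 1.959964 * self.se
        hi = self.beta + 1.959964 * self.se
        return float(np.exp(lo)), float(np.exp(hi))

    @property
    def p(self) -> float:
        if self.se == 0:
            return float("nan")
        return float(2.0 * stats.norm.sf(abs(self.beta / self.se)))

    def as_dict(self) -> dict:
        lo, hi = self.ci
        return {
            "method": self.method,
            "outcome": self.outcome,
            "trait": self.trait,
            "unit_mmHg": self.unit,
            "or": self.odds_ratio,
            "ci_low": lo,
            "ci_high": hi,
            "p": self.p,
            "beta": self.beta,
            "se": self.se,
            "n": self.n,
            "n_cases": self.n_cases,
            **{f"diag_{k}": v for k, v in self.diagnostics.items() if np.isscalar(v)},
        }


class CovariateSet(pd.DataFrame):
    """Design covariates: age, age^2, sex, BMI, 18 PCs, array (no constant)."""


def default_covariates(pheno: pd.DataFrame, include_bmi: bool = True) -> pd.DataFrame:
    age_c = pheno["age"] - pheno["age"].mean()
    cols = {"age": age_c, "age2": age_c ** 2, "sex": pheno["sex"].astype(float)}
    if include_bmi:
        cols["bmi"] = pheno["bmi"].astype(float)
    for k in range(1, 19):
        cols[f"pc{k}"] = pheno[f"pc{k}"].astype(float)
    cols["array"] = pheno["array"].astype(float)
    return pd.DataFrame(cols, index=pheno.index)


@dataclass
class ScoreCalibration:
    """Linear regression of measured exposure on score (+covariates)."""

    beta: float     # mmHg per score unit
    se: float
    t: float
    trait: str

    @property
    def weak(self) -> bool:
        return abs(self.t) < WEAK_CALIBRATION_T


@dataclass
class GRSFit:
    beta: float     # log-odds per score unit
    se: float
    n: int
    n_cases: int
    converged: bool


def _design(score, covariates) -> np.ndarray:
    s = np.asarray(score.score if isinstance(score, GRSResult) else score, dtype=float)
    x = np.column_stack([np.ones_like(s), s])
    if covariates is not None and len(covariates.columns):
        x = np.column_stack([x, np.asarray(covariates, dtype=float)])
    return x


def calibrate_score(exposure, score, covariates=None, trait: str = "sbp") -> ScoreCalibration:
    """OLS of measured (treatment-adjusted) exposure on the score."""
    y = np.asarray(exposure, dtype=float)
    x = _design(score, covariates)
    fit = sm.OLS(y, x).fit()
    cal = ScoreCalibration(beta=float(fit.params[1]), se=float(fit.bse[1]), t=float(fit.tvalues[1]), trait=trait)
    if isinstance(score, GRSResult):
        score.scaling_beta = cal.beta
    return cal


def fit_grs_outcome(outcome, score, covariates=None, min_cases: int = 10) -> GRSFit:
    """Maximum-likelihood logistic fit of a binary outcome on the score."""
    y = np.asarray(outcome, dtype=float)
    n_cases = int(y.sum())
    if n_cases < min_cases or (len(y) - n_cases) < min_cases:
        raise ValueError(f"need >= {min_cases} cases and non-cases (got {n_cases}/{len(y) - n_cases})")
    x = _design(score, covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, x).fit(disp=0, maxiter=100)
        except np.linalg.LinAlgError:
            # quasi-separation can make the Newton Hessian singular; a
            # gradient-based optimizer still reaches the (finite) optimum
            res = sm.Logit(y, x).fit(disp=0, maxiter=500, method="lbfgs")
    if not res.mle_retvals.get("converged", False):
        warnings.warn("logistic fit did not converge (possible separation)", RuntimeWarning)
    return GRSFit(
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        n=len(y),
        n_cases=n_cases,
        converged=bool(res.mle_retvals.get("converged", False)),
    )


def scale_to_exposure_units(
    fit: GRSFit,
    calibration: ScoreCalibration,
    unit: float,
    *,
    outcome: str = "outcome",
    method: str = "grs_logistic",
    se_method: str = "ratio",
) -> MREstimate:
    """Convert per-score-unit log-odds to the per-10/per-5 mmHg scale.

    log-OR per unit = unit * beta_outcome / beta_exposure.  ``se_method``
    'ratio' scales the outcome SE only; 'delta' propagates first-stage error.
    """
    if calibration.beta == 0:
        raise ZeroDivisionError("calibration slope is zero")
    scale = unit / calibration.beta
    beta = fit.beta * scale
    if se_method == "delta":
        se = abs(scale) * np.sqrt(
            fit.se ** 2 + (fit.beta * calibration.se / calibration.beta) ** 2
        )
    else:
        se = fit.se * abs(scale)
    diag = {"beta_score_outcome": fit.beta, "beta_score_exposure": calibration.beta,
            "calibration_t": calibration.t}
    if calibration.weak:
        diag["weak_instrument_warning"] = True
        warnings.warn("weak score-exposure calibration (|t| < 10)", RuntimeWarning)
    return MREstimate(
        method=method, outcome=outcome, trait=calibration.trait, unit=unit,
        beta=float(beta), se=float(se), n=fit.n, n_cases=fit.n_cases, diagnostics=diag,
    )


def multinomial_mr(
    category,
    score,
    covariates,
    calibration: ScoreCalibration,
    unit: float,
    *,
    reference: str,
    outcome: str = "category",
    min_cases: int = 10,
) -> dict[str, MREstimate]:
    """Multinomial logistic MR: one scaled OR per non-reference category."""
    cat = pd.Categorical(category)
    levels = [c for c in cat.categories if (cat == c).sum() > 0]
    if reference not in levels:
        raise ValueError(f"reference category {reference!r} is empty or absent")
    ordered = [reference] + [c for c in levels if c != reference]
    skipped = [c for c in ordered[1:] if int((cat == c).sum()) < min_cases]
    ordered = [c for c in ordered if c not in skipped]
    out: dict[str, MREstimate] = {}
    scale = unit / calibration.beta
    if len(ordered) >= 2:
        codes = pd.Categorical(cat, categories=ordered).codes
        keep = codes >= 0
        x = _design(score, covariates)[keep]
        y = codes[keep]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(y, x).fit(disp=0, maxiter=200, method="newton")
        params = np.asarray(res.params)      # (k_exog, K-1)
        bse = np.asarray(res.bse)
    for k, name in enumerate(ordered[1:]):
        est = MREstimate(
            method="multinomial_grs",
            outcome=f"{outcome}:{name} vs {reference}",
            trait=calibration.trait,
            unit=unit,
            beta=float(params[1, k] * scale),
            se=float(bse[1, k] * abs(scale)),
            n=int(keep.sum()),
            n_cases=int((cat == name).sum()),
            diagnostics={"reference": reference},
        )
        out[name] = est
    for name in skipped:
        out[name] = MREstimate(
            method="multinomial_grs", outcome=f"{outcome}:{name} vs {reference}",
            trait=calibration.trait, unit=unit, beta=float("nan"), se=float("nan"),
            n=0, n_cases=int((cat == name).sum()),
            diagnostics={"not_estimable": True, "reference": reference},
        )
    return out


def compute_mediator_scores(
    dosages: pd.DataFrame, weights: pd.DataFrame, mediators=("bmi", "whr", "t2d")
) -> pd.DataFrame:
    """Predicted-mediator scores: weighted dosage sums using mediator betas."""
    ids = [v for v in weights["variant_id"] if v in dosages.columns]
    if len(ids) < 0.8 * len(weights):
        raise ValueError("mediator weights missing for >20% of SNPs")
    x = dosages[ids].to_numpy(dtype=float)
    w = weights.set_index("variant_id").loc[ids]
    out = {}
    for m in mediators:
        col = f"beta_{m}"
        if col not in w.columns:
            raise ValueError(f"mediator weight column {col!r} absent")
        out[f"score_{m}"] = x @ w[col].to_numpy(dtype=float)
    index = dosages["pid"] if "pid" in dosages.columns else dosages.index
    return pd.DataFrame(out, index=pd.Index(index, name="pid"))


def multivariable_adjusted_mr(
    outcome,
    score,
    covariates: pd.DataFrame,
    mediator_scores: pd.DataFrame,
    calibration: ScoreCalibration,
    unit: float,
    *,
    outcome_name: str = "outcome",
) -> MREstimate:
    """MR with predicted mediator scores (T2D/BMI/WHR) as extra covariates."""
    med = mediator_scores.reset_index(drop=True)
    cov = covariates.reset_index(drop=True)
    full = pd.concat([cov, med], axis=1)
    # drop constant mediator columns (collinear with the intercept)
    keep = [c for c in full.columns if np.nanstd(full[c].to_numpy(dtype=float)) > 0]
    fit = fit_grs_outcome(outcome, score, full[keep])
    est = scale_to_exposure_units(
        fit, calibration, unit, outcome=outcome_name, method="multivariable_grs"
    )
    est.diagnostics["mediators"] = list(med.columns)
    return est


def subgroup_mr(
    outcome,
    score,
    covariates: pd.DataFrame,
    grouping,
    calibration: ScoreCalibration,
    unit: float,
    *,
    ordered: bool = False,
    outcome_name: str = "outcome",
) -> tuple[dict, float]:
    """Stratum-specific scaled ORs plus an interaction p-value.

    For ordered groupings the interaction term is score x (numeric group
    code) — a 1-df trend test; otherwise a likelihood-ratio heterogeneity
    test on the full set of score x stratum terms.
    """
    g = pd.Categorical(grouping)
    levels = [c for c in g.categories if (g == c).sum() > 0]
    if len(levels) < 2:
        raise ValueError("subgroup analysis needs >= 2 strata")
    y = np.asarray(outcome, dtype=float)
    s = np.asarray(score.score if isinstance(score, GRSResult) else score, dtype=float)
    results = {}
    for lev in levels:
        sel = np.asarray(g == lev)
        fit = fit_grs_outcome(y[sel], s[sel], covariates.loc[sel].reset_index(drop=True))
        results[lev] = scale_to_exposure_units(
            fit, calibration, unit, outcome=f"{outcome_name}|{lev}", method="subgroup_grs"
        )
    x0 = _design(s, covariates)
    dummies = pd.get_dummies(g, drop_first=True).to_numpy(dtype=float)
    x_main = np.column_stack([x0, dummies])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if ordered:
            codes = g.codes.astype(float)
            x_int = np.column_stack([x_main, s * codes])
            res = sm.Logit(y, x_int).fit(disp=0, maxiter=100)
            p_int = float(res.pvalues[-1])
        else:
            inter = dummies * s[:, None]
            x_int = np.column_stack([x_main, inter])
            res1 = sm.Logit(y, x_int).fit(disp=0, maxiter=100)
            res0 = sm.Logit(y, x_main).fit(disp=0, maxiter=100)
            lr = 2.0 * (res1.llf - res0.llf)
            p_int = float(stats.chi2.sf(max(lr, 0.0), dummies.shape[1]))
    return results, p_int


def residualize_characteristic(characteristic, score) -> np.ndarray:
    """Remove the genetic (score-predicted) contribution from a characteristic.

    Returns characteristic - gamma_hat * score with gamma_hat from OLS; the
    residual is exactly uncorrelated with the score (the OLS intercept is
    retained, so only the score-predicted part is subtracted).
    """
    c = np.asarray(characteristic, dtype=float)
    s = np.asarray(score.score if isinstance(score, GRSResult) else score, dtype=float)
    if len(c) < 3:
        raise ValueError("need n >= 3")
    x = np.column_stack([np.ones_like(s), s])
    gamma = np.linalg.lstsq(x, c, rcond=None)[0][1]
    return c - gamma * s


def prune_sparse_dummies(dummies: pd.DataFrame, outcome, min_cases: int = 5) -> pd.DataFrame:
    """Drop indicator columns whose level carries fewer than ``min_cases``
    outcome cases or non-cases (quasi-separation guard for adjustment sets)."""
    y = np.asarray(outcome, dtype=float)
    keep = []
    for col in dummies.columns:
        sel = dummies[col].to_numpy(dtype=float) > 0
        cases = y[sel].sum()
        if cases >= min_cases and (sel.sum() - cases) >= min_cases:
            keep.append(col)
    return dummies[keep]


def snp_exclusion_filter(weights: pd.DataFrame, exclusion_ids) -> tuple[pd.DataFrame, dict]:
    """Drop listed variant ids from a weight table; unknown ids are logged."""
    excl = set(exclusion_ids)
    known = excl & set(weights["variant_id"])
    unknown = sorted(excl - known)
    filtered = weights[~weights["variant_id"].isin(known)].reset_index(drop=True)
    log = {"n_removed": len(known), "n_unknown": len(unknown), "unknown_ids": unknown}
    return filtered, log
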