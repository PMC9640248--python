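"""Synthetic biobank cohorts for genetic-epidemiology method validation.

The generator emulates a middle-aged population cohort with:

* independent bi-allelic instruments in Hardy–Weinberg equilibrium, split
  into a systolic-BP set and a diastolic-BP set, with external-style weights
  (true per-allele effect plus estimation noise at a stated GWAS sample
  size);
* true ("usual") blood pressure built from age, sex, adiposity, the genetic
  score component and a correlated residual, scaled so the genetic scores
  explain the requested fraction of *measured* BP variance;
* duplicate baseline readings with independent within-person measurement
  error, tuned so the regression-dilution ratio of a resurvey reading on the
  baseline reading matches a requested target (default 0.60 systolic / 0.53
  diastolic); antihypertensive treatment assigned by a logistic model on
  true systolic BP and subtracting a fixed amount from the observed readings;
* a hierarchical latent kidney-outcome model: CKD is Bernoulli with a logit
  exactly linear in true SBP/10 and DBP/5, manifested as reduced eGFR,
  albuminuria, or both; glomerular hyperfiltration is drawn among non-CKD
  participants with its own SBP pathway, giving a U-shaped marginal
  BP–eGFR relation with both tails governed by recoverable parameters;
* optional direct-outcome (pleiotropic) SNP effects, balanced or
  directional with respect to the BP-raising allele, and optional
  "kidney" SNPs whose primary effect is on eGFR (reverse-pathway
  instruments for Steiger filtering);
* serum creatinine and cystatin C back-computed from each participant's
  latent eGFR so the analysis-side CKD-EPI derivation reproduces the
  intended kidney categories.

Causal parameters are specified on the scale the genetic analysis reports
(log-odds per 10 mmHg systolic / 5 mmHg diastolic).  Because a logistic
outcome marginalized over residual BP is attenuated relative to its
structural coefficient, the generator calibrates the structural liability
coefficients by Gauss–Hermite integration so the requested value is the
exact estimand of the covariate-adjusted, score-scaled estimator.  The
structural and requested (marginal) coefficients are both recorded in the
truth object.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .phenotypes import creatinine_cystatin_for_egfr

__all__ = ["SimConfig", "SimulationTruth", "simulate_variants", "simulate_cohort", "simulate_all"]

_GH_X, _GH_W = np.polynomial.hermite.hermgauss(80)
_GH_Z = math.sqrt(2.0) * _GH_X
_GH_P = _GH_W / math.sqrt(math.pi)


def _normal_mean_expit(mu: float, sigma: float) -> float:
    """E[expit(mu + sigma*Z)], Z standard normal (Gauss-Hermite, 80 nodes)."""
    return float(np.sum(expit(mu + sigma * _GH_Z) * _GH_P))


def _solve_intercept(prev: float, sigma: float) -> float:
    """Intercept alpha with E[expit(alpha + sigma*Z)] = prev."""
    return brentq(lambda a: _normal_mean_expit(a, sigma) - prev, -30.0, 10.0, xtol=1e-12)


def _logit_slope(mu: float, sigma: float) -> float:
    """d/dmu logit E[expit(mu + sigma*Z)]: local attenuation of a logistic
    coefficient after marginalizing a N(0, sigma^2) residual out of the
    linear predictor."""
    p = expit(mu + sigma * _GH_Z)
    f = float(np.sum(p * _GH_P))
    df = float(np.sum(p * (1.0 - p) * _GH_P))
    return df / (f * (1.0 - f))


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the cohort the analysis is designed for: ~46% male,
    mean age 57 (SD 8), measured SBP 141.7 (20.6) mmHg and DBP 84.6 (11.2)
    mmHg, 23% on antihypertensives, CKD prevalence 6.95% (2.5% reduced
    eGFR, 5.0% albuminuria), hyperfiltration 0.59%, AKI hospitalization
    3.3%, 219 SBP / 223 DBP instruments explaining 1.6% / 2.1% of measured
    BP variance, regression-dilution ratios 0.60 / 0.53, 5% resurveyed.
    """

    n_participants: int = 20_000
    n_snps_sbp: int = 219
    n_snps_dbp: int = 223
    maf_range: tuple[float, float] = (0.05, 0.5)
    instrument_r2_sbp: float = 0.016
    instrument_r2_dbp: float = 0.021

    # measured-BP moments and dilution targets
    sbp_mean: float = 141.7
    dbp_mean: float = 84.6
    sbp_measured_sd: float = 20.6
    dbp_measured_sd: float = 11.2
    rdr_sbp: float = 0.60
    rdr_dbp: float = 0.53
    measurement_error_sd_sbp: float | None = None  # per-reading mmHg; derived from rdr if None
    measurement_error_sd_dbp: float | None = None
    resid_corr: float = 0.6  # correlation of non-genetic SBP/DBP residuals

    # demographic effects on BP (per unit of the covariate)
    confounder_effects: dict = field(
        default_factory=lambda: {
            "age_sbp": 0.45, "sex_sbp": 4.0, "bmi_sbp": 0.8,
            "age_dbp": 0.10, "sex_dbp": 1.0, "bmi_dbp": 0.5,
            "bmi_ckd": 0.03,  # direct (non-BP) log-odds of CKD per kg/m2
        }
    )

    # causal effects on the reporting scale (GRS-identifiable marginals)
    causal_logor_per10_sbp: float = math.log(1.37)
    causal_logor_per5_dbp: float = math.log(1.19)
    hyperfiltration_logor_per10_sbp: float = math.log(1.49)
    aki_logor_per10_sbp: float = math.log(1.15)

    # outcome prevalences
    ckd_prevalence: float = 0.0695
    ckd_manifest_probs: tuple[float, float, float] = (0.283, 0.640, 0.077)  # reduced / albumin / both
    hyperfiltration_prevalence: float = 0.0059
    aki_prevalence: float = 0.0325
    krt_prob: float = 0.02  # among reduced-eGFR CKD

    egfr_class_means: tuple[float, float, float] = (95.0, 50.0, 125.0)  # normal / declining / hyper
    egfr_class_sds: tuple[float, float, float] = (10.0, 8.0, 5.0)

    # horizontal pleiotropy (direct CKD log-odds per effect allele)
    pleiotropy_fraction: float = 0.0
    pleiotropy_mode: str = "balanced"  # or "directional" (aligned with BP-raising allele)
    pleiotropy_effect: float = 0.004

    # reverse-pathway ("kidney") SNPs for Steiger filtering
    kidney_snp_fraction: float = 0.0
    kidney_egfr_effect: float = 1.5          # mL/min/1.73m2 per BP-raising allele (sign-aligned, negative on eGFR)
    kidney_ckd_logor_per_allele: float = 0.0225

    # mediator (BMI / WHR / T2D) genetics
    mediator_fraction: float = 0.0
    mediator_bmi_effect: float = 0.05   # kg/m2 per allele for mediator SNPs
    mediator_whr_effect: float = 0.003
    mediator_t2d_logor: float = 0.02

    # antihypertensive treatment
    treatment_prevalence: float = 0.231
    treatment_slope: float = 0.07       # logistic slope on true SBP, per mmHg
    treatment_effect_sbp: float = 15.0  # mmHg subtracted from observed readings
    treatment_effect_dbp: float = 10.0

    resurvey_fraction: float = 0.05
    gwas_n: int = 750_000
    exact_weights: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("instrument_r2_sbp", "instrument_r2_dbp"):
            r2 = getattr(self, name)
            if not (0.0 <= r2 < 1.0):
                raise ValueError(f"{name} must be in [0, 1); got {r2}")
        for name in (
            "pleiotropy_fraction", "kidney_snp_fraction", "mediator_fraction",
            "resurvey_fraction", "ckd_prevalence", "hyperfiltration_prevalence",
            "aki_prevalence", "treatment_prevalence", "krt_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]; got {v}")
        if self.pleiotropy_mode not in ("balanced", "directional"):
            raise ValueError("pleiotropy_mode must be 'balanced' or 'directional'")
        if abs(sum(self.ckd_manifest_probs) - 1.0) > 1e-6:
            raise ValueError("ckd_manifest_probs must sum to 1")

    # ---- derived variance bookkeeping (analytic, no data involved) ----

    @property
    def var_meas_sbp(self) -> float:
        return self.sbp_measured_sd ** 2

    @property
    def var_meas_dbp(self) -> float:
        return self.dbp_measured_sd ** 2

    @property
    def error_sd_sbp(self) -> float:
        """Per-reading measurement-error SD implied by the dilution target."""
        if self.measurement_error_sd_sbp is not None:
            return self.measurement_error_sd_sbp
        return math.sqrt(2.0 * self.var_meas_sbp * (1.0 - self.rdr_sbp))

    @property
    def error_sd_dbp(self) -> float:
        if self.measurement_error_sd_dbp is not None:
            return self.measurement_error_sd_dbp
        return math.sqrt(2.0 * self.var_meas_dbp * (1.0 - self.rdr_dbp))

    @property
    def var_true_sbp(self) -> float:
        """Variance of usual SBP (baseline measurement = mean of two readings)."""
        return self.var_meas_sbp - self.error_sd_sbp ** 2 / 2.0

    @property
    def var_true_dbp(self) -> float:
        return self.var_meas_dbp - self.error_sd_dbp ** 2 / 2.0

    @property
    def rdr_true_sbp(self) -> float:
        return self.var_true_sbp / self.var_meas_sbp

    @property
    def rdr_true_dbp(self) -> float:
        return self.var_true_dbp / self.var_meas_dbp

    # fixed demographic distributions
    AGE_MEAN, AGE_SD = 57.0, 8.0
    BMI_MEAN, BMI_SD = 27.4, 4.7
    WHR_MEAN, WHR_SD = 0.87, 0.09
    MALE_FRACTION = 0.465

    def _bp_component_vars(self) -> dict:
        ce = self.confounder_effects
        out = {}
        for trait in ("sbp", "dbp"):
            out[f"age_{trait}"] = (ce[f"age_{trait}"] * self.AGE_SD) ** 2
            out[f"sex_{trait}"] = ce[f"sex_{trait}"] ** 2 * self.MALE_FRACTION * (1 - self.MALE_FRACTION)
            out[f"bmi_{trait}"] = (ce[f"bmi_{trait}"] * self.BMI_SD) ** 2
        out["genetic_sbp"] = self.instrument_r2_sbp * self.var_meas_sbp
        out["genetic_dbp"] = self.instrument_r2_dbp * self.var_meas_dbp
        return out

    @property
    def resid_sd_sbp(self) -> float:
        v = self._bp_component_vars()
        resid = self.var_true_sbp - v["genetic_sbp"] - v["age_sbp"] - v["sex_sbp"] - v["bmi_sbp"]
        if resid <= 0:
            raise ValueError("infeasible configuration: non-genetic SBP variance exhausted")
        return math.sqrt(resid)

    @property
    def resid_sd_dbp(self) -> float:
        v = self._bp_component_vars()
        resid = self.var_true_dbp - v["genetic_dbp"] - v["age_dbp"] - v["sex_dbp"] - v["bmi_dbp"]
        if resid <= 0:
            raise ValueError("infeasible configuration: non-genetic DBP variance exhausted")
        return math.sqrt(resid)

    def bp_covariance(self) -> tuple[float, float, float]:
        """(Var SBP_true, Var DBP_true, Cov) of centred usual BP."""
        ce = self.confounder_effects
        cov = (
            ce["age_sbp"] * ce["age_dbp"] * self.AGE_SD ** 2
            + ce["sex_sbp"] * ce["sex_dbp"] * self.MALE_FRACTION * (1 - self.MALE_FRACTION)
            + ce["bmi_sbp"] * ce["bmi_dbp"] * self.BMI_SD ** 2
            + self.resid_corr * self.resid_sd_sbp * self.resid_sd_dbp
        )
        return self.var_true_sbp, self.var_true_dbp, cov


@dataclass
class SimulationTruth:
    """Ground-truth parameters stored alongside every simulated cohort."""

    variant_id: list
    trait: list                      # which GRS each SNP belongs to
    maf: np.ndarray
    true_beta_sbp: np.ndarray        # mmHg per effect allele
    true_beta_dbp: np.ndarray
    direct_ckd_logor: np.ndarray     # horizontal pleiotropy, per allele
    direct_egfr_effect: np.ndarray   # reverse-pathway effect, mL/min per allele
    is_kidney_snp: np.ndarray
    beta_bmi: np.ndarray
    beta_whr: np.ndarray
    beta_t2d: np.ndarray
    # causal coefficients, marginal = GRS-identifiable reporting scale
    ckd_logor_per10_sbp: float = 0.0
    ckd_logor_per5_dbp: float = 0.0
    hyper_logor_per10_sbp: float = 0.0
    aki_logor_per10_sbp: float = 0.0
    # structural liability coefficients actually used to draw outcomes
    ckd_logor_per10_sbp_structural: float = 0.0
    ckd_logor_per5_dbp_structural: float = 0.0
    hyper_logor_per10_sbp_structural: float = 0.0
    aki_logor_per10_sbp_structural: float = 0.0
    rdr_sbp: float = 1.0
    rdr_dbp: float = 1.0
    egfr_class_means: tuple = (95.0, 50.0, 125.0)
    egfr_class_sds: tuple = (10.0, 8.0, 5.0)
    var_true_sbp: float = 0.0
    var_true_dbp: float = 0.0

    def to_json(self, path) -> None:
        rec = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, tuple):
                v = list(v)
            rec[f.name] = v
        with open(path, "w") as fh:
            json.dump(rec, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            rec = json.load(fh)
        arrays = {
            "maf", "true_beta_sbp", "true_beta_dbp", "direct_ckd_logor",
            "direct_egfr_effect", "is_kidney_snp", "beta_bmi", "beta_whr", "beta_t2d",
        }
        for k in arrays:
            rec[k] = np.asarray(rec[k])
        for k in ("egfr_class_means", "egfr_class_sds"):
            rec[k] = tuple(rec[k])
        return cls(**rec)


_BASES = np.array(list("ACGT"))


def simulate_variants(config: SimConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw instrument MAFs, true per-allele effects and external-style weights.

    Per-trait effects are scaled so that sum_j 2 p_j (1-p_j) a_j^2 equals the
    requested fraction of measured BP variance exactly (analytically).
    Reported weights are the true effects plus Gaussian estimation noise with
    the GWAS-scale standard error, unless ``exact_weights`` is set.
    """
    rng = np.random.default_rng([config.seed, 101])
    n_s, n_d = config.n_snps_sbp, config.n_snps_dbp
    n = n_s + n_d
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=n)
    het = 2.0 * maf * (1.0 - maf)

    trait = np.array(["sbp"] * n_s + ["dbp"] * n_d)
    true_beta_sbp = np.zeros(n)
    true_beta_dbp = np.zeros(n)
    for tr, sl, r2, vmeas in (
        ("sbp", slice(0, n_s), config.instrument_r2_sbp, config.var_meas_sbp),
        ("dbp", slice(n_s, n), config.instrument_r2_dbp, config.var_meas_dbp),
    ):
        if sl.stop == sl.start:
            continue
        raw = rng.standard_normal(sl.stop - sl.start)
        scale = math.sqrt(r2 * vmeas / float(np.sum(het[sl] * raw ** 2)))
        if tr == "sbp":
            true_beta_sbp[sl] = raw * scale
        else:
            true_beta_dbp[sl] = raw * scale

    own_beta = np.where(trait == "sbp", true_beta_sbp, true_beta_dbp)
    own_sign = np.sign(own_beta)

    # direct-outcome (pleiotropic) effects on the CKD logit
    direct = np.zeros(n)
    if config.pleiotropy_fraction > 0:
        k = int(round(config.pleiotropy_fraction * n))
        idx = rng.choice(n, size=k, replace=False)
        if config.pleiotropy_mode == "directional":
            signs = own_sign[idx]
        else:
            signs = rng.choice([-1.0, 1.0], size=k)
        direct[idx] = config.pleiotropy_effect * signs

    # reverse-pathway kidney SNPs
    is_kidney = np.zeros(n, dtype=bool)
    egfr_eff = np.zeros(n)
    if config.kidney_snp_fraction > 0:
        k = int(round(config.kidney_snp_fraction * n))
        idx = rng.choice(n, size=k, replace=False)
        is_kidney[idx] = True
        egfr_eff[idx] = -config.kidney_egfr_effect * own_sign[idx]
        direct[idx] += config.kidney_ckd_logor_per_allele * own_sign[idx]

    # mediator genetics
    beta_bmi = np.zeros(n)
    beta_whr = np.zeros(n)
    beta_t2d = np.zeros(n)
    if config.mediator_fraction > 0:
        k = int(round(config.mediator_fraction * n))
        idx = rng.choice(n, size=k, replace=False)
        beta_bmi[idx] = config.mediator_bmi_effect * own_sign[idx]
        beta_whr[idx] = config.mediator_whr_effect * own_sign[idx]
        beta_t2d[idx] = config.mediator_t2d_logor * own_sign[idx]

    # alleles: unordered base pair per SNP.  Published instrument lists have
    # already resolved strand ambiguity, so palindromic (A/T, G/C) pairs are
    # not emitted at frequencies the harmonizer would have to drop.
    eff_idx = rng.integers(0, 4, size=n)
    shift = rng.integers(1, 4, size=n)
    oth_idx = (eff_idx + shift) % 4
    complement_idx = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT order
    ambiguous = (oth_idx == complement_idx[eff_idx]) & (maf >= 0.40)
    oth_idx[ambiguous] = (eff_idx[ambiguous] + 2) % 4  # never the complement
    effect_allele = _BASES[eff_idx]
    other_allele = _BASES[oth_idx]

    se_sbp = config.sbp_measured_sd / np.sqrt(config.gwas_n * het)
    se_dbp = config.dbp_measured_sd / np.sqrt(config.gwas_n * het)
    if config.exact_weights:
        w_sbp, w_dbp = true_beta_sbp.copy(), true_beta_dbp.copy()
    else:
        w_sbp = true_beta_sbp + rng.standard_normal(n) * se_sbp * (trait == "sbp")
        w_dbp = true_beta_dbp + rng.standard_normal(n) * se_dbp * (trait == "dbp")

    ids = [f"{t}_{i:04d}" for i, t in enumerate(trait)]
    table = pd.DataFrame(
        {
            "variant_id": ids,
            "trait": trait,
            "effect_allele": effect_allele,
            "other_allele": other_allele,
            "eaf": maf,
            "beta_sbp": w_sbp,
            "se_sbp": se_sbp,
            "beta_dbp": w_dbp,
            "se_dbp": se_dbp,
            "beta_bmi": beta_bmi,
            "beta_whr": beta_whr,
            "beta_t2d": beta_t2d,
        }
    )
    truth = SimulationTruth(
        variant_id=ids,
        trait=list(trait),
        maf=maf,
        true_beta_sbp=true_beta_sbp,
        true_beta_dbp=true_beta_dbp,
        direct_ckd_logor=direct,
        direct_egfr_effect=egfr_eff,
        is_kidney_snp=is_kidney,
        beta_bmi=beta_bmi,
        beta_whr=beta_whr,
        beta_t2d=beta_t2d,
        rdr_sbp=config.rdr_true_sbp,
        rdr_dbp=config.rdr_true_dbp,
        egfr_class_means=config.egfr_class_means,
        egfr_class_sds=config.egfr_class_sds,
        var_true_sbp=config.var_true_sbp,
        var_true_dbp=config.var_true_dbp,
    )
    return table, truth


def _calibrate_ckd(config: SimConfig) -> tuple[float, float, float]:
    """Solve (alpha, structural SBP per-10, structural DBP per-5) so that the
    requested marginal log-ORs are the covariate-conditional estimands and
    the population CKD prevalence matches the target."""
    bm_s = config.causal_logor_per10_sbp
    bm_d = config.causal_logor_per5_dbp
    vs, vd, cov = config.bp_covariance()
    ss, sd_, rho = config.resid_sd_sbp, config.resid_sd_dbp, config.resid_corr
    c_bmi = config.confounder_effects.get("bmi_ckd", 0.0)
    vb = config.BMI_SD ** 2
    cov_sb = config.confounder_effects["bmi_sbp"] * vb
    cov_db = config.confounder_effects["bmi_dbp"] * vb
    atten = 1.0
    alpha = 0.0
    for _ in range(60):
        u = (bm_s / atten) / 10.0
        v = (bm_d / atten) / 5.0
        sig_res = math.sqrt(
            max(u ** 2 * ss ** 2 + v ** 2 * sd_ ** 2 + 2 * u * v * rho * ss * sd_, 1e-12)
        )
        sig_tot = math.sqrt(
            max(
                u ** 2 * vs + v ** 2 * vd + 2 * u * v * cov
                + c_bmi ** 2 * vb + 2 * u * c_bmi * cov_sb + 2 * v * c_bmi * cov_db,
                1e-12,
            )
        )
        alpha = _solve_intercept(config.ckd_prevalence, sig_tot)
        mu0 = _solve_intercept(config.ckd_prevalence, sig_res)
        new = _logit_slope(mu0, sig_res)
        if abs(new - atten) < 1e-12:
            atten = new
            break
        atten = new
    return alpha, bm_s / atten, bm_d / atten


def _calibrate_single(prev: float, bm_per10: float, resid_sd: float, total_var: float) -> tuple[float, float]:
    """Same calibration for a single-exposure (SBP-only) logistic pathway."""
    atten = 1.0
    alpha = 0.0
    for _ in range(60):
        u = (bm_per10 / atten) / 10.0
        sig_res = max(abs(u) * resid_sd, 1e-9)
        sig_tot = max(abs(u) * math.sqrt(total_var), 1e-9)
        alpha = _solve_intercept(prev, sig_tot)
        mu0 = _solve_intercept(prev, sig_res)
        new = _logit_slope(mu0, sig_res)
        if abs(new - atten) < 1e-12:
            atten = new
            break
        atten = new
    return alpha, bm_per10 / atten


def _tn(rng, mean, sd, lower=-np.inf, upper=np.inf, size=None):
    """Truncated-normal draws with (possibly array) parameters, seeded via rng."""
    a = (np.asarray(lower, dtype=float) - mean) / sd
    b = (np.asarray(upper, dtype=float) - mean) / sd
    u = rng.uniform(size=size)
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def simulate_cohort(
    config: SimConfig, variants: pd.DataFrame, truth: SimulationTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort consistent with ``variants``/``truth``.

    Returns ``(phenotypes, dosages)``: a phenotype table (one row per
    participant, including ``true_``-prefixed oracle columns that the
    analysis must not use) and a participants x variants dosage matrix
    (int8, columns = variant ids).
    """
    if list(variants["variant_id"]) != list(truth.variant_id):
        raise ValueError("variant table and truth are inconsistent")
    rng = np.random.default_rng([config.seed, 202])
    n = config.n_participants
    maf = truth.maf
    j = len(maf)

    # sum of two Bernoulli(p) allele draws == Binomial(2, p) under HWE
    geno = (
        (rng.random((n, j)) < maf[None, :]).astype(np.int8)
        + (rng.random((n, j)) < maf[None, :]).astype(np.int8)
    )
    centred = geno - 2.0 * maf  # for latent pathways only

    # demographics
    age = np.clip(rng.normal(config.AGE_MEAN, config.AGE_SD, n), 40, 73)
    sex = (rng.uniform(size=n) < config.MALE_FRACTION).astype(np.int8)  # 1 = male
    bmi = rng.normal(config.BMI_MEAN, config.BMI_SD, n) + centred @ truth.beta_bmi
    whr = rng.normal(config.WHR_MEAN, config.WHR_SD, n) + centred @ truth.beta_whr
    pcs = rng.standard_normal((n, 18))
    array = (rng.uniform(size=n) < 0.1).astype(np.int8)
    region = rng.integers(0, 10, n)
    education = rng.integers(0, 5, n)
    townsend = rng.standard_normal(n)
    smoking = (rng.uniform(size=n) < 0.10).astype(np.int8)
    alcohol = rng.integers(0, 5, n)
    physical_activity = rng.integers(0, 3, n)
    hosp_count = rng.poisson(1.0, n)

    ce = config.confounder_effects
    g_sbp = centred @ truth.true_beta_sbp
    g_dbp = centred @ truth.true_beta_dbp
    z = rng.standard_normal((n, 2))
    eps_s = config.resid_sd_sbp * z[:, 0]
    eps_d = config.resid_sd_dbp * (
        config.resid_corr * z[:, 0] + math.sqrt(1 - config.resid_corr ** 2) * z[:, 1]
    )
    age_c = age - config.AGE_MEAN
    bmi_c = bmi - config.BMI_MEAN
    sex_c = sex - config.MALE_FRACTION
    sbp_true = config.sbp_mean + ce["age_sbp"] * age_c + ce["sex_sbp"] * sex_c + ce["bmi_sbp"] * bmi_c + g_sbp + eps_s
    dbp_true = config.dbp_mean + ce["age_dbp"] * age_c + ce["sex_dbp"] * sex_c + ce["bmi_dbp"] * bmi_c + g_dbp + eps_d

    # antihypertensive treatment: logistic on true SBP, lowers observed readings
    b_tr = config.treatment_slope
    a_tr = _solve_intercept(config.treatment_prevalence, b_tr * math.sqrt(config.var_true_sbp))
    treated = rng.uniform(size=n) < expit(a_tr + b_tr * (sbp_true - config.sbp_mean))

    err = rng.standard_normal((n, 4))
    sbp_r1 = sbp_true - config.treatment_effect_sbp * treated + config.error_sd_sbp * err[:, 0]
    sbp_r2 = sbp_true - config.treatment_effect_sbp * treated + config.error_sd_sbp * err[:, 1]
    dbp_r1 = dbp_true - config.treatment_effect_dbp * treated + config.error_sd_dbp * err[:, 2]
    dbp_r2 = dbp_true - config.treatment_effect_dbp * treated + config.error_sd_dbp * err[:, 3]

    resurvey = rng.uniform(size=n) < config.resurvey_fraction
    err_r = rng.standard_normal((n, 4))
    sbp_rs1 = np.where(resurvey, sbp_true - config.treatment_effect_sbp * treated + config.error_sd_sbp * err_r[:, 0], np.nan)
    sbp_rs2 = np.where(resurvey, sbp_true - config.treatment_effect_sbp * treated + config.error_sd_sbp * err_r[:, 1], np.nan)
    dbp_rs1 = np.where(resurvey, dbp_true - config.treatment_effect_dbp * treated + config.error_sd_dbp * err_r[:, 2], np.nan)
    dbp_rs2 = np.where(resurvey, dbp_true - config.treatment_effect_dbp * treated + config.error_sd_dbp * err_r[:, 3], np.nan)

    # ---- latent kidney outcomes ----
    alpha_ckd, bs_st, bd_st = _calibrate_ckd(config)
    sbp_c = sbp_true - config.sbp_mean
    dbp_c = dbp_true - config.dbp_mean
    lp_ckd = (
        alpha_ckd
        + bs_st * sbp_c / 10.0
        + bd_st * dbp_c / 5.0
        + ce.get("bmi_ckd", 0.0) * bmi_c
        + centred @ truth.direct_ckd_logor
    )
    ckd = rng.uniform(size=n) < expit(lp_ckd)

    manifest = np.full(n, "none", dtype=object)
    n_ckd = int(ckd.sum())
    if n_ckd:
        u = rng.uniform(size=n_ckd)
        p_r, p_a, _ = config.ckd_manifest_probs
        lab = np.where(u < p_r, "reduced", np.where(u < p_r + p_a, "albuminuria", "both"))
        manifest[ckd] = lab

    prev_h = config.hyperfiltration_prevalence / max(1.0 - config.ckd_prevalence, 1e-9)
    alpha_h, bh_st = _calibrate_single(
        prev_h, config.hyperfiltration_logor_per10_sbp, config.resid_sd_sbp, config.var_true_sbp
    )
    hyper = (~ckd) & (rng.uniform(size=n) < expit(alpha_h + bh_st * sbp_c / 10.0))

    m_n, m_d, m_h = config.egfr_class_means
    s_n, s_d, s_h = config.egfr_class_sds
    egfr = np.empty(n)
    reduced = (manifest == "reduced") | (manifest == "both")
    albumin_only = manifest == "albuminuria"
    normal = ~ckd & ~hyper
    egfr[reduced] = _tn(rng, m_d, s_d, upper=60.0, size=int(reduced.sum()))
    egfr[albumin_only] = _tn(rng, m_n, s_n, lower=60.0, upper=120.0, size=int(albumin_only.sum()))
    egfr[normal] = _tn(rng, m_n, s_n, lower=60.0, upper=120.0, size=int(normal.sum()))
    egfr[hyper] = _tn(rng, m_h, s_h, lower=120.0, size=int(hyper.sum()))
    egfr = egfr + centred @ truth.direct_egfr_effect
    egfr = np.clip(egfr, 2.0, None)

    krt = reduced & (rng.uniform(size=n) < config.krt_prob)

    albuminuric = (manifest == "albuminuria") | (manifest == "both")
    ln_uacr = np.empty(n)
    mu_alb = math.log(6.0) + 0.015 * sbp_c[albuminuric]
    ln_uacr[albuminuric] = _tn(rng, mu_alb, 0.9, lower=math.log(3.0), size=int(albuminuric.sum()))
    mu_non = math.log(1.0) + 0.005 * sbp_c[~albuminuric]
    ln_uacr[~albuminuric] = _tn(rng, mu_non, 0.8, upper=math.log(3.0), size=int((~albuminuric).sum()))
    uacr = np.exp(ln_uacr)

    alpha_aki, ba_st = _calibrate_single(
        config.aki_prevalence, config.aki_logor_per10_sbp, config.resid_sd_sbp, config.var_true_sbp
    )
    aki = rng.uniform(size=n) < expit(alpha_aki + ba_st * sbp_c / 10.0 + 0.10 * (hosp_count - 1.0))

    # comorbidity flags with a mild dependence on usual SBP (so GRS-fifth
    # gradients in prevalence emerge, as in real cohort descriptive tables)
    a_diab = _solve_intercept(0.052, 0.02 * math.sqrt(config.var_true_sbp))
    diabetes = rng.uniform(size=n) < expit(a_diab + 0.02 * sbp_c + centred @ truth.beta_t2d)
    a_vasc = _solve_intercept(0.058, 0.025 * math.sqrt(config.var_true_sbp))
    vascular = rng.uniform(size=n) < expit(a_vasc + 0.025 * sbp_c)

    scr, scys = creatinine_cystatin_for_egfr(egfr, age, sex)

    latent_class = np.where(hyper, "hyper", np.where(ckd, manifest, "normal"))
    pheno = pd.DataFrame(
        {
            "pid": np.arange(n),
            "sbp_reading1": sbp_r1,
            "sbp_reading2": sbp_r2,
            "dbp_reading1": dbp_r1,
            "dbp_reading2": dbp_r2,
            "on_antihypertensive": treated.astype(np.int8),
            "serum_creatinine": scr,
            "serum_cystatin_c": scys,
            "uacr": uacr,
            "krt": krt.astype(np.int8),
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "whr": whr,
            "diabetes": diabetes.astype(np.int8),
            "vascular_disease": vascular.astype(np.int8),
            "aki_hosp": aki.astype(np.int8),
            "hosp_count": hosp_count,
            "array": array,
            "region": region,
            "education": education,
            "townsend": townsend,
            "smoking": smoking,
            "alcohol": alcohol,
            "physical_activity": physical_activity,
            "resurvey": resurvey.astype(np.int8),
            "sbp_resurvey1": sbp_rs1,
            "sbp_resurvey2": sbp_rs2,
            "dbp_resurvey1": dbp_rs1,
            "dbp_resurvey2": dbp_rs2,
            # oracle truth columns (never used by the analysis modules)
            "true_sbp": sbp_true,
            "true_dbp": dbp_true,
            "true_egfr": egfr,
            "latent_ckd": ckd.astype(np.int8),
            "latent_class": latent_class,
        }
    )
    for k in range(18):
        pheno[f"pc{k + 1}"] = pcs[:, k]

    truth.ckd_logor_per10_sbp = config.causal_logor_per10_sbp
    truth.ckd_logor_per5_dbp = config.causal_logor_per5_dbp
    truth.hyper_logor_per10_sbp = config.hyperfiltration_logor_per10_sbp
    truth.aki_logor_per10_sbp = config.aki_logor_per10_sbp
    truth.ckd_logor_per10_sbp_structural = bs_st
    truth.ckd_logor_per5_dbp_structural = bd_st
    truth.hyper_logor_per10_sbp_structural = bh_st
    truth.aki_logor_per10_sbp_structural = ba_st

    dosages = pd.DataFrame(geno, columns=list(variants["variant_id"]))
    dosages.insert(0, "pid", np.arange(n))
    return pheno, dosages


def simulate_all(config: SimConfig):
    """Convenience wrapper: variants + truth + cohort in one call."""
    variants, truth = simulate_variants(config)
    pheno, dosages = simulate_cohort(config, variants, truth)
    return variants, truth, pheno, dosages
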