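"""Two-sample-style sensitivity estimators on per-SNP summary statistics.

Given per-variant exposure effects (beta_x, mmHg per allele) and outcome
effects (beta_y, log-odds per allele) with standard errors, the battery
comprises:

* Wald ratios beta_y/beta_x with first-order SE se_y/|beta_x|;
* inverse-variance-weighted (IVW) pooling (fixed effect) with Cochran's Q;
* MR-Egger: weighted regression of beta_y on beta_x with a free intercept
  (average directional pleiotropy), variants oriented so beta_x > 0;
* the weighted median: the causal estimate at 50% of cumulative normalized
  inverse-variance weight over ordered ratios, bootstrap SE;
* modified-Q outlier removal: iteratively drop the variant with the largest
  Q contribution while it exceeds a Bonferroni-corrected chi-square bound;
* MR-PRESSO: leave-one-out residual-sum-of-squares global test with a
  simulated null, per-variant outlier tests, distortion test, and an
  outlier-corrected IVW;
* Steiger filtering: drop variants explaining more outcome than exposure
  variance (likely reverse-direction instruments).

Estimates are on the per-unit-exposure scale (log-odds per mmHg); multiply
by 10 (SBP) or 5 (DBP) for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "per_snp_associations",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "modified_q_filter",
    "mr_presso",
    "steiger_filter",
    "SummaryMREstimate",
]

SUMMARY_COLUMNS = ["snp", "beta_exp", "se_exp", "beta_out", "se_out", "r2_exp", "r2_out"]


@dataclass
class SummaryMREstimate:
    method: str
    beta: float          # log-odds per unit exposure
    se: float
    n_snps: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.beta / self.se))) if self.se > 0 else float("nan")

    def odds_ratio(self, unit: float = 1.0) -> float:
        return float(np.exp(self.beta * unit))

    def ci(self, unit: float = 1.0) -> tuple[float, float]:
        lo = (self.beta - 1.959964 * self.se) * unit
        hi = (self.beta + 1.959964 * self.se) * unit
        return float(np.exp(lo)), float(np.exp(hi))


# ---------------------------------------------------------------------------
# deriving summary statistics from individual-level data


def _residualize(mat: np.ndarray, q: np.ndarray) -> np.ndarray:
    return mat - q @ (q.T @ mat)


def per_snp_associations(
    dosages: pd.DataFrame,
    exposure,
    outcome,
    covariates: pd.DataFrame | None = None,
    *,
    steiger_outcome=None,
    chunk: int = 64,
    exact: bool = False,
) -> pd.DataFrame:
    """Per-SNP exposure (linear) and outcome (logistic) associations.

    Exposure slopes use exact covariate-adjusted OLS via residualization
    (Frisch–Waugh).  Outcome slopes fit, per SNP, a logistic model with an
    intercept, the SNP, and the covariate-only linear predictor as offset —
    vectorized Newton iterations across SNPs; ``exact=True`` fits the full
    joint model per SNP with statsmodels instead (slow, for verification).
    r2 columns are squared correlations of the dosage with the exposure and
    with the outcome (or with ``steiger_outcome`` when supplied, e.g. a
    continuous kidney-function measure for Steiger filtering).
    Monomorphic SNPs are dropped and logged in ``df.attrs['dropped']``.
    """
    ids = [c for c in dosages.columns if c != "pid"]
    g_all = dosages[ids].to_numpy(dtype=float)
    e = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(e)
    poly = g_all.std(axis=0) > 0
    dropped = [ids[k] for k in np.where(~poly)[0]]
    ids = [ids[k] for k in np.where(poly)[0]]
    g_all = g_all[:, poly]

    if covariates is not None and len(covariates.columns):
        c = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    else:
        c = np.ones((n, 1))
    q, _ = np.linalg.qr(c)
    re = _residualize(e[:, None], q)[:, 0]
    p_cov = c.shape[1]

    # covariate-only logistic fit -> offset
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null = sm.Logit(y, c).fit(disp=0, maxiter=100)
    offset = c @ np.asarray(null.params)

    sv = steiger_outcome if steiger_outcome is not None else y
    sv = np.asarray(sv, dtype=float)
    sv_c = sv - sv.mean()
    e_c = e - e.mean()
    rows = []
    for start in range(0, len(ids), chunk):
        sl = slice(start, min(start + chunk, len(ids)))
        g = g_all[:, sl]
        rg = _residualize(g, q)
        gg = np.einsum("ij,ij->j", rg, rg)
        slope = (rg.T @ re) / gg
        resid = re[:, None] - rg * slope[None, :]
        sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - p_cov - 1)
        se_slope = np.sqrt(sigma2 / gg)

        if exact:
            b_out = np.empty(g.shape[1])
            se_out = np.empty(g.shape[1])
            for k in range(g.shape[1]):
                x = np.column_stack([c, g[:, k]])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
                b_out[k] = fit.params[-1]
                se_out[k] = fit.bse[-1]
        else:
            b_out, se_out = _offset_logistic(y, g, offset)

        gc = g - g.mean(axis=0)
        gsd = gc.std(axis=0)
        r2e = (np.einsum("ij,i->j", gc, e_c) / n / (gsd * e_c.std())) ** 2
        r2o = (np.einsum("ij,i->j", gc, sv_c) / n / (gsd * sv_c.std())) ** 2
        for k in range(g.shape[1]):
            rows.append(
                (ids[start + k], slope[k], se_slope[k], b_out[k], se_out[k], r2e[k], r2o[k])
            )
    out = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    out.attrs["dropped"] = dropped
    return out


def _offset_logistic(y: np.ndarray, g: np.ndarray, offset: np.ndarray, n_iter: int = 12):
    """Per-SNP (intercept, slope) logistic fits with a fixed offset,
    Newton-Raphson vectorized across SNPs."""
    n, j = g.shape
    a = np.zeros(j)
    b = np.zeros(j)
    gg = g * g
    h11 = h12 = h22 = det = None
    for _ in range(n_iter):
        eta = offset[:, None] + a[None, :] + g * b[None, :]
        p = expit(eta)
        w = p * (1.0 - p)
        r = y[:, None] - p
        g1 = r.sum(axis=0)
        g2 = np.einsum("ij,ij->j", r, g)
        h11 = w.sum(axis=0)
        h12 = np.einsum("ij,ij->j", w, g)
        h22 = np.einsum("ij,ij->j", w, gg)
        det = h11 * h22 - h12 ** 2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        da = (h22 * g1 - h12 * g2) / det
        db = (h11 * g2 - h12 * g1) / det
        a += da
        b += db
        if max(np.abs(da).max(initial=0), np.abs(db).max(initial=0)) < 1e-8:
            break
    se_b = np.sqrt(h11 / det)
    return b, se_b


def attach_external_weights(ss: pd.DataFrame, weights: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Use external instrument weights as the exposure side of the summary set.

    Replaces the in-sample ``beta_exp``/``se_exp`` by the weight table's
    per-allele effect and its (typically much smaller) GWAS standard error,
    the usual design when instruments come from an external consortium
    meta-analysis.  In-sample exposure betas at biobank scale have per-SNP
    F-statistics low enough that IVW/Egger suffer visible weak-instrument
    dilution; external weights restore the no-measurement-error regime.
    """
    w = weights.set_index("variant_id")
    out = ss.copy()
    out["beta_exp"] = w.loc[out["snp"], f"beta_{trait}"].to_numpy(dtype=float)
    out["se_exp"] = w.loc[out["snp"], f"se_{trait}"].to_numpy(dtype=float)
    return out


# ---------------------------------------------------------------------------
# estimators


def wald_ratio(beta_x: float, beta_y: float, se_y: float, *, floor: float = 0.0):
    """Per-SNP ratio estimate beta_y/beta_x with first-order SE se_y/|beta_x|."""
    if abs(beta_x) <= floor or beta_x == 0:
        raise ValueError("exposure effect below floor; variant should be excluded")
    return beta_y / beta_x, se_y / abs(beta_x)


def _ratios(ss: pd.DataFrame):
    bx = ss["beta_exp"].to_numpy(dtype=float)
    by = ss["beta_out"].to_numpy(dtype=float)
    sy = ss["se_out"].to_numpy(dtype=float)
    r = by / bx
    se = sy / np.abs(bx)
    return r, se


def ivw(ss: pd.DataFrame) -> SummaryMREstimate:
    """Fixed-effect inverse-variance-weighted mean of Wald ratios.

    Algebraically identical to the zero-intercept weighted regression of
    beta_out on beta_exp with weights 1/se_out^2.  Reports Cochran's Q.
    """
    if len(ss) < 1:
        raise ValueError("no SNPs")
    if len(ss) == 1:
        r, se = _ratios(ss)
        return SummaryMREstimate("wald_ratio_single", float(r[0]), float(se[0]), 1,
                                 {"fallback": "single_snp"})
    r, se = _ratios(ss)
    w = 1.0 / se ** 2
    beta = float(np.sum(w * r) / np.sum(w))
    se_ivw = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (r - beta) ** 2))
    p_q = float(stats.chi2.sf(q, len(r) - 1))
    return SummaryMREstimate("ivw", beta, se_ivw, len(r), {"Q": q, "Q_p": p_q, "Q_df": len(r) - 1})


def _orient(ss: pd.DataFrame) -> pd.DataFrame:
    """Flip variants so every exposure effect is positive (allele relabel)."""
    flip = np.sign(ss["beta_exp"].to_numpy(dtype=float))
    flip[flip == 0] = 1.0
    out = ss.copy()
    out["beta_exp"] = ss["beta_exp"] * flip
    out["beta_out"] = ss["beta_out"] * flip
    return out


def mr_egger(ss: pd.DataFrame) -> SummaryMREstimate:
    """MR-Egger: WLS of beta_out on beta_exp with free intercept.

    The slope is the pleiotropy-adjusted causal estimate; the intercept is
    the average directional pleiotropic effect per variant (exponentiate for
    an OR-scale intercept).  SEs use a multiplicative residual scale
    truncated below at 1; inference on J-2 t degrees of freedom.
    """
    if len(ss) < 3:
        raise ValueError("MR-Egger needs >= 3 SNPs")
    o = _orient(ss)
    bx = o["beta_exp"].to_numpy(dtype=float)
    by = o["beta_out"].to_numpy(dtype=float)
    w = 1.0 / o["se_out"].to_numpy(dtype=float) ** 2
    x = np.column_stack([np.ones_like(bx), bx])
    xtwx = x.T * w @ x
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    j = len(bx)
    scale = max(float(np.sum(w * resid ** 2) / (j - 2)), 1.0)
    cov = np.linalg.inv(xtwx) * scale
    se = np.sqrt(np.diag(cov))
    t_int = coef[0] / se[0]
    p_int = float(2.0 * stats.t.sf(abs(t_int), j - 2))
    # instrument-strength heterogeneity (weak-regression diagnostic)
    wbx = np.sum(w * bx) / np.sum(w)
    q_gx = float(np.sum((bx - wbx) ** 2 / o["se_exp"].to_numpy(dtype=float) ** 2))
    i2_gx = max(0.0, (q_gx - (j - 1)) / q_gx) if q_gx > 0 else 0.0
    diag = {
        "intercept": float(coef[0]),
        "intercept_se": float(se[0]),
        "intercept_p": p_int,
        "intercept_or": float(np.exp(coef[0])),
        "I2_GX": i2_gx,
        "scale": scale,
    }
    if i2_gx < 0.9:
        diag["weak_regression_warning"] = True
        warnings.warn("low spread in exposure effects (I2_GX < 0.9); Egger may be unreliable",
                      RuntimeWarning)
    return SummaryMREstimate("mr_egger", float(coef[1]), float(se[1]), j, diag)


def weighted_median(ss: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> SummaryMREstimate:
    """Weighted median of Wald ratios (linear interpolation at cumulative
    normalized inverse-variance weight 0.5); SE by parametric bootstrap."""
    if len(ss) < 3:
        raise ValueError("weighted median needs >= 3 SNPs")
    r, se = _ratios(ss)
    w = 1.0 / se ** 2
    est = _weighted_median_point(r, w)
    rng = np.random.default_rng(seed)
    bx = ss["beta_exp"].to_numpy(dtype=float)
    by = ss["beta_out"].to_numpy(dtype=float)
    sx = ss["se_exp"].to_numpy(dtype=float)
    sy = ss["se_out"].to_numpy(dtype=float)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + rng.standard_normal(len(bx)) * sx
        bys = by + rng.standard_normal(len(by)) * sy
        rs = bys / bxs
        ws = (bxs / sy) ** 2
        boots[b] = _weighted_median_point(rs, ws)
    return SummaryMREstimate("weighted_median", float(est), float(boots.std(ddof=1)), len(r),
                             {"n_boot": n_boot})


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r)
    r = r[order]
    w = w[order] / w.sum()
    cum = np.cumsum(w) - w / 2.0
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def modified_q_filter(ss: pd.DataFrame, alpha: float = 0.05):
    """Iterative outlier removal by per-SNP Q contributions.

    Removes the variant with the largest contribution q_j = w_j (r_j - IVW)^2
    while its chi-square(1) p-value, Bonferroni-corrected over the remaining
    variants, is below ``alpha``; the IVW fit is refreshed after each
    removal.  Returns (filtered stats, removed ids in order, refitted IVW).
    """
    if len(ss) < 3:
        raise ValueError("need >= 3 SNPs")
    current = ss.reset_index(drop=True)
    removed: list = []
    while True:
        if len(current) <= 1:
            raise RuntimeError("outlier removal would leave <= 1 SNP; aborting")
        fit = ivw(current)
        r, se = _ratios(current)
        w = 1.0 / se ** 2
        qj = w * (r - fit.beta) ** 2
        k = int(np.argmax(qj))
        p = stats.chi2.sf(qj[k], 1) * len(current)
        if alpha > 0 and p < alpha:
            removed.append(current.loc[k, "snp"])
            current = current.drop(index=k).reset_index(drop=True)
        else:
            break
    return current, removed, ivw(current)


def _loo_ivw_beta(bx, by, w):
    """Leave-one-out IVW slopes (zero-intercept WLS), vectorized."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(ss: pd.DataFrame, n_sim: int = 1000, seed: int = 0, outlier_alpha: float = 0.05):
    """MR-PRESSO global, outlier and distortion tests.

    The observed statistic is the weighted residual sum of squares of
    leave-one-out IVW predictions.  The null distribution is built by
    simulating per-SNP effects from their sampling distributions around the
    leave-one-out fits.  Per-SNP outlier p-values compare each observed
    residual with its simulated distribution (Bonferroni over SNPs); the
    distortion test contrasts the raw estimate with the outlier-corrected
    one against random pseudo-outlier sets.
    """
    if len(ss) < 4:
        raise ValueError("MR-PRESSO needs >= 4 SNPs")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    bx = ss["beta_exp"].to_numpy(dtype=float)
    by = ss["beta_out"].to_numpy(dtype=float)
    sx = ss["se_exp"].to_numpy(dtype=float)
    sy = ss["se_out"].to_numpy(dtype=float)
    j = len(bx)
    w = 1.0 / sy ** 2
    beta_loo = _loo_ivw_beta(bx, by, w)
    res_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(res_obs.sum())

    rss_sim = np.empty(n_sim)
    res_sim = np.empty((n_sim, j))
    for s in range(n_sim):
        bys = beta_loo * bx + rng.standard_normal(j) * sy
        bxs = bx + rng.standard_normal(j) * sx
        bl = _loo_ivw_beta(bxs, bys, w)
        res = w * (bys - bl * bxs) ** 2
        res_sim[s] = res
        rss_sim[s] = res.sum()
    global_p = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))

    # raw empirical proportion (may be zero) so Bonferroni can still flag
    outlier_p = np.sum(res_sim >= res_obs[None, :], axis=0) / n_sim
    outlier_p_bonf = np.minimum(outlier_p * j, 1.0)
    outliers = ss["snp"].to_numpy()[outlier_p_bonf < outlier_alpha]

    raw = ivw(ss)
    keep = ~ss["snp"].isin(outliers)
    corrected = ivw(ss[keep]) if keep.sum() >= 2 else raw
    distortion_p = float("nan")
    distortion_coef = float("nan")
    n_out = int((~keep).sum())
    if 0 < n_out < j - 1:
        diff_obs = raw.beta - corrected.beta
        diffs = np.empty(n_sim)
        idx = np.arange(j)
        for s in range(n_sim):
            drop = rng.choice(idx, size=n_out, replace=False)
            mask = np.ones(j, dtype=bool)
            mask[drop] = False
            b_sub = np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(w[mask] * bx[mask] ** 2)
            diffs[s] = raw.beta - b_sub
        distortion_p = float((np.sum(np.abs(diffs) >= abs(diff_obs)) + 1) / (n_sim + 1))
        distortion_coef = float(100.0 * diff_obs / abs(corrected.beta)) if corrected.beta else float("nan")
    return {
        "global_p": global_p,
        "rss_obs": rss_obs,
        "outlier_p": pd.Series(outlier_p_bonf, index=ss["snp"].to_numpy()),
        "outliers": list(outliers),
        "raw": raw,
        "corrected": corrected,
        "distortion_p": distortion_p,
        "distortion_coefficient": distortion_coef,
    }


def steiger_filter(ss: pd.DataFrame):
    """Drop variants explaining more outcome than exposure variance.

    Strict inequality: a variant is removed iff r2_out > r2_exp; missing r2
    retains the variant with a warning.  Returns (retained, removed) frames.
    """
    r2e = ss["r2_exp"].to_numpy(dtype=float)
    r2o = ss["r2_out"].to_numpy(dtype=float)
    missing = np.isnan(r2e) | np.isnan(r2o)
    if missing.any():
        warnings.warn(f"{int(missing.sum())} variants missing r2; retained", RuntimeWarning)
    remove = (r2o > r2e) & ~missing
    return ss[~remove].reset_index(drop=True), ss[remove].reset_index(drop=True)
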