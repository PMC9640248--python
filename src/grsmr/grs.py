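"""Genetic risk scores: allele harmonization, scoring, descriptive summaries.

A genetic risk score is the weighted sum of effect-allele dosages,
score_i = sum_j w_j x_ij, with weights taken from an external GWAS.  Before
scoring, the external weight table must be aligned to the allele counted in
the dosage matrix: dosages counted on the other allele are flipped
(x -> 2 - x), strand-ambiguous palindromic variants with near-0.5 allele
frequency are dropped (their orientation cannot be resolved), and variants
absent from either side are dropped and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "harmonize",
    "compute_grs",
    "variance_explained",
    "quintile_table",
    "GRSResult",
    "HarmonizedWeights",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)


def _is_palindromic(a1: str, a2: str) -> bool:
    return len(a1) == 1 and len(a2) == 1 and _COMPLEMENT.get(a1.upper()) == a2.upper()


@dataclass
class HarmonizedWeights:
    """Weight/dosage alignment: per retained variant, whether the counted
    allele must be flipped, plus the exclusion log."""

    table: pd.DataFrame          # weight rows retained, aligned to counted allele
    flip: np.ndarray             # True where dosage must be replaced by 2 - x
    exclusions: pd.DataFrame     # variant_id, reason

    @property
    def variant_ids(self) -> list:
        return list(self.table["variant_id"])


@dataclass
class GRSResult:
    score: pd.Series
    trait: str
    n_variants_used: int
    variance_explained: float | None = None
    scaling_beta: float | None = None  # exposure units per score unit
    diagnostics: dict = field(default_factory=dict)


def harmonize(
    weights: pd.DataFrame,
    dosage_meta: pd.DataFrame,
    *,
    eaf_window: tuple[float, float] = PALINDROMIC_EAF_WINDOW,
) -> HarmonizedWeights:
    """Align a weight table to the dosage matrix's counted alleles.

    ``dosage_meta`` needs columns ``variant_id``, ``counted_allele`` and
    optionally ``other_allele`` and ``af`` (cohort frequency of the counted
    allele).  Palindromic variants whose effect-allele frequency falls in
    ``eaf_window`` are dropped as strand-ambiguous.  Raises if no variant
    survives.
    """
    if weights.empty or dosage_meta.empty:
        raise ValueError("weights and dosage_meta must be non-empty")
    meta = dosage_meta.set_index("variant_id")
    rows, flips, excl = [], [], []
    for _, row in weights.iterrows():
        vid = row["variant_id"]
        if vid not in meta.index:
            excl.append((vid, "not_in_dosages"))
            continue
        ea, oa = str(row["effect_allele"]).upper(), str(row["other_allele"]).upper()
        counted = str(meta.at[vid, "counted_allele"]).upper()
        if _is_palindromic(ea, oa):
            eaf = float(row["eaf"])
            if eaf_window[0] <= eaf <= eaf_window[1]:
                excl.append((vid, "palindromic_ambiguous"))
                continue
        if counted == ea:
            rows.append(row)
            flips.append(False)
        elif counted == oa:
            rows.append(row)
            flips.append(True)
        elif _is_palindromic(ea, oa) is False and counted == _COMPLEMENT.get(ea, ""):
            # strand-flipped record of the effect allele
            rows.append(row)
            flips.append(False)
        elif counted == _COMPLEMENT.get(oa, ""):
            rows.append(row)
            flips.append(True)
        else:
            excl.append((vid, "allele_mismatch"))
    if not rows:
        raise ValueError("harmonization removed every variant")
    table = pd.DataFrame(rows).reset_index(drop=True)
    exclusions = pd.DataFrame(excl, columns=["variant_id", "reason"])
    return HarmonizedWeights(table=table, flip=np.asarray(flips, dtype=bool), exclusions=exclusions)


def compute_grs(
    dosages: pd.DataFrame,
    harmonized: HarmonizedWeights,
    trait: str,
    *,
    missing_flag_fraction: float = 0.10,
) -> GRSResult:
    """Weighted sum of effect-allele dosages for one trait.

    ``dosages`` has one column per variant id (plus optional ``pid``).
    Missing dosages are imputed at 2 x EAF; participants missing more than
    ``missing_flag_fraction`` of variants are flagged in the diagnostics.
    """
    beta_col = f"beta_{trait}"
    if beta_col not in harmonized.table.columns:
        raise KeyError(f"no weight column {beta_col!r}")
    ids = harmonized.variant_ids
    x = dosages[ids].to_numpy(dtype=float)
    miss = np.isnan(x)
    if miss.any():
        fill = 2.0 * harmonized.table["eaf"].to_numpy(dtype=float)
        x = np.where(miss, fill[None, :], x)
    x = np.where(harmonized.flip[None, :], 2.0 - x, x)
    w = harmonized.table[beta_col].to_numpy(dtype=float)
    score = x @ w
    if not np.all(np.isfinite(score)):
        raise FloatingPointError("non-finite GRS values")
    index = dosages["pid"] if "pid" in dosages.columns else dosages.index
    flagged = np.where(miss.mean(axis=1) > missing_flag_fraction)[0]
    return GRSResult(
        score=pd.Series(score, index=pd.Index(index, name="pid"), name=f"grs_{trait}"),
        trait=trait,
        n_variants_used=len(ids),
        diagnostics={"n_flagged_missing": int(len(flagged)), "flagged_rows": flagged.tolist()},
    )


def variance_explained(score: GRSResult, exposure: np.ndarray) -> float:
    """Squared Pearson correlation between the score and the exposure."""
    s = np.asarray(score.score, dtype=float)
    e = np.asarray(exposure, dtype=float)
    ok = np.isfinite(s) & np.isfinite(e)
    s, e = s[ok], e[ok]
    if len(s) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(s) == 0:
        return float("nan")
    r = np.corrcoef(s, e)[0, 1]
    r2 = float(r * r)
    score.variance_explained = r2
    return r2


def _assign_fifths(score: np.ndarray) -> np.ndarray:
    """Rank-based fifths (1..5), equal sizes, ties broken by stable order."""
    order = np.argsort(score, kind="stable")
    n = len(score)
    fifths = np.empty(n, dtype=int)
    bounds = [round(k * n / 5) for k in range(6)]
    for k in range(5):
        fifths[order[bounds[k]:bounds[k + 1]]] = k + 1
    return fifths


def quintile_table(
    score: GRSResult,
    characteristics: pd.DataFrame,
    binary: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-fifth summary of cohort characteristics with trend tests.

    Continuous columns report mean (SD); columns listed in ``binary`` report
    n (%).  ``difference`` is the top-fifth minus bottom-fifth summary and
    ``p_trend`` comes from regressing the characteristic on the ordinal
    fifth index (logistic for binary columns).
    """
    s = np.asarray(score.score, dtype=float)
    if len(s) < 5:
        raise ValueError("need at least five participants to form fifths")
    fifth = _assign_fifths(s)
    rows = []
    x_trend = sm.add_constant(fifth.astype(float))
    for col in characteristics.columns:
        v = characteristics[col].to_numpy(dtype=float)
        rec = {"characteristic": col, "kind": "binary" if col in binary else "continuous"}
        for k in range(1, 6):
            sel = fifth == k
            if col in binary:
                rec[f"fifth{k}_n"] = int(np.nansum(v[sel]))
                rec[f"fifth{k}"] = float(np.nanmean(v[sel]))
            else:
                rec[f"fifth{k}"] = float(np.nanmean(v[sel]))
                rec[f"fifth{k}_sd"] = float(np.nanstd(v[sel], ddof=1))
        rec["difference"] = rec["fifth5"] - rec["fifth1"]
        try:
            if col in binary:
                fit = sm.Logit(v, x_trend).fit(disp=0)
            else:
                fit = sm.OLS(v, x_trend, missing="drop").fit()
            rec["p_trend"] = float(fit.pvalues[1])
        except Exception:  # constant column etc.
            rec["p_trend"] = float("nan")
        rows.append(rec)
    return pd.DataFrame(rows).set_index("characteristic")
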