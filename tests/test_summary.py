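"""Summary-data MR estimators against brute-force oracles and planted truths."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_summary
from grsmr.summary import (
    _offset_logistic,
    _weighted_median_point,
    ivw,
    modified_q_filter,
    mr_egger,
    mr_presso,
    per_snp_associations,
    steiger_filter,
    wald_ratio,
    weighted_median,
)


def frame(bx, by, sy, sx=None, r2e=0.01, r2o=0.001):
    bx = np.asarray(bx, float)
    j = len(bx)
    return pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(j)],
            "beta_exp": bx,
            "se_exp": np.full(j, 0.01) if sx is None else np.asarray(sx, float),
            "beta_out": np.asarray(by, float),
            "se_out": np.asarray(sy, float),
            "r2_exp": np.full(j, r2e, float),
            "r2_out": np.full(j, r2o, float),
        }
    )


class TestWaldRatio:
    def test_arithmetic(self):
        est, se = wald_ratio(0.5, 0.1, 0.02)
        assert est == pytest.approx(0.2)
        assert se == pytest.approx(0.04)

    def test_zero_outcome(self):
        assert wald_ratio(0.5, 0.0, 0.02)[0] == 0.0

    def test_antisymmetry(self):
        a, _ = wald_ratio(0.5, 0.1, 0.02)
        b, _ = wald_ratio(-0.5, 0.1, 0.02)
        assert a == -b

    def test_floor_exclusion(self):
        with pytest.raises(ValueError):
            wald_ratio(0.001, 0.1, 0.02, floor=0.01)


class TestIVW:
    def test_identical_ratios_zero_q(self):
        ss = frame([0.2, 0.4, 0.5], [0.02, 0.04, 0.05], [0.01, 0.01, 0.01])
        f = ivw(ss)
        assert f.beta == pytest.approx(0.1)
        assert f.diagnostics["Q"] == pytest.approx(0.0, abs=1e-20)

    def test_equal_weights_reduce_to_mean(self):
        # equal ratio SEs: se_out proportional to |beta_exp|
        bx = np.array([0.2, 0.25, 0.5])
        ratios = np.array([0.08, 0.12, 0.10])
        ss = frame(bx, ratios * bx, 0.01 * bx)
        assert ivw(ss).beta == pytest.approx(ratios.mean())

    def test_single_snp_falls_back_to_wald(self):
        ss = frame([0.5], [0.1], [0.02])
        f = ivw(ss)
        assert f.method == "wald_ratio_single"
        assert f.beta == pytest.approx(0.2)

    def test_matches_zero_intercept_wls_identity(self, rng):
        bx = rng.uniform(0.1, 0.5, 12)
        by = 0.05 * bx + rng.standard_normal(12) * 0.01
        sy = rng.uniform(0.005, 0.02, 12)
        ss = frame(bx, by, sy)
        w = 1.0 / sy ** 2
        slope = np.sum(w * bx * by) / np.sum(w * bx ** 2)
        assert ivw(ss).beta == pytest.approx(slope, abs=1e-12)

    def test_brute_force_oracle_five_snps(self):
        """IVW equals the from-definition computation (ratio-level weights)
        on a fixed 5-SNP instance to 1e-10."""
        bx = [0.30, 0.22, 0.45, 0.18, 0.36]
        by = [0.015, 0.010, 0.024, 0.008, 0.020]
        sy = [0.004, 0.006, 0.005, 0.007, 0.004]
        ss = frame(bx, by, sy)
        # oracle: explicit loop over the definition
        num = den = 0.0
        for x, y, s in zip(bx, by, sy):
            r = y / x
            w = 1.0 / (s / abs(x)) ** 2
            num += w * r
            den += w
        assert abs(ivw(ss).beta - num / den) < 1e-10
        assert abs(ivw(ss).se - (1.0 / den) ** 0.5) < 1e-10

    def test_recovery_no_pleiotropy(self):
        reps = [ivw(make_summary(n_snps=50, b=0.03, seed=s)) for s in range(40)]
        hits = sum(abs(f.beta - 0.03) < 2 * f.se for f in reps)
        assert hits >= 33  # ~95% of 40 within 2 SE


class TestEgger:
    def test_no_pleiotropy_limit(self):
        """Points on a line through the origin: intercept 0, slope = ratio."""
        bx = np.array([0.2, 0.3, 0.4, 0.5])
        ss = frame(bx, 0.07 * bx, [0.01] * 4)
        f = mr_egger(ss)
        assert f.beta == pytest.approx(0.07, abs=1e-10)
        assert f.diagnostics["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_orientation_invariance(self, rng):
        ss = make_summary(n_snps=30, b=0.04, seed=5)
        flip = rng.choice([-1.0, 1.0], len(ss))
        flipped = ss.copy()
        flipped["beta_exp"] *= flip
        flipped["beta_out"] *= flip
        a, b = mr_egger(ss), mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-10)
        assert a.diagnostics["intercept"] == pytest.approx(b.diagnostics["intercept"], rel=1e-10)

    def test_directional_pleiotropy_recovered(self):
        """Constant pleiotropic offset delta on every variant: the intercept
        recovers delta within 2 SE, the slope stays near truth while IVW is
        biased by roughly delta / mean(beta_exp)."""
        delta, b = 0.01, 0.03
        covered = 0
        egger_err, ivw_err = [], []
        for seed in range(30):
            ss = make_summary(n_snps=60, b=b, seed=seed)
            ss["beta_out"] += delta * np.sign(ss["beta_exp"])  # aligned with exposure-raising allele
            e = mr_egger(ss)
            if abs(e.diagnostics["intercept"] - delta) < 2 * e.diagnostics["intercept_se"]:
                covered += 1
            egger_err.append(e.beta - b)
            ivw_err.append(ivw(ss).beta - b)
        assert covered >= 25
        # Egger is unbiased where IVW carries the directional offset
        assert abs(np.mean(egger_err)) < 0.5 * abs(np.mean(ivw_err))

    def test_balanced_pleiotropy_null_intercept(self):
        rng = np.random.default_rng(8)
        hits = 0
        for seed in range(25):
            pl = rng.choice([-0.01, 0.01], 60)
            ss = make_summary(n_snps=60, b=0.03, seed=100 + seed, pleio=pl)
            e = mr_egger(ss)
            hits += abs(e.diagnostics["intercept"]) < 3 * e.diagnostics["intercept_se"]
        assert hits >= 22

    def test_needs_three(self):
        with pytest.raises(ValueError):
            mr_egger(frame([0.2, 0.3], [0.01, 0.02], [0.01, 0.01]))


class TestWeightedMedian:
    def test_symmetric_three_ratios(self):
        bx = np.ones(3)
        ss = frame(bx, [0.9, 1.0, 1.1], [0.05] * 3)
        f = weighted_median(ss, n_boot=100, seed=1)
        assert f.beta == pytest.approx(1.0)

    def test_equal_weights_reduce_to_interpolated_median(self, rng):
        r = rng.normal(0.1, 0.02, 7)
        ss = frame(np.ones(7), r, np.full(7, 0.03))
        got = _weighted_median_point(r, np.ones(7))
        # ordinary interpolated median at equal weights
        rs = np.sort(r)
        cum = (np.arange(1, 8) - 0.5) / 7
        expected = np.interp(0.5, cum, rs)
        assert got == pytest.approx(expected, abs=1e-12)
        assert weighted_median(ss, n_boot=50, seed=0).beta == pytest.approx(expected, abs=1e-12)

    def test_brute_force_oracle_five_snps(self):
        """Exhaustive evaluation of the interpolated weighted-median
        definition on a 5-SNP instance matches the implementation exactly."""
        bx = np.array([0.30, 0.22, 0.45, 0.18, 0.36])
        by = np.array([0.020, 0.008, 0.030, 0.004, 0.016])
        sy = np.array([0.004, 0.006, 0.005, 0.007, 0.004])
        ss = frame(bx, by, sy)
        r = by / bx
        w = (bx / sy) ** 2
        order = np.argsort(r)
        rs, ws = r[order], w[order] / w.sum()
        cum = np.cumsum(ws) - ws / 2
        k = int(np.searchsorted(cum, 0.5))
        oracle = rs[k - 1] + (rs[k] - rs[k - 1]) * (0.5 - cum[k - 1]) / (cum[k] - cum[k - 1])
        assert abs(weighted_median(ss, n_boot=50, seed=0).beta - oracle) < 1e-10

    def test_robust_to_forty_percent_invalid(self):
        """With 40% of weight pleiotropic and 60% clean, the weighted median
        stays near truth while IVW shifts away."""
        b = 0.03
        wm_err, ivw_err = [], []
        for seed in range(25):
            ss = make_summary(n_snps=50, b=b, seed=400 + seed, se_out=0.001)
            pl = np.zeros(50)
            pl[:20] = 0.03  # 40% of (roughly equal) weight
            ss["beta_out"] += pl * np.sign(ss["beta_exp"])
            wm_err.append(weighted_median(ss, n_boot=60, seed=seed).beta - b)
            ivw_err.append(ivw(ss).beta - b)
        assert abs(np.mean(wm_err)) < 0.25 * abs(np.mean(ivw_err))

    def test_seed_determinism(self):
        ss = make_summary(n_snps=20, seed=9)
        a = weighted_median(ss, n_boot=200, seed=42)
        b = weighted_median(ss, n_boot=200, seed=42)
        assert a.se == b.se


class TestModifiedQ:
    def test_homogeneous_nothing_removed(self):
        ss = make_summary(n_snps=30, b=0.03, seed=3)
        kept, removed, refit = modified_q_filter(ss)
        assert removed == []
        assert len(kept) == 30

    def test_planted_outlier_removed_first(self):
        ss = make_summary(n_snps=30, b=0.03, seed=4)
        ss.loc[7, "beta_out"] += 0.2
        kept, removed, refit = modified_q_filter(ss)
        assert removed[0] == "snp7"

    def test_alpha_zero_is_identity(self):
        ss = make_summary(n_snps=10, seed=5)
        ss.loc[2, "beta_out"] += 1.0
        kept, removed, _ = modified_q_filter(ss, alpha=0.0)
        assert removed == []
        assert len(kept) == 10

    def test_aborts_rather_than_removing_everything(self):
        # wildly heterogeneous ratios: removal cascade must stop with an error
        ss = frame([0.2, 0.3, 0.4], [10.0, -10.0, 5.0], [0.001] * 3)
        with pytest.raises(RuntimeError):
            modified_q_filter(ss, alpha=1.0)


class TestPRESSO:
    def test_seed_determinism(self):
        ss = make_summary(n_snps=20, seed=6)
        a = mr_presso(ss, n_sim=200, seed=7)
        b = mr_presso(ss, n_sim=200, seed=7)
        assert a["global_p"] == b["global_p"]
        assert list(a["outlier_p"]) == list(b["outlier_p"])

    def test_n_sim_floor(self):
        with pytest.raises(ValueError):
            mr_presso(make_summary(n_snps=10), n_sim=50)

    def test_planted_outlier_flagged(self):
        ss = make_summary(n_snps=30, b=0.03, seed=8)
        ss.loc[4, "beta_out"] += 0.2
        res = mr_presso(ss, n_sim=1000, seed=1)
        assert "snp4" in res["outliers"]
        assert res["global_p"] < 0.05
        assert abs(res["corrected"].beta - 0.03) < abs(res["raw"].beta - 0.03)

    def test_null_global_p_not_small(self):
        ps = [mr_presso(make_summary(n_snps=30, b=0.03, seed=s), n_sim=300, seed=s)["global_p"]
              for s in range(20)]
        assert np.mean(ps) > 0.25
        assert min(ps) > 0.0

    def test_needs_four(self):
        with pytest.raises(ValueError):
            mr_presso(make_summary(n_snps=3), n_sim=200)


class TestSteiger:
    def test_retained_when_exposure_dominates(self):
        ss = frame([0.3], [0.01], [0.01], r2e=0.010, r2o=0.001)
        kept, removed = steiger_filter(ss)
        assert len(kept) == 1 and len(removed) == 0

    def test_removed_when_outcome_dominates(self):
        ss = frame([0.3, 0.2], [0.01, 0.01], [0.01, 0.01])
        ss.loc[1, "r2_out"] = 0.05
        kept, removed = steiger_filter(ss)
        assert list(removed["snp"]) == ["s1"]

    def test_tie_retained(self):
        ss = frame([0.3], [0.01], [0.01], r2e=0.01, r2o=0.01)
        kept, removed = steiger_filter(ss)
        assert len(removed) == 0

    def test_missing_r2_retained_with_warning(self):
        ss = frame([0.3, 0.2], [0.01, 0.01], [0.01, 0.01])
        ss.loc[0, "r2_out"] = np.nan
        with pytest.warns(RuntimeWarning):
            kept, removed = steiger_filter(ss)
        assert len(kept) == 2


class TestPerSnpAssociations:
    def test_offset_fit_matches_exact_joint_fit(self, cohort, derived, covariates):
        ids = [c for c in cohort["dosages"].columns if c.startswith("sbp_")][:12]
        dos = cohort["dosages"][["pid"] + ids]
        approx = per_snp_associations(
            dos, derived["sbp_adj"], derived["ckd"].astype(float), covariates
        )
        exact = per_snp_associations(
            dos, derived["sbp_adj"], derived["ckd"].astype(float), covariates, exact=True
        )
        # agreement well inside sampling noise (genotypes ~ independent of covariates)
        assert np.max(np.abs(approx["beta_out"] - exact["beta_out"]) / exact["se_out"]) < 0.1
        np.testing.assert_allclose(approx["se_out"], exact["se_out"], rtol=0.02)

    def test_monomorphic_dropped(self, derived, covariates, cohort):
        dos = cohort["dosages"][["pid"]].copy()
        dos["mono"] = 0
        dos["ok"] = cohort["dosages"].filter(like="sbp_").iloc[:, 0]
        ss = per_snp_associations(dos, derived["sbp_adj"], derived["ckd"].astype(float), covariates)
        assert ss.attrs["dropped"] == ["mono"]
        assert list(ss["snp"]) == ["ok"]

    def test_permuted_outcome_z_scores_standard_normal(self, cohort, derived, covariates, rng):
        ids = [c for c in cohort["dosages"].columns if c.startswith("sbp_")]
        y = rng.permutation(derived["ckd"].astype(float).to_numpy())
        ss = per_snp_associations(cohort["dosages"][["pid"] + ids], derived["sbp_adj"], y, covariates)
        z = ss["beta_out"] / ss["se_out"]
        assert abs(z.mean()) < 0.4
        assert 0.7 < z.std() < 1.3

    def test_exposure_slope_recovers_planted_effect(self, cohort, derived, covariates):
        truth = cohort["truth"]
        ids = [c for c in cohort["dosages"].columns if c.startswith("sbp_")]
        ss = per_snp_associations(
            cohort["dosages"][["pid"] + ids], derived["sbp_adj"], derived["ckd"].astype(float), covariates
        )
        a = truth.true_beta_sbp[: len(ids)]
        within = np.abs(ss["beta_exp"] - a) < 2 * ss["se_exp"]
        assert within.mean() > 0.85
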