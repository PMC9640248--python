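"""One-sample MR: scaling arithmetic, likelihood properties, multinomial
consistency, residualization, subgroup machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from grsmr.grs import GRSResult
from grsmr.onesample import (
    ScoreCalibration,
    calibrate_score,
    compute_mediator_scores,
    default_covariates,
    fit_grs_outcome,
    multinomial_mr,
    multivariable_adjusted_mr,
    residualize_characteristic,
    scale_to_exposure_units,
    snp_exclusion_filter,
    subgroup_mr,
)


def cal(beta, trait="sbp", t=100.0):
    return ScoreCalibration(beta=beta, se=abs(beta) / t, t=t, trait=trait)


class TestScaling:
    def test_arithmetic(self):
        from grsmr.onesample import GRSFit

        fit = GRSFit(beta=0.05, se=0.01, n=100, n_cases=20, converged=True)
        est = scale_to_exposure_units(fit, cal(1.6), unit=10)
        assert est.beta == pytest.approx(0.3125)
        assert est.odds_ratio == pytest.approx(math.exp(0.3125))  # ~1.367
        assert est.se == pytest.approx(0.01 * 10 / 1.6)

    def test_null_outcome_gives_or_one(self):
        from grsmr.onesample import GRSFit

        fit = GRSFit(beta=0.0, se=0.01, n=100, n_cases=20, converged=True)
        assert scale_to_exposure_units(fit, cal(1.6), unit=10).odds_ratio == 1.0

    def test_zero_calibration_rejected(self):
        from grsmr.onesample import GRSFit

        fit = GRSFit(beta=0.1, se=0.01, n=100, n_cases=20, converged=True)
        with pytest.raises(ZeroDivisionError):
            scale_to_exposure_units(fit, cal(0.0), unit=10)

    def test_weak_calibration_warns(self):
        from grsmr.onesample import GRSFit

        fit = GRSFit(beta=0.1, se=0.01, n=100, n_cases=20, converged=True)
        with pytest.warns(RuntimeWarning):
            est = scale_to_exposure_units(fit, cal(1.6, t=3.0), unit=10)
        assert est.diagnostics.get("weak_instrument_warning")

    def test_delta_se_exceeds_ratio_se(self):
        from grsmr.onesample import GRSFit

        fit = GRSFit(beta=0.1, se=0.01, n=100, n_cases=20, converged=True)
        a = scale_to_exposure_units(fit, cal(1.6, t=20), unit=10, se_method="ratio")
        b = scale_to_exposure_units(fit, cal(1.6, t=20), unit=10, se_method="delta")
        assert b.se > a.se

    def test_ci_brackets_or(self):
        from grsmr.onesample import GRSFit

        fit = GRSFit(beta=0.05, se=0.02, n=100, n_cases=20, converged=True)
        est = scale_to_exposure_units(fit, cal(1.6), unit=10)
        lo, hi = est.ci
        assert lo < est.odds_ratio < hi


class TestFitGRSOutcome:
    def test_duplicating_rows_halves_variance(self, rng):
        s = rng.standard_normal(2000)
        y = rng.random(2000) < expit(-2 + 0.5 * s)
        f1 = fit_grs_outcome(y.astype(float), s)
        f2 = fit_grs_outcome(np.tile(y.astype(float), 2), np.tile(s, 2))
        assert f2.beta == pytest.approx(f1.beta, rel=1e-6)
        assert f2.se == pytest.approx(f1.se / math.sqrt(2), rel=1e-6)

    def test_case_floor_enforced(self, rng):
        s = rng.standard_normal(100)
        y = np.zeros(100)
        y[:3] = 1
        with pytest.raises(ValueError):
            fit_grs_outcome(y, s)

    def test_known_coefficient_recovered(self, rng):
        s = rng.standard_normal(40_000)
        y = (rng.random(40_000) < expit(-2.5 + 0.3 * s)).astype(float)
        f = fit_grs_outcome(y, s)
        assert abs(f.beta - 0.3) < 2.5 * f.se

    def test_unit_coherence_weight_doubling(self, cohort, derived, covariates):
        """Doubling every weight rescales the score but leaves the scaled OR
        invariant (the calibration denominator doubles too)."""
        from grsmr.grs import compute_grs, harmonize

        v = cohort["variants"]
        w = v[v["trait"] == "sbp"].copy()
        meta = pd.DataFrame({"variant_id": w["variant_id"], "counted_allele": w["effect_allele"]})
        res1 = compute_grs(cohort["dosages"], harmonize(w, meta), "sbp")
        w2 = w.assign(beta_sbp=2.0 * w["beta_sbp"])
        res2 = compute_grs(cohort["dosages"], harmonize(w2, meta), "sbp")
        exp = derived["sbp_adj"].to_numpy()
        e1 = scale_to_exposure_units(
            fit_grs_outcome(derived["ckd"], res1, covariates),
            calibrate_score(exp, res1, covariates), 10, outcome="ckd",
        )
        e2 = scale_to_exposure_units(
            fit_grs_outcome(derived["ckd"], res2, covariates),
            calibrate_score(exp, res2, covariates), 10, outcome="ckd",
        )
        assert e1.beta == pytest.approx(e2.beta, rel=1e-6)
        assert e1.se == pytest.approx(e2.se, rel=1e-6)


class TestMultinomial:
    def test_matches_binary_on_two_category_subset(self, rng):
        """Multinomial A-vs-reference equals the binary logistic fit on the
        A/reference subset (identical likelihood for two categories)."""
        n = 6000
        s = rng.standard_normal(n)
        lp = -1.0 + 0.4 * s
        y = np.where(rng.random(n) < expit(lp), "A", "ref")
        c = cal(1.0)
        ests = multinomial_mr(y, s, None, c, unit=10, reference="ref")
        fb = fit_grs_outcome((y == "A").astype(float), s)
        eb = scale_to_exposure_units(fb, c, unit=10)
        assert ests["A"].beta == pytest.approx(eb.beta, rel=1e-4)

    def test_reference_must_exist(self, rng):
        y = np.repeat(["A", "B"], 50)
        with pytest.raises(ValueError):
            multinomial_mr(y, rng.standard_normal(100), None, cal(1.0), 10, reference="C")

    def test_sparse_category_reported_not_estimable(self, rng):
        n = 600
        y = np.array(["ref"] * (n - 3) + ["rare"] * 3)
        ests = multinomial_mr(y, rng.standard_normal(n), None, cal(1.0), 10, reference="ref")
        assert ests["rare"].diagnostics.get("not_estimable")


class TestResidualize:
    def test_orthogonality_machine_precision(self, rng):
        s = rng.standard_normal(500)
        c = 1.5 * s + rng.standard_normal(500)
        score = GRSResult(score=pd.Series(s), trait="sbp", n_variants_used=1)
        r = residualize_characteristic(c, score)
        assert abs(np.corrcoef(r, s)[0, 1]) < 1e-10

    def test_exact_removal(self, rng):
        s = rng.standard_normal(100)
        r = residualize_characteristic(2.0 * s, s)
        np.testing.assert_allclose(r, 0.0, atol=1e-10)

    def test_independent_characteristic_unchanged_slope(self, rng):
        s = rng.standard_normal(50_000)
        c = rng.standard_normal(50_000)
        r = residualize_characteristic(c, s)
        assert np.std(r - c) < 0.02  # gamma-hat ~ 0

    def test_needs_three(self):
        with pytest.raises(ValueError):
            residualize_characteristic([1.0, 2.0], [0.1, 0.2])


class TestSubgroups:
    def test_permuted_grouping_gives_null_interaction(self, cohort, derived, covariates, rng):
        from grsmr.grs import compute_grs, harmonize

        v = cohort["variants"]
        w = v[v["trait"] == "sbp"]
        meta = pd.DataFrame({"variant_id": w["variant_id"], "counted_allele": w["effect_allele"]})
        res = compute_grs(cohort["dosages"], harmonize(w, meta), "sbp")
        c = calibrate_score(derived["sbp_adj"].to_numpy(), res, covariates)
        g = rng.permutation(cohort["pheno"]["sex"].to_numpy())
        results, p_int = subgroup_mr(derived["ckd"], res, covariates, g, c, 10)
        assert len(results) == 2
        assert p_int > 0.001  # permutation null: not spuriously tiny

    def test_residualized_strata_materially_similar(self, cohort, derived, covariates):
        """Without a collider pathway, stratifying on residualized BMI gives
        stratum ORs close to stratifying on raw BMI."""
        from grsmr.grs import compute_grs, harmonize

        v = cohort["variants"]
        w = v[v["trait"] == "sbp"]
        meta = pd.DataFrame({"variant_id": w["variant_id"], "counted_allele": w["effect_allele"]})
        res = compute_grs(cohort["dosages"], harmonize(w, meta), "sbp")
        c = calibrate_score(derived["sbp_adj"].to_numpy(), res, covariates)
        bmi = cohort["pheno"]["bmi"].to_numpy()
        raw_groups = (bmi > np.median(bmi)).astype(int)
        resid = residualize_characteristic(bmi, res)
        resid_groups = (resid > np.median(resid)).astype(int)
        covs = covariates.drop(columns=["bmi"])
        raw_res, _ = subgroup_mr(derived["ckd"], res, covs, raw_groups, c, 10)
        rez_res, _ = subgroup_mr(derived["ckd"], res, covs, resid_groups, c, 10)
        for g in (0, 1):
            assert abs(raw_res[g].beta - rez_res[g].beta) < 1.0 * max(raw_res[g].se, rez_res[g].se)

    def test_single_stratum_rejected(self, rng):
        s = rng.standard_normal(200)
        y = (rng.random(200) < 0.3).astype(float)
        with pytest.raises(ValueError):
            subgroup_mr(y, s, pd.DataFrame(index=range(200)), np.zeros(200), cal(1.0), 10)


class TestMultivariable:
    def test_zero_mediator_effects_leave_estimate_unchanged(self, cohort, derived, covariates):
        """All-zero mediator weights produce constant (dropped) mediator
        scores, so the adjusted estimate equals the unadjusted one."""
        from grsmr.grs import compute_grs, harmonize

        v = cohort["variants"]
        w = v[v["trait"] == "sbp"]
        meta = pd.DataFrame({"variant_id": w["variant_id"], "counted_allele": w["effect_allele"]})
        res = compute_grs(cohort["dosages"], harmonize(w, meta), "sbp")
        c = calibrate_score(derived["sbp_adj"].to_numpy(), res, covariates)
        med = compute_mediator_scores(cohort["dosages"], v)
        assert np.allclose(med.to_numpy().std(axis=0), 0.0)  # default config: no mediator genetics
        adj = multivariable_adjusted_mr(derived["ckd"], res, covariates, med, c, 10)
        unadj = scale_to_exposure_units(fit_grs_outcome(derived["ckd"], res, covariates), c, 10)
        assert adj.beta == pytest.approx(unadj.beta, rel=1e-6)

    def test_missing_mediator_columns_rejected(self, cohort):
        v = cohort["variants"].drop(columns=["beta_bmi"])
        with pytest.raises(ValueError):
            compute_mediator_scores(cohort["dosages"], v)

    def test_mediated_effect_attenuates_toward_direct(self):
        """Routing part of the SNP effect through BMI (with BMI causal for
        the outcome) inflates the unadjusted estimate; adjusting for the
        predicted-BMI score moves it back toward the direct effect."""
        from grsmr import SimConfig, derive_outcomes, simulate_all
        from grsmr.grs import compute_grs, harmonize

        cfg = SimConfig(
            n_participants=60_000, n_snps_sbp=120, n_snps_dbp=0, seed=31,
            mediator_fraction=0.5, mediator_bmi_effect=0.2,
            confounder_effects={
                "age_sbp": 0.45, "sex_sbp": 4.0, "bmi_sbp": 0.8,
                "age_dbp": 0.10, "sex_dbp": 1.0, "bmi_dbp": 0.5,
                "bmi_ckd": 0.10,
            },
        )
        variants, truth, pheno, dosages = simulate_all(cfg)
        der = derive_outcomes(pheno)
        covs = default_covariates(pheno, include_bmi=False)  # leave the BMI path open
        w = variants[variants["trait"] == "sbp"]
        meta = pd.DataFrame({"variant_id": w["variant_id"], "counted_allele": w["effect_allele"]})
        res = compute_grs(dosages, harmonize(w, meta), "sbp")
        c = calibrate_score(der["sbp_adj"].to_numpy(), res, covs)
        unadj = scale_to_exposure_units(fit_grs_outcome(der["ckd"], res, covs), c, 10)
        med = compute_mediator_scores(dosages, variants, mediators=("bmi",))
        adj = multivariable_adjusted_mr(der["ckd"], res, covs, med, c, 10)
        direct = truth.ckd_logor_per10_sbp
        assert abs(adj.beta - direct) < abs(unadj.beta - direct)


class TestSnpExclusion:
    def test_empty_list_is_identity(self, cohort):
        filt, log = snp_exclusion_filter(cohort["variants"], [])
        assert len(filt) == len(cohort["variants"])
        assert log["n_removed"] == 0

    def test_unknown_ids_logged_not_fatal(self, cohort):
        filt, log = snp_exclusion_filter(cohort["variants"], ["nope_1", "nope_2"])
        assert log["n_unknown"] == 2
        assert len(filt) == len(cohort["variants"])

    def test_removing_everything_breaks_downstream(self, cohort):
        from grsmr.grs import harmonize

        filt, _ = snp_exclusion_filter(
            cohort["variants"], list(cohort["variants"]["variant_id"])
        )
        meta = pd.DataFrame({"variant_id": [], "counted_allele": []})
        with pytest.raises(ValueError):
            harmonize(filt, meta)
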