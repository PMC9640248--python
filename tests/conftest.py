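import numpy as np
import pandas as pd
import pytest

from grsmr import SimConfig, derive_outcomes, simulate_all
from grsmr.onesample import default_covariates


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_participants=6000, n_snps_sbp=80, n_snps_dbp=80, seed=11)


@pytest.fixture(scope="session")
def cohort(small_config):
    """A modest synthetic cohort shared across unit tests."""
    variants, truth, pheno, dosages = simulate_all(small_config)
    return {"variants": variants, "truth": truth, "pheno": pheno, "dosages": dosages}


@pytest.fixture(scope="session")
def derived(cohort):
    return derive_outcomes(cohort["pheno"])


@pytest.fixture(scope="session")
def covariates(cohort):
    return default_covariates(cohort["pheno"])


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_summary(n_snps=20, b=0.03, seed=0, pleio=None, se_out=0.02, se_exp=0.002):
    """Summary-statistics generator for estimator tests: per-SNP exposure
    effects around 0.3 mmHg/allele, outcome = b * exposure + optional
    pleiotropic offsets + noise at the stated SEs."""
    rng = np.random.default_rng(seed)
    bx_true = rng.uniform(0.15, 0.5, n_snps) * rng.choice([-1.0, 1.0], n_snps)
    delta = np.zeros(n_snps) if pleio is None else np.asarray(pleio, dtype=float)
    bx = bx_true + rng.standard_normal(n_snps) * se_exp
    by = b * bx_true + delta + rng.standard_normal(n_snps) * se_out
    return pd.DataFrame(
        {
            "snp": [f"snp{i}" for i in range(n_snps)],
            "beta_exp": bx,
            "se_exp": np.full(n_snps, se_exp),
            "beta_out": by,
            "se_out": np.full(n_snps, se_out),
            "r2_exp": 0.01 * np.ones(n_snps),
            "r2_out": 0.001 * np.ones(n_snps),
        }
    )
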