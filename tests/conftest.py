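"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest
from hypothesis import settings

from stiffpipe import phenoprep, synthdata

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """2,000 samples x 500 variants with the default causal structure."""
    cfg = synthdata.SimConfig(n_samples=2_000, n_variants=500, seed=7)
    dosages, variants = synthdata.simulate_genotypes(cfg)
    raw, truth = synthdata.simulate_phenotypes(dosages, variants, cfg)
    return cfg, dosages, variants, raw, truth


@pytest.fixture(scope="session")
def clean_pheno(small_cohort):
    _cfg, _d, _v, raw, _t = small_cohort
    clean = phenoprep.select_measurements(raw)
    return phenoprep.log_transform(clean, ["baPWV", "cfPWV", "bfPWV", "SBP", "DBP"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
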