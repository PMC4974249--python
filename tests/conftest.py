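import numpy as np
import pytest
from hypothesis import settings

import longgwas as lg

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_cohort():
    """150 unrelated subjects, 4 courses, 120 SNPs, default calibration."""
    cfg = lg.SimConfig(n_subjects=150, n_snps=120, seed=42)
    g, gt = lg.simulate_genotypes(cfg)
    pheno, pt = lg.simulate_phenotype(g, None, cfg)
    return cfg, g, gt, pheno, pt


@pytest.fixture(scope="session")
def tiny_pheno():
    """12 subjects x 4 courses with a couple of missing cells."""
    rng = np.random.default_rng(0)
    Y = rng.normal(3.6, 0.2, size=(12, 4))
    Y[0, 3] = np.nan
    Y[5, 1] = np.nan
    return lg.LongitudinalPhenotype(Y)
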