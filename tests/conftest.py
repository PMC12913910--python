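import numpy as np
import pytest

from wildgwas.simdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort under study defaults: 52 x 5000, 5 causal loci."""
    return simulate_cohort(SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort for smoke/IO tests."""
    return simulate_cohort(SimConfig(seed=7, n_loci=600))


@pytest.fixture(scope="session")
def null_cohort():
    """Global-null cohort: growth independent of genotype, no structure."""
    return simulate_cohort(SimConfig(seed=17, n_loci=2000, n_causal=0,
                                     per_locus_r2=0.0, k_latent=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
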