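import numpy as np
import pytest

from poolgwas import synthetic_data as sd
from poolgwas.pooled_array import PafMatrix


@pytest.fixture(scope="session")
def small_study():
    """Compact full study: 600 SNPs, 2 effect regions, 50 per group."""
    cfg = sd.SimulationConfig(
        seed=7, m_snps=600, n_effect_snps=2, strip_count=3, n_per_group=50,
        n_chromosomes=3,
    )
    return sd.simulate_study(cfg, phenotypes=False)


@pytest.fixture(scope="session")
def small_matrix(small_study):
    return PafMatrix.from_intensities(small_study.intensities)


@pytest.fixture(scope="session")
def pheno_study():
    """Small study including OGTT phenotype generation."""
    cfg = sd.SimulationConfig(
        seed=11, m_snps=20, n_effect_snps=1, effect_region_size=5,
        strip_count=2, n_per_group=60, n_chromosomes=1,
    )
    return sd.simulate_study(cfg, phenotypes=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_917)
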