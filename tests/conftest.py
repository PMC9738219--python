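import numpy as np
import pytest

from aiopheno.io import GenotypeMatrix
from aiopheno.synthetic import SimConfig, generate_genotypes, generate_climate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genotype():
    values = np.array([
        [0, 1, 2, 0],
        [0, 1, 0, 0],
        [2, 2, 1, 1],
    ])
    return GenotypeMatrix(values, ["a1", "a2", "a3"], ["s1", "s2", "s3", "s4"])


@pytest.fixture(scope="session")
def small_panel():
    """A structured panel shared by slower tests: 300 accessions × 300 SNPs,
    5 subpopulations."""
    cfg = SimConfig(n_accessions=300, n_snps=300, n_subpops=5, divergence=0.12, seed=7)
    G, labels = generate_genotypes(cfg)
    return cfg, G, labels


@pytest.fixture(scope="session")
def climate_window():
    return generate_climate(SimConfig(seed=3), environment=0)
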