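import numpy as np
import pytest

from rfikit.simulate import SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def small_genotypes():
    """426 birds x 500 SNPs on two chromosomes; shared across tests."""
    cfg = SimConfig(n_individuals=426, n_snps=500, chrom_lengths=(450_000, 450_000), seed=11)
    return simulate_genotypes(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
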