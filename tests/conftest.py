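import pytest

from karyofeat import synthgenome as sg

TOY_SEED = 1
GENO_SEED = 3


@pytest.fixture(scope="session")
def toy():
    """Standard planted toy genome: (reference, diverged query, truth)."""
    return sg.toy_genome(seed=TOY_SEED)


@pytest.fixture(scope="session")
def geno_sim():
    """Two-population genotype simulation: (GenotypeMatrix, truth)."""
    return sg.simulate_two_population_genotypes(seed=GENO_SEED)
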