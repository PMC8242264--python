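import numpy as np
import pytest

from mlgwas.simulate import QTNSpec, SimSpec, simulate_genotypes, simulate_phenotype


@pytest.fixture(scope="session")
def small_dataset():
    """A modest two-QTN dataset reused across tests (seed fixed)."""
    spec = SimSpec(
        n=150,
        m=600,
        chromosomes=3,
        qtns=[QTNSpec(index=100, r2=0.15), QTNSpec(index=400, r2=0.10)],
        h2_poly=0.3,
        ld_rho=0.3,
        seed=11,
    )
    genotype = simulate_genotypes(spec)
    phenotype, truth = simulate_phenotype(genotype, spec)
    return genotype, phenotype.values[:, 0], truth, spec


@pytest.fixture(scope="session")
def null_dataset():
    """No QTNs, polygenic background only."""
    spec = SimSpec(n=120, m=400, chromosomes=2, qtns=[], h2_poly=0.3, seed=5)
    genotype = simulate_genotypes(spec)
    phenotype, truth = simulate_phenotype(genotype, spec)
    return genotype, phenotype.values[:, 0], truth, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
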