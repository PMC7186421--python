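import numpy as np
import pytest

from gxp.grm import compute_grm
from gxp.synthpop import TruthModel, simulate_genotypes, simulate_phenotype


@pytest.fixture(scope="session")
def cohort():
    """Small two-population cohort reused across test modules."""
    G = simulate_genotypes((150, 150), 500, fst=0.02, seed=101)
    truth = TruthModel(h2=0.5, fst=0.02)
    ph = simulate_phenotype(G, truth, seed=102)
    return G, truth, ph


@pytest.fixture(scope="session")
def cohort_grm(cohort):
    G, _, _ = cohort
    return compute_grm(G)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
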