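import numpy as np
import pytest
from hypothesis import settings

from panmap import simulate

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_pair():
    """A small genome pair with planted variants, shared across tests."""
    cfg = simulate.SimulationConfig(seed=11, genome_size=500_000, n_genes=100,
                                    n_dup_in_q=5, n_dup_in_r=5,
                                    n_deleted_in_q=3, n_te_genes=5, n_tes=10)
    return simulate.simulate_genome_pair(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
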