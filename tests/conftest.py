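import numpy as np
import pytest

from ptvburden import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-individual cohort shared by the read-only pipeline tests."""
    cfg = SimulationConfig(
        n_individuals=300, n_genes=40, n_variants=200, seed=42
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
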