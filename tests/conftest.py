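import numpy as np
import pytest

from gcanddi.simulate import SimulationConfig, simulate_ddis, simulate_drugs


@pytest.fixture(scope="session")
def small_cohort():
    """30 drugs in 3 latent classes with mild noise, plus their typed pairs."""
    config = SimulationConfig(n_drugs=30, n_classes=3, seed=11)
    drugs = simulate_drugs(config)
    return config, drugs, simulate_ddis(drugs, config)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small noise-free cohort: signatures are an exact function of class."""
    config = SimulationConfig(n_drugs=24, n_classes=2, n_types=4,
                              bit_flip_rate=0.0, expr_noise_sd=0.0,
                              n_pairs=200, seed=5)
    drugs = simulate_drugs(config)
    return config, drugs, simulate_ddis(drugs, config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
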