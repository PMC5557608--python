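import numpy as np
import pytest

from nucflux import CellCycleParams, NoiseModel, SimulationConfig
from nucflux.simulate import sample_gene_parameters, simulate_experiment


@pytest.fixture(scope="session")
def ccp() -> CellCycleParams:
    return CellCycleParams()


@pytest.fixture(scope="session")
def flat_noise() -> NoiseModel:
    return NoiseModel.constant(0.2)


@pytest.fixture(scope="session")
def clean_experiment():
    """Small noise-free experiment with escape and carry-over off."""
    config = SimulationConfig(
        n_genes=8, seed=42, noise=False, U=0.0, uridine_fraction=1e12
    )
    rng = config.rng()
    truth = sample_gene_parameters(config, rng)
    return config, truth, simulate_experiment(truth, config, rng)


@pytest.fixture(scope="session")
def noisy_experiment():
    """Small experiment at the full study conditions (noise, escape, U)."""
    config = SimulationConfig(n_genes=60, seed=7)
    rng = config.rng()
    truth = sample_gene_parameters(config, rng)
    return config, truth, simulate_experiment(truth, config, rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
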