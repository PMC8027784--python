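import numpy as np
import pytest

from plumefall.gp_model import Hyperparams, ModelConfig
from plumefall.synthetic_data import SimulationConfig, generate_survey


@pytest.fixture(scope="session")
def fast_sim_config() -> SimulationConfig:
    """Default study design with a coarser truth-quadrature grid (speed)."""
    return SimulationConfig(truth_grid_n=30)


@pytest.fixture(scope="session")
def survey(fast_sim_config):
    """One default synthetic survey, shared across read-only tests."""
    return generate_survey(fast_sim_config, seed=7)


@pytest.fixture(scope="session")
def quick_model_config() -> ModelConfig:
    return ModelConfig(iterations=1200)


@pytest.fixture
def hp() -> Hyperparams:
    return Hyperparams(
        mu=np.array([0.4, 0.1, -0.3, -0.2, 0.0]),
        alpha=0.8,
        rho_r=0.5,
        rho_theta=0.6,
        sigma=0.3,
    )
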