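import numpy as np
import pytest

from zonasim import InitialCondition, RateConstants, simulate


@pytest.fixture(scope="session")
def default_params() -> RateConstants:
    return RateConstants()


@pytest.fixture(scope="session")
def standard_trajectory(default_params):
    """One 24 h trajectory at a GSH-depleting dose, shared across tests."""
    grid = np.linspace(0.0, 24.0, 121)
    return simulate(InitialCondition(P0=20.0), default_params, 24.0, output_grid=grid)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
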