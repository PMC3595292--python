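import numpy as np
import pytest

from ecokrige import (
    LandscapeConfig,
    ObservationSet,
    SeasonConfig,
    VariogramParams,
    generate_landscape,
    simulate_grf,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def toy_obs():
    """Four fixed sites on a ~50 m square; small enough for quadrature."""
    coords = np.array([[0.0, 0.0], [30.0, 10.0], [10.0, 40.0], [50.0, 50.0]])
    values = np.array([1.2, 0.7, 1.9, 1.1])
    return ObservationSet(coords, values)


@pytest.fixture(scope="session")
def sim_obs150():
    """n=150 sites simulated from known parameters (phi=60, nu=0.1)."""
    truth = VariogramParams(beta=3.0, sigma2=1.5, tau2=0.15, phi=60.0)
    r = np.random.default_rng(0)
    coords = r.uniform(0, 300, (150, 2))
    values = truth.beta + simulate_grf(coords, truth, r)
    return ObservationSet(coords, values), truth


@pytest.fixture(scope="session")
def small_landscape():
    """Reduced domain (~1.2 ha, 400 trees, 40 sites) for fast spatial tests."""
    cfg = LandscapeConfig(
        width=120.0, height=100.0, cell=2.0, coarse_cell=10.0,
        n_trees=400, n_sites=40,
    )
    return generate_landscape(cfg, seed=0)


@pytest.fixture(scope="session")
def season():
    return SeasonConfig()
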