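import numpy as np
import pytest

from placerep.maze import build_standard_maze
from placerep.synthetic import PopulationParams, simulate_session


@pytest.fixture(scope="session")
def geometry():
    return build_standard_maze()


@pytest.fixture(scope="session")
def small_session(geometry):
    """A 20-minute synthetic session with 8 cells, shared across tests."""
    session, cells = simulate_session(
        geometry,
        duration_s=1200.0,
        population_params=PopulationParams(n_cells=8, p_drifting=0.3),
        seed=11,
    )
    return session, cells


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
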