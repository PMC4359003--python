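import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import shipworm as sw

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario():
    return sw.SyntheticScenario()


@pytest.fixture(scope="session")
def grid():
    """Demo-scale Baltic-like grid (20 x 36 cells, 6 depth bins)."""
    return sw.default_grid()


@pytest.fixture(scope="session")
def bathy(grid, scenario):
    return sw.synth_bathymetry(grid, scenario)


@pytest.fixture(scope="session")
def hydro_year(grid, bathy, scenario):
    """One year of daily synthetic fields on the demo grid."""
    return sw.synth_hydro(grid, bathy, scenario, [2000])


@pytest.fixture(scope="session")
def small_state(scenario):
    """Monthly surface-layer state on a small grid, for property sweeps."""
    g = sw.make_grid(6, 10, [0.0, 9.0, 25.0, 120.0], (10.0, 20.0, 54.0, 57.0))
    b = sw.synth_bathymetry(g, scenario)
    h = sw.synth_hydro(g, b, scenario, [2000], time_step=np.timedelta64(2, "D"))
    state = sw.monthly_bin(sw.extract_layer(h, b, sw.SURFACE))
    return g, b, state


@pytest.fixture(scope="session")
def equatorial():
    """All-sea equatorial grid where the lon-lat metric is ~Cartesian."""
    g = sw.make_grid(20, 40, [0.0, 12.0], (-3.0, 3.0, -1.5, 1.5))
    b = sw.synth_bathymetry(g, sw.SyntheticScenario(), flat_depth=12.0)
    return g, b


@pytest.fixture(scope="session")
def vel_span():
    """Timestamps bracketing all release windows used in tests."""
    return np.array(["2000-01-01", "2001-12-31"], dtype="datetime64[s]")
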