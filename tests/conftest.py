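import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from shipplume.grids import SizeGrid
from shipplume.simulate import simulate_event


@pytest.fixture(scope="session")
def grid():
    return SizeGrid()


@pytest.fixture(scope="session")
def small_grid():
    return SizeGrid(n_sections=40)


@pytest.fixture(scope="session")
def traj_summer():
    """Full-length base run of the unstable summer event."""
    return simulate_event("J_20100811", duration=900.0)


@pytest.fixture(scope="session")
def traj_winter():
    """Full-length base run of the stable dark-winter event."""
    return simulate_event("J_20110217", duration=900.0)


@pytest.fixture(scope="session")
def traj_reference():
    """Full-length base run of the reference summer event."""
    return simulate_event("A_20110912", duration=900.0)


@pytest.fixture(scope="session")
def scenario_short_runs():
    """35-s runs of the reference event under the sensitivity scenarios."""
    return {
        sc: simulate_event("A_20110912", scenario=sc, duration=35.0)
        for sc in ("base", "2XSO3", "NUHET", "HSULF")
    }
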