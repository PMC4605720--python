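import pytest
from hypothesis import settings

from hazage.registry_io import AgeGrid, PeriodGrid, RegistryTable, RunConfig, fixture_table
from hazage.synthetic_data import SimulationParams

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def stomach_table() -> RegistryTable:
    """The embedded stomach-cancer (men, all areas, 1975-2009) registry pair."""
    return fixture_table()


@pytest.fixture()
def default_config() -> RunConfig:
    return RunConfig(period_index=4, age_index=11)


@pytest.fixture()
def default_params() -> SimulationParams:
    return SimulationParams(p_true=0.01, seed=0)


@pytest.fixture()
def small_grids() -> tuple[AgeGrid, PeriodGrid]:
    return AgeGrid(n=4), PeriodGrid(J=3)
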