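import numpy as np
import pytest

from elasmoiso import climate, synthetic


@pytest.fixture(scope="session")
def grid_3x() -> climate.ClimateGrid:
    return synthetic.make_climate_grid("3x", seed=0)


@pytest.fixture(scope="session")
def grid_6x() -> climate.ClimateGrid:
    return synthetic.make_climate_grid("6x", seed=0)


@pytest.fixture(scope="session")
def seymour_envelope(grid_3x) -> climate.MonthlyEnvelope:
    return climate.extract_site_series(grid_3x, climate.SEYMOUR_ISLAND)


@pytest.fixture(scope="session")
def envelope_6x(grid_6x) -> climate.MonthlyEnvelope:
    return climate.extract_site_series(grid_6x, climate.SEYMOUR_ISLAND)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
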