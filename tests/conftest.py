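import logging

import numpy as np
import pytest

from isoclim.climate_io import StationSeries
from isoclim.indices import MonthlyClimatology
from isoclim.surfaces import GridSpec
from isoclim.synthetic import ScenarioConfig

logging.disable(logging.WARNING)


def random_climatology(rng: np.random.Generator) -> MonthlyClimatology:
    """A random but physically shaped 12-month climatology."""
    m = np.arange(12)
    seasonal = -np.cos(2 * np.pi * (m + 0.5) / 12.0)
    t = rng.uniform(-5, 20) + rng.uniform(3, 12) * seasonal + rng.normal(0, 1, 12)
    p = np.maximum(rng.uniform(10, 120) * (1 + 0.9 * np.cos(2 * np.pi * (m + 0.5) / 12))
                   + rng.normal(0, 10, 12), 0.0)
    return MonthlyClimatology(t=t, p=p)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_grid():
    return GridSpec(west=-124.0, north=42.0, cell=0.2, n_cols=30, n_rows=30)


@pytest.fixture
def small_cfg(small_grid):
    return ScenarioConfig(seed=11, n_stations=40, grid=small_grid)


@pytest.fixture
def complete_station(rng):
    """A 12-year complete synthetic station."""
    years = np.arange(2000, 2012)
    temp = 10 + 8 * -np.cos(2 * np.pi * (np.arange(12) + 0.5) / 12)[None, :] \
        + rng.normal(0, 0.3, (12, 12))
    precip = np.maximum(50 + rng.normal(0, 5, (12, 12)), 0)
    return StationSeries("T001", -120.0, 38.0, 500.0, years, temp, precip)
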