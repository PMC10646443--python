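import numpy as np
import pandas as pd
import pytest

from rastertrend.raster import AnnualSeries, RasterStack, WetlandMask


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


def make_stack(values, start_year=1982, lat=None, lon=None, variable="NDVI",
               freq="YS"):
    values = np.asarray(values, dtype=float)
    nt, ny, nx = values.shape
    if lat is None:
        lat = np.linspace(44.0, 54.0, ny)
    if lon is None:
        lon = np.linspace(115.0, 135.0, nx)
    time = pd.date_range(f"{start_year}-01-01", periods=nt, freq=freq)
    return RasterStack(values, time, lat, lon, variable=variable)


@pytest.fixture
def random_annual_stack(rng):
    """8 x 5 x 6 annual cube of bounded random values."""
    vals = rng.uniform(0.2, 0.9, size=(8, 5, 6))
    return make_stack(vals)


@pytest.fixture
def full_mask():
    def _make(stack):
        return WetlandMask(np.ones(stack.shape[1:], bool), stack.lat, stack.lon)

    return _make


def series_from(values, start_year=1982, name="NDVI"):
    values = np.asarray(values, dtype=float)
    return AnnualSeries(start_year + np.arange(values.size), values, name)
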