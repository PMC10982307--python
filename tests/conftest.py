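import numpy as np
import pandas as pd
import pytest

import eurosoy as es
from eurosoy.synthetic import DEFAULT_ARCHETYPES


def make_series(tmin, tmax, precip=0.0, srad=20.0, year=2001, n_days=365,
                lat=47.0):
    """Hand-built single-year daily weather series for oracle tests."""
    dates = pd.date_range(f"{year}-01-01", periods=n_days, freq="D")
    df = pd.DataFrame({
        "date": dates,
        "tmin_c": np.broadcast_to(np.asarray(tmin, float), (n_days,)).copy(),
        "tmax_c": np.broadcast_to(np.asarray(tmax, float), (n_days,)).copy(),
        "precip_mm": np.broadcast_to(np.asarray(precip, float), (n_days,)).copy(),
        "srad_mj_m2": np.broadcast_to(np.asarray(srad, float), (n_days,)).copy(),
    })
    df.attrs["lat"] = lat
    return df


def constant_gdu_series(gdu, **kw):
    """Series whose daily GDU is exactly ``gdu`` (via tmin = tmax)."""
    return make_series(10.0 + gdu, 10.0 + gdu, **kw)


@pytest.fixture(scope="session")
def table1():
    return es.load_table1_fixture()


@pytest.fixture(scope="session")
def coeffs():
    return es.ScenarioCoefficients()


def _engine_run(archetype_name, lat, n_years=10, seed=1):
    grid = es.gen_site_grid(1, 1).assign(lat=[lat])
    weather = {0: es.gen_weather(DEFAULT_ARCHETYPES[archetype_name], n_years,
                                 seed=seed, lat=lat)}
    soils = {0: es.gen_soil(seed)}
    return es.run_factorial(grid, weather, soils)


@pytest.fixture(scope="session")
def continental_run():
    """Factorial results for one continental site over 10 years."""
    return _engine_run("continental", lat=47.0)


@pytest.fixture(scope="session")
def subarctic_run():
    """Factorial results for one sub-arctic site over 10 years."""
    return _engine_run("subarctic", lat=60.0)


@pytest.fixture(scope="session")
def mediterranean_run():
    return _engine_run("mediterranean", lat=40.0)
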