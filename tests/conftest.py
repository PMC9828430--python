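import numpy as np
import pandas as pd
import pytest

from switchfor import SiteInfo, generate_soil, generate_weather, preset
from switchfor.soil_water import campbell_parameters


@pytest.fixture(scope="session")
def site():
    return SiteInfo(latitude=36.0, longitude=107.0)


@pytest.fixture(scope="session")
def loam():
    return generate_soil("loam")


@pytest.fixture(scope="session")
def loam_retention(loam):
    return campbell_parameters(loam)


@pytest.fixture(scope="session")
def semiarid_weather(site):
    """Ten years of temperate-continental synthetic forcing."""
    return generate_weather(preset("loess-semiarid"), 10, site, seed=11)


@pytest.fixture(scope="session")
def warm_wet_weather(site):
    """Warm, humid forcing where both ecotypes complete the cycle."""
    return generate_weather(preset("warm-humid"), 6, site, seed=11)


@pytest.fixture(scope="session")
def cold_weather():
    """Strongly continental forcing: >60 dormant-season days below -24 degC."""
    return generate_weather(preset("cold-continental"), 6,
                            SiteInfo(latitude=40.0), seed=11)


def constant_weather(tmean, years=2, diurnal=4.0, precip=10.0, par=8.0,
                     start="2001-01-01"):
    """Degenerate constant forcing for closed-form checks."""
    dates = pd.date_range(start, periods=int(365.25 * years) // 1, freq="D")
    n = len(dates)
    return pd.DataFrame({
        "date": dates,
        "tmin": np.full(n, tmean - diurnal / 2),
        "tmax": np.full(n, tmean + diurnal / 2),
        "precip": np.full(n, float(precip)),
        "solar": np.full(n, 2.0 * par),
        "par": np.full(n, float(par)),
    })
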