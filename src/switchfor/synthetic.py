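"""Parametric synthetic forcing: daily weather, soil profiles, small grids.

Every module of the package is testable without external downloads.  The
weather generator produces a seasonal sinusoid in mean temperature with
AR(1) noise, a fixed diurnal range, a two-state (wet/dry) Markov
occurrence chain with gamma-distributed rain amounts, and solar radiation
as extraterrestrial radiation times a transmissivity that drops on wet
days.  Three presets bracket the climates of interest:

* ``loess-semiarid`` — temperate continental, 9 degC annual mean, 450 mm;
* ``warm-humid`` — 16 degC, 1100 mm, mild winters;
* ``cold-continental`` — 0 degC mean, strong seasonality: winter minima
  sit below -24 degC for well over 60 days, summers still warm enough to
  grow an upland stand.

All randomness flows through a seeded ``numpy.random.Generator``; the same
seed reproduces the same series bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import xarray as xr

from .meteo import SiteInfo, extraterrestrial_radiation, validate_weather
from .soil_water import SoilProfile

__all__ = [
    "ClimateArchetype",
    "PRESETS",
    "preset",
    "generate_weather",
    "generate_soil",
    "generate_grid",
]


@dataclass(frozen=True)
class ClimateArchetype:
    """Statistical description of a daily climate."""

    mean_temp: float           # degC, annual mean
    seasonal_amplitude: float  # degC, half peak-to-trough
    diurnal_range: float       # degC, tmax - tmin
    annual_precip: float       # mm
    wet_day_prob: float        # unconditional wet-day probability
    wet_persistence: float = 0.6   # P(wet | wet yesterday)
    gamma_shape: float = 0.7       # rain-amount distribution
    transmissivity: float = 0.65   # clear-day fraction of extraterrestrial
    wet_day_transmissivity_drop: float = 0.4
    ar1_rho: float = 0.7           # temperature-noise autocorrelation
    ar1_sigma: float = 2.0         # degC, noise innovation scale
    peak_doy: float = 196.0        # day of warmest mean temperature

    def __post_init__(self) -> None:
        if not 0.0 <= self.wet_day_prob <= 1.0:
            raise ValueError("wet_day_prob outside [0, 1]")
        if self.seasonal_amplitude < 0 or self.diurnal_range < 0:
            raise ValueError("amplitudes must be non-negative")


PRESETS: dict[str, ClimateArchetype] = {
    "loess-semiarid": ClimateArchetype(
        mean_temp=9.0, seasonal_amplitude=14.0, diurnal_range=10.0,
        annual_precip=450.0, wet_day_prob=0.25),
    "warm-humid": ClimateArchetype(
        mean_temp=16.0, seasonal_amplitude=9.0, diurnal_range=9.0,
        annual_precip=1100.0, wet_day_prob=0.40),
    "cold-continental": ClimateArchetype(
        mean_temp=0.0, seasonal_amplitude=24.0, diurnal_range=10.0,
        annual_precip=420.0, wet_day_prob=0.25),
}


def preset(name: str) -> ClimateArchetype:
    """Look up a named climate preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; "
                         f"choose from {sorted(PRESETS)}") from None


def generate_weather(archetype: ClimateArchetype, years: int,
                     site: SiteInfo, seed: int,
                     start_year: int = 2001) -> pd.DataFrame:
    """Generate a contiguous daily weather series of ``years`` years.

    Mean temperature is ``mean + A sin(2 pi (doy - phase)/365.25)`` plus
    AR(1) noise; tmin/tmax sit half the diurnal range either side.
    Precipitation occurrence follows a two-state Markov chain calibrated
    to the unconditional wet-day probability and persistence, with gamma
    amounts scaled so the expected annual total matches the archetype.
    The output passes the weather-series invariants by construction.
    """
    if years < 1:
        raise ValueError("need at least one year")
    dates = pd.date_range(f"{start_year}-01-01",
                          f"{start_year + years - 1}-12-31", freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy().astype(float)
    rng = np.random.default_rng(seed)

    phase = archetype.peak_doy - 365.25 / 4.0
    seasonal = archetype.mean_temp + archetype.seasonal_amplitude * np.sin(
        2.0 * np.pi * (doy - phase) / 365.25)
    if site.latitude < 0:
        seasonal = 2.0 * archetype.mean_temp - seasonal  # flip seasons

    noise = np.zeros(n)
    innovations = rng.normal(0.0, archetype.ar1_sigma, size=n)
    for i in range(1, n):
        noise[i] = archetype.ar1_rho * noise[i - 1] + innovations[i]
    tmean = seasonal + noise
    tmin = tmean - archetype.diurnal_range / 2.0
    tmax = tmean + archetype.diurnal_range / 2.0

    # two-state occurrence chain with the requested stationary probability
    p = archetype.wet_day_prob
    p_ww = archetype.wet_persistence
    if p <= 0.0:
        wet = np.zeros(n, dtype=bool)
    else:
        p_wd = np.clip(p * (1.0 - p_ww) / max(1e-9, 1.0 - p), 0.0, 1.0)
        wet = np.zeros(n, dtype=bool)
        u = rng.random(n)
        wet[0] = u[0] < p
        for i in range(1, n):
            wet[i] = u[i] < (p_ww if wet[i - 1] else p_wd)
    precip = np.zeros(n)
    n_wet = int(wet.sum())
    if n_wet:
        expected_wet_per_year = p * 365.25
        mean_amount = archetype.annual_precip / max(1.0,
                                                    expected_wet_per_year)
        scale = mean_amount / archetype.gamma_shape
        precip[wet] = rng.gamma(archetype.gamma_shape, scale, size=n_wet)

    ra = extraterrestrial_radiation(site.latitude, doy)
    tau = archetype.transmissivity * np.where(
        wet, 1.0 - archetype.wet_day_transmissivity_drop, 1.0)
    solar = np.maximum(0.5, ra * tau)

    df = pd.DataFrame({
        "date": dates, "tmin": tmin, "tmax": tmax,
        "precip": precip, "solar": solar,
    })
    return validate_weather(df)


_SOIL_ARCHETYPES = {
    "loam": SoilProfile(sand=0.40, silt=0.40, clay=0.20, soc=0.015,
                        bulk_density=1.35, depth=1000.0),
    "sandy": SoilProfile(sand=0.70, silt=0.20, clay=0.10, soc=0.008,
                         bulk_density=1.55, depth=1000.0),
    "clay": SoilProfile(sand=0.20, silt=0.30, clay=0.50, soc=0.020,
                        bulk_density=1.25, depth=1000.0),
}


def generate_soil(archetype: str = "loam") -> SoilProfile:
    """Textbook soil profile for a named texture archetype (no randomness)."""
    try:
        return _SOIL_ARCHETYPES[archetype]
    except KeyError:
        raise ValueError(f"unknown soil archetype {archetype!r}; "
                         f"choose from {sorted(_SOIL_ARCHETYPES)}") from None


def generate_grid(nx: int, ny: int, base: ClimateArchetype, years: int,
                  seed: int, temperature_gradient: float = 0.0,
                  precip_gradient: float = 0.0,
                  base_latitude: float = 36.0, cell_degrees: float = 0.25,
                  soil_archetype: str = "loam",
                  start_year: int = 2001) -> xr.Dataset:
    """Synthetic climate cube plus soil, slope and mask rasters.

    Row 0 is the northern edge; each row southward shifts the archetype's
    mean temperature by ``temperature_gradient`` degC and its annual
    precipitation by ``precip_gradient`` mm (so a negative temperature
    gradient makes the north cold).  Per-cell weather uses independent
    substreams of ``seed``, so the cube is reproducible and a 1x1 grid
    equals single-site generation with the same seed.

    Returns an ``xarray.Dataset`` with dims ``(time, y, x)`` for tmin,
    tmax, precip, solar; 2-D soil bands (sand, silt, clay, soc,
    bulk_density); a flat ``slope`` raster (degrees) and an all-ones
    ``mask``; latitude/longitude coordinates on a north-up grid.
    """
    if nx < 1 or ny < 1:
        raise ValueError("grid must be at least 1x1")
    lats = base_latitude - cell_degrees * np.arange(ny)  # north-up
    lons = 107.0 + cell_degrees * np.arange(nx)
    dates = pd.date_range(f"{start_year}-01-01",
                          f"{start_year + years - 1}-12-31", freq="D")
    nt = len(dates)

    fields = {k: np.zeros((nt, ny, nx)) for k in
              ("tmin", "tmax", "precip", "solar")}
    for j in range(ny):
        for i in range(nx):
            cell = replace(
                base,
                mean_temp=base.mean_temp + temperature_gradient * j,
                annual_precip=max(0.0,
                                  base.annual_precip + precip_gradient * j))
            cell_seed = seed if (nx == 1 and ny == 1) else (
                seed + 7919 * j + 104729 * i)
            wx = generate_weather(cell, years,
                                  SiteInfo(latitude=float(lats[j]),
                                           longitude=float(lons[i])),
                                  cell_seed, start_year=start_year)
            for k in fields:
                fields[k][:, j, i] = wx[k].to_numpy()

    soil = _SOIL_ARCHETYPES[soil_archetype]
    ones = np.ones((ny, nx))
    ds = xr.Dataset(
        data_vars={
            **{k: (("time", "y", "x"), v) for k, v in fields.items()},
            "sand": (("y", "x"), soil.sand * ones),
            "silt": (("y", "x"), soil.silt * ones),
            "clay": (("y", "x"), soil.clay * ones),
            "soc": (("y", "x"), soil.soc * ones),
            "bulk_density": (("y", "x"), soil.bulk_density * ones),
            "slope": (("y", "x"), np.zeros((ny, nx))),
            "mask": (("y", "x"), ones),
        },
        coords={"time": dates, "lat": ("y", lats), "lon": ("x", lons)},
        attrs={"soil_depth_mm": soil.depth, "seed": seed},
    )
    return ds
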