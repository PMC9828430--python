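"""Daily meteorological forcing: temperature statistics, thermal time,
photoperiod, radiation and potential evapotranspiration.

The simulator is driven by a daily series of minimum/maximum air
temperature, precipitation, global solar radiation (or PAR directly) and,
optionally, wind speed and humidity.  This module derives everything the
plant and soil routines need from that series:

* mean temperature and degree days above a base temperature (the thermal
  clock of the phenology state machine),
* astronomical day length (the photoperiod trigger),
* photosynthetically active radiation as a fixed fraction of global
  radiation,
* potential evapotranspiration (PET) by the FAO-56 Penman-Monteith
  reference method when wind and humidity are available, or by the
  Thornthwaite (1948) monthly method otherwise.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SiteInfo",
    "WEATHER_COLUMNS",
    "read_weather",
    "validate_weather",
    "daily_mean_temperature",
    "degree_days",
    "day_length",
    "solar_declination",
    "extraterrestrial_radiation",
    "par_from_solar",
    "pet_thornthwaite",
    "pet_penman_monteith",
    "InsufficientInputs",
    "prepare_forcing",
]

#: canonical column order for a daily weather frame
WEATHER_COLUMNS = ("date", "tmin", "tmax", "precip", "solar",
                   "par", "pet", "wind", "rh", "ea")

#: default PAR fraction of global shortwave radiation
DEFAULT_PAR_FRACTION = 0.5

SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1


class InsufficientInputs(ValueError):
    """Raised when a PET method lacks the forcing variables it needs."""


@dataclass(frozen=True)
class SiteInfo:
    """Geographic location of a simulated site.

    Parameters
    ----------
    latitude : float
        Degrees north, in [-90, 90].
    longitude : float
        Degrees east.
    elevation : float, optional
        Metres above sea level; used for the barometric pressure in the
        Penman-Monteith method.  Defaults to 0.
    """

    latitude: float
    longitude: float = 0.0
    elevation: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")


def daily_mean_temperature(tmin, tmax):
    """Arithmetic daily mean temperature, (Tmin + Tmax) / 2 (deg C).

    Raises ``ValueError`` if ``tmin > tmax`` anywhere.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin exceeds tmax")
    out = (tmin + tmax) / 2.0
    return float(out) if out.ndim == 0 else out


def degree_days(tmean_series, base: float) -> np.ndarray:
    """Cumulative degree days above ``base`` (deg C day).

    Element ``i`` is ``sum_{j<=i} max(0, tmean_j - base)``; the result is
    non-decreasing.  An empty series is rejected.
    """
    t = np.asarray(tmean_series, dtype=float)
    if t.size == 0:
        raise ValueError("empty temperature series")
    return np.cumsum(np.maximum(0.0, t - base))


def solar_declination(doy) -> np.ndarray:
    """Solar declination in radians for day of year ``doy`` (CBM form)."""
    doy = np.asarray(doy, dtype=float)
    return np.deg2rad(-23.44 * np.cos(2.0 * np.pi * (doy + 10.0) / 365.0))


def day_length(latitude: float, doy) -> np.ndarray:
    """Astronomical day length in hours.

    Standard sunrise-geometry: ``cos h = -tan(phi) tan(delta)`` with the
    hour angle clamped for polar day/night.  Returns values in [0, 24].
    """
    if abs(latitude) > 90.0:
        raise ValueError("latitude outside [-90, 90]")
    phi = np.deg2rad(latitude)
    delta = solar_declination(doy)
    cos_h = -np.tan(phi) * np.tan(delta)
    cos_h = np.clip(cos_h, -1.0, 1.0)
    hours = 24.0 / np.pi * np.arccos(cos_h)
    return float(hours) if np.ndim(hours) == 0 else hours


def extraterrestrial_radiation(latitude: float, doy) -> np.ndarray:
    """Daily extraterrestrial shortwave radiation Ra (MJ m-2 day-1).

    FAO-56 formulation with inverse relative Earth-Sun distance and the
    sunset hour angle.
    """
    doy = np.asarray(doy, dtype=float)
    phi = np.deg2rad(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = solar_declination(doy)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(phi) * np.sin(delta)
        + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    ra = np.maximum(ra, 0.0)
    return float(ra) if np.ndim(ra) == 0 else ra


def par_from_solar(solar, f_par: float = DEFAULT_PAR_FRACTION):
    """PAR as a fixed fraction of global radiation (MJ m-2 day-1)."""
    solar = np.asarray(solar, dtype=float)
    if np.any(solar < 0.0):
        raise ValueError("negative global radiation")
    out = f_par * solar
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Thornthwaite (1948) monthly PET
# ---------------------------------------------------------------------------

def pet_thornthwaite(dates, tmean, latitude: float) -> np.ndarray:
    """Daily PET series by the Thornthwaite (1948) monthly method.

    Monthly PET (mm) is ``16 (L/12) (N/30) (10 T / I)^a`` with the annual
    heat index ``I`` formed per calendar year, zero for months with mean
    temperature <= 0 degC, and distributed uniformly over each month's
    days.  ``L`` is the month-mean day length and ``N`` the true month
    length (leap-aware).  At least a full year of data is required.

    Parameters
    ----------
    dates : datetime-like sequence, contiguous daily
    tmean : deg C, same length
    latitude : degrees
    """
    dates = pd.DatetimeIndex(dates)
    tmean = np.asarray(tmean, dtype=float)
    if len(dates) != len(tmean):
        raise ValueError("dates and tmean length mismatch")
    if len(dates) < 365:
        raise ValueError("Thornthwaite needs at least one year of data")

    df = pd.DataFrame({"tmean": tmean}, index=dates)
    monthly = df["tmean"].resample("MS").mean()

    pet_daily = np.zeros(len(dates))
    for year, tm in monthly.groupby(monthly.index.year):
        tpos = np.maximum(tm.to_numpy(), 0.0)
        heat_index = np.sum((tpos / 5.0) ** 1.514)
        if heat_index <= 0.0:
            continue
        a = (6.75e-7 * heat_index**3 - 7.71e-5 * heat_index**2
             + 1.792e-2 * heat_index + 0.49239)
        for month_start, t_month in tm.items():
            if t_month <= 0.0:
                continue
            n_days = calendar.monthrange(year, month_start.month)[1]
            doys = pd.date_range(month_start, periods=n_days).dayofyear
            mean_daylen = float(np.mean(day_length(latitude, doys)))
            pet_month = (16.0 * (mean_daylen / 12.0) * (n_days / 30.0)
                         * (10.0 * t_month / heat_index) ** a)
            sel = (dates.year == year) & (dates.month == month_start.month)
            pet_daily[sel] = pet_month / n_days
    return pet_daily


# ---------------------------------------------------------------------------
# FAO-56 Penman-Monteith reference evapotranspiration
# ---------------------------------------------------------------------------

def _saturation_vapour_pressure(t: np.ndarray) -> np.ndarray:
    """Tetens saturation vapour pressure (kPa) at temperature t (deg C)."""
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def pet_penman_monteith(dates, tmin, tmax, solar, wind, site: SiteInfo,
                        rh=None, ea=None) -> np.ndarray:
    """Daily FAO-56 reference (grass) evapotranspiration, mm day-1.

    Requires wind speed at 2 m (m s-1) and humidity, either as mean
    relative humidity ``rh`` (%) or actual vapour pressure ``ea`` (kPa).
    Net radiation is derived from measured global radiation with albedo
    0.23 and the FAO-56 clear-sky and net-longwave formulation; soil heat
    flux is taken as zero at the daily step.

    Raises
    ------
    InsufficientInputs
        if wind or humidity is missing (caller should fall back to
        Thornthwaite).
    """
    if wind is None or (ea is None and rh is None):
        raise InsufficientInputs("Penman-Monteith needs wind and humidity")

    dates = pd.DatetimeIndex(dates)
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    rs = np.asarray(solar, dtype=float)
    u2 = np.asarray(wind, dtype=float)
    tmean = (tmin + tmax) / 2.0

    es = (_saturation_vapour_pressure(tmax)
          + _saturation_vapour_pressure(tmin)) / 2.0
    if ea is not None:
        ea = np.asarray(ea, dtype=float)
    else:
        ea = np.asarray(rh, dtype=float) / 100.0 * es
    ea = np.minimum(ea, es)

    delta = (4098.0 * _saturation_vapour_pressure(tmean)
             / (tmean + 237.3) ** 2)
    pressure = 101.3 * ((293.0 - 0.0065 * site.elevation) / 293.0) ** 5.26
    gamma = 0.665e-3 * pressure

    doy = dates.dayofyear.to_numpy()
    ra = extraterrestrial_radiation(site.latitude, doy)
    rso = (0.75 + 2e-5 * site.elevation) * ra
    rns = (1.0 - 0.23) * rs
    sigma = 4.903e-9  # MJ K-4 m-2 day-1
    # relative shortwave bounded below per FAO-56 guidance for dark/overcast
    # conditions, so net longwave cannot turn into a spurious energy gain
    rel = np.clip(np.divide(rs, rso, out=np.ones_like(rs),
                            where=rso > 0), 0.3, 1.0)
    rnl = (sigma * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0
           * (0.34 - 0.14 * np.sqrt(ea))
           * (1.35 * rel - 0.35))
    rn = rns - rnl

    et0 = ((0.408 * delta * rn
            + gamma * 900.0 / (tmean + 273.0) * u2 * (es - ea))
           / (delta + gamma * (1.0 + 0.34 * u2)))
    return np.maximum(et0, 0.0)


# ---------------------------------------------------------------------------
# Weather frame handling
# ---------------------------------------------------------------------------

def validate_weather(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a daily weather frame.

    Enforces the series invariants: contiguous daily dates without
    duplicates, tmin <= tmax, non-negative precipitation, and PAR not
    exceeding global radiation where both are present.  Derives ``tmean``
    and ``par`` when absent.  Returns a copy with a clean RangeIndex.
    """
    required = {"date", "tmin", "tmax", "precip"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weather frame missing columns: {sorted(missing)}")
    if "solar" not in df.columns and "par" not in df.columns:
        raise ValueError("weather frame needs 'solar' or 'par'")

    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    if df["date"].duplicated().any():
        raise ValueError("duplicate dates in weather series")
    df = df.sort_values("date").reset_index(drop=True)
    deltas = df["date"].diff().dropna()
    if len(deltas) and not (deltas == pd.Timedelta(days=1)).all():
        raise ValueError("weather series is not contiguous daily")

    if np.any(df["tmin"].to_numpy() > df["tmax"].to_numpy()):
        raise ValueError("tmin exceeds tmax")
    if np.any(df["precip"].to_numpy() < 0.0):
        raise ValueError("negative precipitation")
    if "tmean" not in df.columns:
        df["tmean"] = daily_mean_temperature(df["tmin"], df["tmax"])
    if "par" not in df.columns:
        df["par"] = par_from_solar(df["solar"])
    elif "solar" in df.columns:
        if np.any(df["par"].to_numpy() > df["solar"].to_numpy() + 1e-9):
            raise ValueError("PAR exceeds global radiation")
    return df


def read_weather(path) -> pd.DataFrame:
    """Read a delimited daily weather file.

    Expects a header ``date,tmin,tmax,precip,solar[,par][,pet][,wind][,rh]``
    with ISO-8601 dates; optional columns may be absent.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return validate_weather(df)


def prepare_forcing(weather: pd.DataFrame, site: SiteInfo,
                    pet_method: str = "auto",
                    f_par: float = DEFAULT_PAR_FRACTION) -> pd.DataFrame:
    """Complete a weather frame with every derived forcing the simulator needs.

    Adds ``tmean``, ``par``, ``doy``, ``day_length`` and ``pet``.  PET
    selection: ``"auto"`` uses Penman-Monteith when wind and humidity
    columns are present and Thornthwaite otherwise; ``"penman_monteith"``
    and ``"thornthwaite"`` force a method.  The chosen method is recorded
    in ``df.attrs["pet_method"]``.
    """
    df = validate_weather(weather)
    if "par" not in df.columns:
        df["par"] = par_from_solar(df["solar"], f_par)
    dates = pd.DatetimeIndex(df["date"])
    df["doy"] = dates.dayofyear
    df["day_length"] = day_length(site.latitude, df["doy"].to_numpy())

    if "pet" in df.columns and df["pet"].notna().all():
        df.attrs["pet_method"] = "provided"
        return df

    has_pm_inputs = ("wind" in df.columns and
                     ("rh" in df.columns or "ea" in df.columns) and
                     "solar" in df.columns)
    if pet_method == "auto":
        pet_method = "penman_monteith" if has_pm_inputs else "thornthwaite"
    if pet_method == "penman_monteith":
        if not has_pm_inputs:
            raise InsufficientInputs(
                "Penman-Monteith requested but wind/humidity missing")
        df["pet"] = pet_penman_monteith(
            dates, df["tmin"], df["tmax"], df["solar"], df["wind"], site,
            rh=df["rh"] if "rh" in df.columns else None,
            ea=df["ea"] if "ea" in df.columns else None)
    elif pet_method == "thornthwaite":
        df["pet"] = pet_thornthwaite(dates, df["tmean"], site.latitude)
    else:
        raise ValueError(f"unknown PET method {pet_method!r}")
    df.attrs["pet_method"] = pet_method
    return df
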