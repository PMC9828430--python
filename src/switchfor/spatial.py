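"""Gridded yield mapping: per-cell simulation, optimal-ecotype maps,
marginal-land masking and area-weighted totals.

A climate cube is an ``xarray.Dataset`` with daily weather variables on
``(time, y, x)`` and co-registered 2-D soil bands (see
``switchfor.synthetic.generate_grid`` for the layout).  ``run_grid``
executes the site simulator in every cell and returns a ``YieldRaster``;
``optimal_map`` takes the cell-wise best ecotype; ``apply_mask`` removes
cells outside the land mask or steeper than a slope limit; and
``aggregate_totals`` turns a raster into regional totals.

NoData is IEEE NaN throughout.  Cells where the stand suffers plant death
in at least a configurable fraction of simulated seasons are outside the
ecotype's adaptation zone and set to NoData.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr

from .meteo import SiteInfo
from .simulator import GenotypeParams, mean_annual_yield, run_site
from .soil_water import SoilProfile

__all__ = [
    "YieldRaster",
    "run_grid",
    "optimal_map",
    "apply_mask",
    "aggregate_totals",
    "cell_areas_ha",
    "ECOTYPE_CODES",
]

ECOTYPE_CODES = {"upland": 0, "lowland": 1}

_EARTH_RADIUS_KM = 6371.0


@dataclass
class YieldRaster:
    """Per-cell mean yield with optional winning-ecotype labels.

    ``values`` is Mg ha-1 with NaN for NoData; ``ecotype`` carries the
    integer code of the winning ecotype (0 upland, 1 lowland) where a
    yield exists.  ``lat``/``lon`` are the cell-centre coordinates of a
    north-up grid.
    """

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    ecotype: Optional[np.ndarray] = None
    cell_degrees: float = field(default=0.25)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lat), len(self.lon)):
            raise ValueError("values shape does not match coordinates")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("yields must be >= 0 or NaN")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def _check_registered(self, other: "YieldRaster") -> None:
        if (self.shape != other.shape
                or not np.allclose(self.lat, other.lat)
                or not np.allclose(self.lon, other.lon)):
            raise ValueError("rasters are not co-registered")


def run_grid(cube: xr.Dataset, params: GenotypeParams,
             period: Optional[tuple[int, int]] = None,
             max_kill_fraction: float = 0.0,
             pet_method: str = "auto") -> YieldRaster:
    """Run the site simulator in every cell of a climate cube.

    Each cell's value is the mean annual harvested yield over ``period``
    (all complete seasons when None).  Cells where the fraction of
    seasons with a plant-death event exceeds ``max_kill_fraction``
    (default: any plant death disqualifies) are NoData — the ecotype is
    not adapted there.
    """
    required = {"tmin", "tmax", "precip", "solar", "sand", "silt", "clay",
                "soc", "bulk_density"}
    missing = required - set(cube.data_vars)
    if missing:
        raise ValueError(f"climate cube missing layers: {sorted(missing)}")
    ny = cube.sizes["y"]
    nx = cube.sizes["x"]
    lats = cube["lat"].to_numpy()
    lons = cube["lon"].to_numpy()
    depth = float(cube.attrs.get("soil_depth_mm", 1000.0))
    dates = pd.DatetimeIndex(cube["time"].to_numpy())

    values = np.full((ny, nx), np.nan)
    for j in range(ny):
        for i in range(nx):
            weather = pd.DataFrame({
                "date": dates,
                "tmin": cube["tmin"].values[:, j, i],
                "tmax": cube["tmax"].values[:, j, i],
                "precip": cube["precip"].values[:, j, i],
                "solar": cube["solar"].values[:, j, i],
            })
            soil = SoilProfile(
                sand=float(cube["sand"].values[j, i]),
                silt=float(cube["silt"].values[j, i]),
                clay=float(cube["clay"].values[j, i]),
                soc=float(cube["soc"].values[j, i]),
                bulk_density=float(cube["bulk_density"].values[j, i]),
                depth=depth)
            site = SiteInfo(latitude=float(lats[j]),
                            longitude=float(lons[i]))
            result = run_site(weather, site, soil, params,
                              pet_method=pet_method)
            annual = result.annual
            if period is not None:
                annual = annual[(annual["year"] >= period[0])
                                & (annual["year"] <= period[1])]
            if annual.empty:
                continue
            deaths = annual["kill_event"].fillna("").str.contains(
                "plant_death|winter kill").sum()
            if deaths / len(annual) > max_kill_fraction:
                continue  # not adapted: NoData
            values[j, i] = float(annual["harvest_yield"].mean())

    ecotype = np.where(np.isfinite(values),
                       float(ECOTYPE_CODES[params.ecotype]), np.nan)
    cell_deg = float(abs(lats[0] - lats[1])) if ny > 1 else 0.25
    return YieldRaster(values=values, lat=lats, lon=lons,
                       ecotype=ecotype, cell_degrees=cell_deg)


def optimal_map(upland: YieldRaster, lowland: YieldRaster) -> YieldRaster:
    """Cell-wise best ecotype: the higher yield wins, labelled.

    NoData only where both inputs are NoData; a cell one ecotype cannot
    occupy passes the other through.  Exact ties go to upland (the more
    widely adapted ecotype).
    """
    upland._check_registered(lowland)
    up = upland.values
    low = lowland.values
    up_f = np.where(np.isnan(up), -np.inf, up)
    low_f = np.where(np.isnan(low), -np.inf, low)
    lowland_wins = low_f > up_f  # ties -> upland
    values = np.where(lowland_wins, low_f, up_f)
    values = np.where(np.isinf(values), np.nan, values)
    ecotype = np.where(np.isnan(values), np.nan,
                       np.where(lowland_wins,
                                float(ECOTYPE_CODES["lowland"]),
                                float(ECOTYPE_CODES["upland"])))
    return YieldRaster(values=values, lat=upland.lat, lon=upland.lon,
                       ecotype=ecotype, cell_degrees=upland.cell_degrees)


def apply_mask(yields: YieldRaster, mask: np.ndarray,
               slope: Optional[np.ndarray] = None,
               slope_limit: float = 15.0) -> YieldRaster:
    """Restrict a yield raster to masked, sufficiently flat land.

    Cells with a falsy/zero mask, or slope strictly greater than
    ``slope_limit`` degrees, become NoData.
    """
    mask = np.asarray(mask)
    if mask.shape != yields.shape:
        raise ValueError("mask shape mismatch")
    keep = mask.astype(bool)
    if slope is not None:
        slope = np.asarray(slope, dtype=float)
        if slope.shape != yields.shape:
            raise ValueError("slope shape mismatch")
        keep &= slope <= slope_limit
    values = np.where(keep, yields.values, np.nan)
    ecotype = (np.where(keep, yields.ecotype, np.nan)
               if yields.ecotype is not None else None)
    return YieldRaster(values=values, lat=yields.lat, lon=yields.lon,
                       ecotype=ecotype, cell_degrees=yields.cell_degrees)


def cell_areas_ha(raster: YieldRaster,
                  constant_area_ha: Optional[float] = None) -> np.ndarray:
    """Per-cell area in hectares.

    Geographic grids use the cosine rule — a cell of ``d`` degrees spans
    ``(pi R d / 180)^2 cos(lat)`` — unless a constant equal-area cell size
    is given.
    """
    ny, nx = raster.shape
    if constant_area_ha is not None:
        return np.full((ny, nx), float(constant_area_ha))
    d = raster.cell_degrees
    km_per_deg = np.pi * _EARTH_RADIUS_KM / 180.0
    areas_km2 = (d * km_per_deg) ** 2 * np.cos(np.deg2rad(raster.lat))
    return np.repeat(areas_km2[:, None] * 100.0, nx, axis=1)  # km2 -> ha


def aggregate_totals(yields: YieldRaster,
                     cell_area_ha=None) -> dict:
    """Region totals over the non-NoData cells.

    Returns ``total_tg`` (sum of yield x area, Tg), ``weighted_mean``
    (area-weighted Mg ha-1, NaN if no live cells), ``area_mha`` (million
    ha of live cells) and ``n_cells``.  ``cell_area_ha`` may be a scalar,
    a full array, or None for the cosine-rule geographic default.
    """
    if cell_area_ha is None:
        areas = cell_areas_ha(yields)
    elif np.ndim(cell_area_ha) == 0:
        areas = np.full(yields.shape, float(cell_area_ha))
    else:
        areas = np.asarray(cell_area_ha, dtype=float)
        if areas.shape != yields.shape:
            raise ValueError("cell_area_ha shape mismatch")
    live = np.isfinite(yields.values)
    mass_mg = np.sum(yields.values[live] * areas[live])  # Mg
    area_ha = float(np.sum(areas[live]))
    return {
        "total_tg": float(mass_mg * 1e-6),
        "weighted_mean": float(mass_mg / area_ha) if area_ha > 0
        else float("nan"),
        "area_mha": area_ha * 1e-6,
        "n_cells": int(live.sum()),
    }
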