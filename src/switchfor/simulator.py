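"""Genotype parameter registry and the daily site-simulation loop.

A simulation season runs from the spring harvest/reset date (1 March in
the northern hemisphere by default) to the next one.  Each day executes,
in order: meteorological forcing, the soil-water bucket, the physiostat
state machine, canopy/dry-matter dynamics, and event checks (drought and
frost kill in season, winter kill over the dormant season).  At the
harvest date the standing crop of the closing season is booked as
``harvest_ratio x peak dry matter`` (absent kill events) and the clocks
reset.

Genotype defaults encode the two switchgrass ecotypes:

===================  ========  ========
parameter            lowland   upland
===================  ========  ========
DD10 stages 1-5      105/168/  80/125/
                     1174/     1085/
                     1566/1694 1395/1488
k                    0.36      0.36
LAI max              12        7
DD-LAI factor        0.004     0.006
LAI senescence       0.03      0.049
RUE max (g/MJ)       5.05      3.19
T opt (degC)         28        23
winter kill (degC)   -23.3     -34.4
harvest ratio        0.832     0.832
===================  ========  ========
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import soil_water as sw
from .canopy import (CanopyParams, daily_dm_increment, fraction_intercepted,
                     temperature_variation_factor, update_lai)
from .events import (HarvestParams, KillRules, harvestable_yield,
                     soil_temperature_10cm)
from .meteo import SiteInfo, prepare_forcing
from .phenology import (PhenologyTriggers, PhysiostatThresholds, PlantState,
                        advance_physiostat, annual_reset)
from .soil_water import SoilProfile

__all__ = [
    "GenotypeParams",
    "SimulationResult",
    "genotype_defaults",
    "apply_overrides",
    "run_site",
    "mean_annual_yield",
]


@dataclass(frozen=True)
class GenotypeParams:
    """Every ecotype-specific constant of the model, in one place."""

    name: str
    ecotype: str  # "upland" or "lowland"
    thresholds: PhysiostatThresholds
    canopy: CanopyParams
    kill: KillRules
    harvest: HarvestParams
    psi_full: float = sw.PSI_FC          # kPa, stress factor = 1
    psi_stop_lai: float = -1000.0        # kPa, leaf expansion stops
    psi_stop_rue: float = sw.PSI_WP      # kPa, photosynthesis stops
    emergence_psi: float = -300.0        # kPa gate on shoot emergence
    base_temp_physiostat: float = 10.0   # degC
    base_temp_lai: float = 0.0           # degC
    t_leaf_window: int = 30              # days, leaf-formation mean T
    photoperiod_enabled: bool = False
    photoperiod_hours: float = 12.5
    k_aet: float = sw.DEFAULT_K_AET
    bare_soil_fraction: float = sw.DEFAULT_BARE_SOIL_FRACTION

    def __post_init__(self) -> None:
        if self.ecotype not in ("upland", "lowland"):
            raise ValueError("ecotype must be 'upland' or 'lowland'")
        if not self.psi_stop_rue <= self.psi_stop_lai < self.psi_full < 0:
            raise ValueError("stress potentials must order "
                             "psi_stop_rue <= psi_stop_lai < psi_full < 0")


_DEFAULTS = {
    "lowland": dict(
        name="Alamo", dd_stage=(105.0, 168.0, 1174.0, 1566.0, 1694.0),
        lai_max=12.0, dd_lai_factor=0.004, lai_senescence_rate=0.03,
        rue_max=5.05, t_opt=28.0, t_kill=-23.3),
    "upland": dict(
        name="Cave-In-Rock", dd_stage=(80.0, 125.0, 1085.0, 1395.0, 1488.0),
        lai_max=7.0, dd_lai_factor=0.006, lai_senescence_rate=0.049,
        rue_max=3.19, t_opt=23.0, t_kill=-34.4),
}


def genotype_defaults(ecotype: str) -> GenotypeParams:
    """Default parameter set for an ecotype ("upland" or "lowland")."""
    try:
        d = _DEFAULTS[ecotype]
    except KeyError:
        raise ValueError(f"unknown ecotype {ecotype!r}; "
                         "choose 'upland' or 'lowland'") from None
    return GenotypeParams(
        name=d["name"], ecotype=ecotype,
        thresholds=PhysiostatThresholds(dd_stage=d["dd_stage"]),
        canopy=CanopyParams(
            k=0.36, lai_max=d["lai_max"], dd_lai_factor=d["dd_lai_factor"],
            lai_senescence_rate=d["lai_senescence_rate"],
            rue_max=d["rue_max"], t_opt=d["t_opt"]),
        kill=KillRules(t_kill=d["t_kill"]),
        harvest=HarvestParams(),
    )


def apply_overrides(params: GenotypeParams, overrides: dict
                    ) -> GenotypeParams:
    """Return a copy of ``params`` with (possibly nested) field overrides.

    ``overrides`` maps top-level field names to values; for the nested
    dataclass fields (``thresholds``, ``canopy``, ``kill``, ``harvest``)
    a dict value is merged field-by-field.
    """
    updates = {}
    for key, value in overrides.items():
        current = getattr(params, key)  # KeyError -> AttributeError surface
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            updates[key] = replace(current, **value)
        else:
            updates[key] = value
    return replace(params, **updates)


@dataclass
class AnnualRecord:
    """One growing season's bookkeeping."""

    year: int
    peak_dm: float
    harvest_yield: float
    kill_event: Optional[str] = None
    establishment: bool = False


@dataclass
class SimulationResult:
    """Daily trajectory plus per-season records and run metadata."""

    daily: pd.DataFrame
    annual: pd.DataFrame
    genotype: str
    ecotype: str
    site: SiteInfo
    pet_method: str
    initial_swc: float = float("nan")  # mm, bucket storage before day one

    @property
    def years(self) -> np.ndarray:
        return self.annual["year"].to_numpy()


def _after_solstice(doy: int, latitude: float) -> bool:
    """Autumn side of the summer solstice for the site's hemisphere."""
    if latitude >= 0.0:
        return doy > 172
    return doy > 355 or doy <= 80


def run_site(weather: pd.DataFrame, site: SiteInfo, soil: SoilProfile,
             params: GenotypeParams, pet_method: str = "auto",
             initial_soil_fraction: float = 1.0) -> SimulationResult:
    """Run the daily model over a contiguous multi-year weather series.

    Deterministic given its inputs.  Seasons run harvest-date to
    harvest-date; only seasons whose harvest falls inside the series are
    booked in ``result.annual``.  The first booked season is flagged as the
    establishment year, as is the replant season after any plant death
    (which is also forced to zero yield).
    """
    forcing = prepare_forcing(weather, site, pet_method=pet_method)
    retention = sw.campbell_parameters(soil)
    depth = soil.depth

    dates = pd.DatetimeIndex(forcing["date"])
    tmean = forcing["tmean"].to_numpy()
    tmin = forcing["tmin"].to_numpy()
    precip = forcing["precip"].to_numpy()
    par = forcing["par"].to_numpy()
    pet = forcing["pet"].to_numpy()
    daylen = forcing["day_length"].to_numpy()
    doy = forcing["doy"].to_numpy()
    n = len(dates)

    t_leaf_series = (pd.Series(tmean)
                     .rolling(params.t_leaf_window, min_periods=1)
                     .mean().to_numpy())
    soil_t10 = soil_temperature_10cm(tmean)
    dd10_inc = np.maximum(0.0, tmean - params.base_temp_physiostat)
    dd0_inc = np.maximum(0.0, tmean - params.base_temp_lai)

    is_harvest_day = ((dates.month == params.harvest.harvest_month)
                      & (dates.day == params.harvest.harvest_day))
    dormant_start_month = 11 if site.latitude >= 0 else 5

    water = sw.initial_state(retention, depth, initial_soil_fraction)
    initial_swc = water.swc
    plant = PlantState()
    kill = params.kill

    season_year = int(dates[0].year)
    season_open = False            # becomes True at the first reset
    season_event: Optional[str] = None
    season_peak = 0.0
    establishment_next = True      # first booked season is establishment
    force_zero_next = False        # replant season after plant death
    replant_pending = False
    drought_run = 0
    frost_run = 0
    cold_days = 0
    in_dormant_window = False
    decline_per_day = 0.0
    harvest_value = 0.0

    annual: list[AnnualRecord] = []
    day_rows = {k: np.zeros(n) for k in
                ("stage", "dd10", "lai", "dm", "swc", "psi", "aet",
                 "drainage")}

    harvest_dates = dates[is_harvest_day]

    def days_to_next_harvest(i: int) -> int:
        later = harvest_dates[harvest_dates > dates[i]]
        if len(later):
            return int((later[0] - dates[i]).days)
        return int((dates[-1] - dates[i]).days) + 1

    for i in range(n):
        # --- season close / annual reset at the harvest date -------------
        if is_harvest_day[i]:
            if season_open:
                winter_killed, winter_cause = False, None
                if plant.alive and cold_days >= kill.kill_day_threshold:
                    winter_killed = True
                    winter_cause = (f"winter kill ({kill.winterkill_mode}"
                                    f", {cold_days} days)")
                if winter_killed and season_event is None:
                    # stand dead over the dormant season: harvest lost
                    season_event = winter_cause
                if force_zero_next and season_event is None:
                    season_event = "replant_after_kill"
                killed = (season_event is not None
                          and season_event != "shoot_death"
                          and "frost" not in season_event)
                yield_mg = (0.0 if killed
                            else harvestable_yield(season_peak,
                                                   params.harvest))
                annual.append(AnnualRecord(
                    year=season_year, peak_dm=season_peak,
                    harvest_yield=yield_mg, kill_event=season_event,
                    establishment=establishment_next))
                establishment_next = False
                force_zero_next = False
                if season_event == "plant_death" or winter_killed:
                    # replant in spring; the replant season carries no
                    # harvestable yield either
                    replant_pending = True
                    force_zero_next = True
            if replant_pending:
                plant = PlantState(alive=True)   # replanted in spring
                establishment_next = True
                replant_pending = False
            else:
                plant = annual_reset(plant)
            season_year = int(dates[i].year)
            season_open = True
            season_event = None
            season_peak = 0.0
            drought_run = 0
            frost_run = 0
            cold_days = 0
            in_dormant_window = False
            decline_per_day = 0.0
            harvest_value = 0.0

        # --- soil water ---------------------------------------------------
        water, aet, drain = sw.update_water_balance(
            water, precip[i], pet[i], plant.lai, retention, depth,
            params.psi_full, params.psi_stop_rue,
            params.k_aet, params.bare_soil_fraction)
        f_lai = sw.downregulation_factor(water.psi, params.psi_full,
                                         params.psi_stop_lai)
        f_rue = sw.downregulation_factor(water.psi, params.psi_full,
                                         params.psi_stop_rue)

        # --- phenology ----------------------------------------------------
        stage_before = plant.stage
        triggers = PhenologyTriggers(
            psi=water.psi, tmean=tmean[i], tmin=tmin[i],
            day_length=daylen[i],
            after_solstice=_after_solstice(int(doy[i]), site.latitude))
        plant = advance_physiostat(
            plant, dd10_inc[i], triggers, params.thresholds,
            params.canopy.lai_max, params.emergence_psi,
            params.psi_stop_lai,
            photoperiod_enabled=params.photoperiod_enabled,
            photoperiod_hours=params.photoperiod_hours, date=dates[i])
        plant = replace(plant, dd0=plant.dd0 + dd0_inc[i],
                        t_leaf=t_leaf_series[i])

        # --- in-season kill events (before canopy growth) -----------------
        if plant.alive and 1 <= plant.stage <= 4:
            if water.psi <= kill.psi_plant_death and season_event is None:
                season_event = "plant_death"
                plant = replace(plant, alive=False, lai=0.0, dm=0.0)
            else:
                drought_run = (drought_run + 1
                               if water.psi < kill.psi_shoot_death else 0)
                if (season_event is None and plant.stage <= 3
                        and drought_run >= kill.drought_kill_days):
                    season_event = "shoot_death"
                    plant = replace(plant, stage=4, peak_dm=plant.dm,
                                    peak_lai=plant.lai,
                                    stage4_onset=dates[i])
            if plant.alive and 1 <= plant.stage <= 3:
                frost_run = (frost_run + 1
                             if soil_t10[i] < kill.frost_soil_temp else 0)
                if season_event is None and frost_run >= kill.frost_days:
                    season_event = "frost_senescence"
                    plant = replace(plant, stage=4, peak_dm=plant.dm,
                                    peak_lai=plant.lai,
                                    stage4_onset=dates[i])

        # --- canopy and dry matter ----------------------------------------
        if plant.alive:
            entered_stage4 = plant.stage >= 4 and stage_before < 4
            if entered_stage4:
                plant = replace(plant, peak_dm=max(plant.peak_dm, plant.dm))
                n_days = days_to_next_harvest(i)
                harvest_value = (params.harvest.harvest_ratio
                                 * plant.peak_dm)
                decline_per_day = ((plant.peak_dm - harvest_value)
                                   / max(1, n_days))
            if plant.stage in (2, 3):
                fipar = fraction_intercepted(params.canopy.k, plant.lai)
                tvf = temperature_variation_factor(
                    tmean[i], plant.t_leaf, params.canopy.t_opt,
                    params.canopy.tvf_sigma)
                inc = daily_dm_increment(params.canopy.rue_max, tvf, f_rue,
                                         fipar, par[i])
                plant = replace(plant, dm=plant.dm + inc)
            elif plant.stage >= 4:
                plant = replace(plant, dm=max(harvest_value,
                                              plant.dm - decline_per_day))
            plant = replace(
                plant, lai=update_lai(plant, dd0_inc[i], f_lai,
                                      params.canopy))
            season_peak = max(season_peak, plant.dm)

        # --- dormant-season winter-kill counter ----------------------------
        if dates[i].month == dormant_start_month and dates[i].day == 1:
            in_dormant_window = True
            cold_days = 0
        if in_dormant_window:
            limit = (kill.chill_temp if kill.winterkill_mode == "chill"
                     else kill.t_kill)
            if tmin[i] < limit:
                cold_days += 1

        day_rows["stage"][i] = plant.stage
        day_rows["dd10"][i] = plant.dd10
        day_rows["lai"][i] = plant.lai
        day_rows["dm"][i] = plant.dm
        day_rows["swc"][i] = water.swc
        day_rows["psi"][i] = water.psi
        day_rows["aet"][i] = aet
        day_rows["drainage"][i] = drain

    daily = pd.DataFrame({"date": dates, **day_rows})
    annual_df = pd.DataFrame(
        [dataclasses.asdict(r) for r in annual],
        columns=["year", "peak_dm", "harvest_yield", "kill_event",
                 "establishment"])
    return SimulationResult(
        daily=daily, annual=annual_df, genotype=params.name,
        ecotype=params.ecotype, site=site,
        pet_method=forcing.attrs.get("pet_method", "unknown"),
        initial_swc=initial_swc)


def mean_annual_yield(result: SimulationResult,
                      period: Optional[tuple[int, int]] = None,
                      include_establishment: bool = True) -> float:
    """Arithmetic mean of harvested yields over ``period`` (inclusive).

    Killed-year zeros count toward the mean (the stand produced nothing
    that year); set ``include_establishment=False`` to drop establishment
    seasons, including replant years after a plant death.
    """
    annual = result.annual
    if period is not None:
        lo, hi = period
        annual = annual[(annual["year"] >= lo) & (annual["year"] <= hi)]
    if not include_establishment:
        annual = annual[~annual["establishment"]]
    if annual.empty:
        raise ValueError("no seasons in the requested period")
    return float(annual["harvest_yield"].mean())
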