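"""Kill events and dry-matter repartition to the harvestable yield.

Three classes of lethal or season-ending events are modelled:

* **Winter kill** (plant death, replant required): during a dormant season
  the daily minimum temperature falls below the genotype's hardiness
  limit (-23.3 degC lowland, -34.4 degC upland) on at least 60 days.  An
  alternative chill-day rule counts days below 0 degC against the same
  day threshold; mode is selected per run.
* **Drought kill**: 30 or more consecutive growing-season days with soil
  drier than the wilt point (-2 MPa) terminate the season (shoot death;
  the stand regrows next year); any single day at or below -11 MPa is
  plant death (necrosis).
* **Frost kill**: soil at 10 cm colder than a threshold for a run of days
  during the growing season forces premature plant senescence.

After the onset of plant senescence the standing crop dries down; the
spring harvest (1 March by default) recovers a fixed fraction 0.832 of the
peak dry matter for both ecotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "KillRules",
    "HarvestParams",
    "check_winter_kill",
    "check_drought_kill",
    "check_frost_kill",
    "harvestable_yield",
    "soil_temperature_10cm",
]

#: damping of the exponential running mean approximating soil T at 10 cm
SOIL_T_DAMPING = 0.2  # day-1


@dataclass(frozen=True)
class KillRules:
    """Genotype cold/drought tolerance and event thresholds."""

    t_kill: float                    # degC, absolute minimum tolerated
    kill_day_threshold: int = 60     # days below the limit => plant death
    chill_temp: float = 0.0          # degC, alternative chill-day rule
    drought_kill_days: int = 30      # consecutive days below wilt point
    psi_shoot_death: float = -2000.0   # kPa
    psi_plant_death: float = -11000.0  # kPa
    frost_soil_temp: float = -2.0    # degC at 10 cm
    frost_days: int = 3              # consecutive days
    winterkill_mode: str = "absolute"  # or "chill"

    def __post_init__(self) -> None:
        if self.t_kill >= self.chill_temp:
            raise ValueError("t_kill must be below chill_temp")
        if min(self.kill_day_threshold, self.drought_kill_days,
               self.frost_days) < 1:
            raise ValueError("day thresholds must be at least 1")
        if self.winterkill_mode not in ("absolute", "chill"):
            raise ValueError("winterkill_mode must be 'absolute' or 'chill'")


@dataclass(frozen=True)
class HarvestParams:
    """Peak-to-harvest repartition ratio and harvest date."""

    harvest_ratio: float = 0.832
    harvest_month: int = 3
    harvest_day: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.harvest_ratio <= 1.0:
            raise ValueError("harvest_ratio must lie in (0, 1]")


def check_winter_kill(winter_tmin_series, rules: KillRules
                      ) -> tuple[bool, Optional[str]]:
    """Decide whether a dormant season killed the stand.

    Count-based over the whole dormant season (days need not be
    consecutive).  ``absolute`` mode counts days below the genotype
    hardiness limit ``t_kill``; ``chill`` mode counts days below
    ``chill_temp``.  Returns ``(killed, cause)``.
    """
    tmin = np.asarray(winter_tmin_series, dtype=float)
    if rules.winterkill_mode == "chill":
        n_cold = int(np.sum(tmin < rules.chill_temp))
    else:
        n_cold = int(np.sum(tmin < rules.t_kill))
    if n_cold >= rules.kill_day_threshold:
        return True, f"winter kill ({rules.winterkill_mode}, {n_cold} days)"
    return False, None


def _longest_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def check_drought_kill(psi_series, rules: KillRules) -> Optional[str]:
    """Classify a growing season's drought outcome.

    Returns ``"plant_death"`` if any day reaches the necrosis potential,
    ``"shoot_death"`` if the wilt point is exceeded for the consecutive-day
    threshold, else ``None``.
    """
    psi = np.asarray(psi_series, dtype=float)
    if psi.size and np.any(psi <= rules.psi_plant_death):
        return "plant_death"
    if _longest_run(psi < rules.psi_shoot_death) >= rules.drought_kill_days:
        return "shoot_death"
    return None


def soil_temperature_10cm(tmean_series, damping: float = SOIL_T_DAMPING
                          ) -> np.ndarray:
    """Soil temperature at 10 cm as an exponentially damped mean of air T.

    ``T_soil[i] = T_soil[i-1] + damping (T_air[i] - T_soil[i-1])``,
    initialised at the first air temperature.  A crude but standard proxy
    when no soil-temperature forcing exists.
    """
    t = np.asarray(tmean_series, dtype=float)
    out = np.empty_like(t)
    if t.size == 0:
        return out
    out[0] = t[0]
    for i in range(1, t.size):
        out[i] = out[i - 1] + damping * (t[i] - out[i - 1])
    return out


def check_frost_kill(soil_t10_series, rules: KillRules) -> bool:
    """True if in-season soil frost forces premature plant senescence.

    Fires when soil temperature at 10 cm stays below ``frost_soil_temp``
    for at least ``frost_days`` consecutive days.
    """
    t10 = np.asarray(soil_t10_series, dtype=float)
    return _longest_run(t10 < rules.frost_soil_temp) >= rules.frost_days


def harvestable_yield(peak_dm: float, params: HarvestParams) -> float:
    """Spring-harvest yield, ``harvest_ratio x peak_dm`` (Mg ha-1)."""
    if peak_dm < 0.0:
        raise ValueError("peak_dm must be non-negative")
    return params.harvest_ratio * peak_dm
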