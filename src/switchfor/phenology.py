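"""Physiostat: the discrete plant-development state machine.

Six stages — 0 dormant, 1 shoot emergence, 2 leaf expansion, 3 leaf-area
maximum / onset of leaf senescence, 4 plant senescence and nutrient
repartition to the rhizome, 5 above-ground biomass drying — advanced by
cumulative degree days above a 10 degC base (DD10), with environmental
triggers and brakes:

* emergence (0 -> 1) additionally needs moist soil (psi above the
  emergence gate, default -300 kPa) and a frost-free day;
* leaf senescence (2 -> 3) can be forced early by reaching maximum LAI,
  the first autumn frost, soil drier than the leaf-expansion stop
  potential, or (if enabled) a short photoperiod;
* plant senescence (3 -> 4) can be forced by a killing frost; the peak
  standing dry matter is frozen at this onset.

Stages only move forward within a season; the annual reset (at the spring
harvest date) returns the clock to dormancy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import pandas as pd

__all__ = [
    "PhysiostatThresholds",
    "PhenologyTriggers",
    "PlantState",
    "advance_physiostat",
    "annual_reset",
]

#: soil-moisture gate for shoot emergence (kPa); seedlings emerging drier
#: than about -0.3 MPa show sharply reduced establishment
DEFAULT_EMERGENCE_PSI = -300.0
#: air temperature below which a frost is "killing" (forces stage 4)
DEFAULT_KILLING_FROST_TMIN = -5.0
#: photoperiod brake threshold (h); inert unless explicitly enabled
DEFAULT_PHOTOPERIOD_HOURS = 12.5


@dataclass(frozen=True)
class PhysiostatThresholds:
    """Cumulative DD10 (degC day above 10 degC) triggering stages 1-5."""

    dd_stage: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        dd = self.dd_stage
        if len(dd) != 5:
            raise ValueError("need five stage thresholds")
        if any(d <= 0 for d in dd) or any(a >= b for a, b in zip(dd, dd[1:])):
            raise ValueError("stage thresholds must be positive and "
                             "strictly increasing")


@dataclass(frozen=True)
class PhenologyTriggers:
    """Environmental conditions of one day, as seen by the physiostat."""

    psi: float                  # soil matric potential, kPa
    tmean: float                # degC
    tmin: float                 # degC
    day_length: float           # h
    after_solstice: bool = False  # past the summer solstice (autumn side)


@dataclass(frozen=True)
class PlantState:
    """Full per-day plant state carried through the simulation."""

    stage: int = 0
    dd10: float = 0.0
    dd0: float = 0.0
    lai: float = 0.0
    dm: float = 0.0           # above-ground dry matter, Mg ha-1
    peak_dm: float = 0.0      # frozen at stage-4 onset
    peak_lai: float = 0.0     # LAI attained when senescence began
    t_leaf: float = 0.0       # mean temperature over leaf formation, degC
    alive: bool = True
    stage4_onset: Optional[pd.Timestamp] = None


def advance_physiostat(state: PlantState, dd10_today: float,
                       triggers: PhenologyTriggers,
                       thresholds: PhysiostatThresholds,
                       lai_max: float,
                       emergence_psi: float = DEFAULT_EMERGENCE_PSI,
                       psi_stop_lai: float = -1000.0,
                       killing_frost_tmin: float = DEFAULT_KILLING_FROST_TMIN,
                       photoperiod_enabled: bool = False,
                       photoperiod_hours: float = DEFAULT_PHOTOPERIOD_HOURS,
                       date: Optional[pd.Timestamp] = None) -> PlantState:
    """Advance the physiostat by one day.

    Accumulates today's DD10 onto the clock and applies the stage-transition
    rules.  At most one transition fires per day, and stages never move
    backward within a season.  Returns the updated state; a dead plant is
    returned unchanged apart from its thermal clock.
    """
    dd10 = state.dd10 + max(0.0, dd10_today)
    state = replace(state, dd10=dd10)
    if not state.alive:
        return state
    dd = thresholds.dd_stage
    stage = state.stage

    if stage == 0:
        frost_today = triggers.tmin < 0.0
        if dd10 >= dd[0] and triggers.psi >= emergence_psi and not frost_today:
            return replace(state, stage=1)
    elif stage == 1:
        if dd10 >= dd[1]:
            return replace(state, stage=2)
    elif stage == 2:
        autumn_frost = triggers.after_solstice and triggers.tmin < 0.0
        short_day = (photoperiod_enabled and triggers.after_solstice
                     and triggers.day_length < photoperiod_hours)
        if (dd10 >= dd[2] or state.lai >= lai_max
                or autumn_frost or triggers.psi < psi_stop_lai or short_day):
            return replace(state, stage=3, peak_lai=state.lai)
    elif stage == 3:
        killing_frost = triggers.tmin < killing_frost_tmin
        if dd10 >= dd[3] or killing_frost:
            return replace(state, stage=4, peak_dm=state.dm,
                           stage4_onset=date)
    elif stage == 4:
        if dd10 >= dd[4]:
            return replace(state, stage=5)
    return state


def annual_reset(state: PlantState) -> PlantState:
    """Reset the seasonal clocks at the spring harvest date.

    Zeroes the degree-day clocks, LAI and standing dry matter and returns
    the plant to dormancy; the establishment/alive flag survives the reset.
    Idempotent.
    """
    return PlantState(alive=state.alive)
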