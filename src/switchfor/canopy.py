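"""Canopy light interception, temperature-modulated RUE, and LAI / dry
matter dynamics.

Daily dry-matter gain follows the radiation-use-efficiency paradigm:
intercepted PAR (Beer's law, extinction coefficient k = 0.36 for both
switchgrass ecotypes) times an effective RUE, which is the genotype's
maximum RUE downregulated by a temperature variation factor (TVF) and by
soil-water stress.  The TVF is a bivariate Gaussian in the daily
temperature and the mean temperature over the leaf-formation period,
centred on the genotype's optimum (28 degC lowland, 23 degC upland) and
equal to one at the optimum.

LAI expands during stages 1-2 in proportion to degree days above 0 degC
(0.004 LAI per degC day for Alamo/lowland, 0.006 for Cave-In-Rock/upland),
scaled by the leaf-expansion water-stress factor and capped at the
genotype maximum (12 lowland, 7 upland).  From the onset of leaf
senescence (stage 3) LAI declines linearly at the genotype senescence rate
(0.03 / 0.049 day-1, read as fraction of the attained peak per day).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phenology import PlantState

__all__ = [
    "CanopyParams",
    "fraction_intercepted",
    "temperature_variation_factor",
    "update_lai",
    "daily_dm_increment",
]

#: Gaussian width of the temperature variation factor (degC)
DEFAULT_TVF_SIGMA = 8.0

#: g m-2 -> Mg ha-1
_G_M2_TO_MG_HA = 0.01


@dataclass(frozen=True)
class CanopyParams:
    """Genotype canopy constants.

    k : Beer's-law light extinction coefficient (dimensionless)
    lai_max : maximum leaf area index
    dd_lai_factor : LAI increment per degC day above 0 degC
    lai_senescence_rate : fraction of peak LAI shed per day after onset
    rue_max : maximum radiation-use efficiency, g DM per MJ intercepted PAR
    t_opt : optimal growth temperature, degC
    tvf_sigma : width of the temperature response, degC
    senescence_mode : "linear" (default) or "exponential" decline
    """

    k: float
    lai_max: float
    dd_lai_factor: float
    lai_senescence_rate: float
    rue_max: float
    t_opt: float
    tvf_sigma: float = DEFAULT_TVF_SIGMA
    senescence_mode: str = "linear"

    def __post_init__(self) -> None:
        positives = (self.k, self.lai_max, self.dd_lai_factor,
                     self.lai_senescence_rate, self.rue_max, self.tvf_sigma)
        if any(v <= 0 for v in positives):
            raise ValueError("canopy parameters must be positive")
        if self.lai_max < 1.0:
            raise ValueError("lai_max must be at least 1")
        if self.senescence_mode not in ("linear", "exponential"):
            raise ValueError("senescence_mode must be linear or exponential")


def fraction_intercepted(k: float, lai) -> float:
    """Beer's-law fraction of incident PAR intercepted, 1 - exp(-k LAI)."""
    lai = np.asarray(lai, dtype=float)
    if np.any(lai < 0.0):
        raise ValueError("LAI must be non-negative")
    out = 1.0 - np.exp(-k * lai)
    return float(out) if out.ndim == 0 else out


def temperature_variation_factor(t_day: float, t_leaf: float, t_opt: float,
                                 sigma: float = DEFAULT_TVF_SIGMA) -> float:
    """Temperature multiplier of RUE in (0, 1].

    ``exp(-[(t_day - t_opt)^2 + (t_leaf - t_opt)^2] / (2 sigma^2))`` —
    equal to one only when both the daily temperature and the
    leaf-formation mean temperature sit at the optimum.
    """
    if sigma <= 0.0:
        raise ValueError("sigma must be positive")
    return float(np.exp(-((t_day - t_opt) ** 2 + (t_leaf - t_opt) ** 2)
                        / (2.0 * sigma ** 2)))


def update_lai(state: PlantState, dd0_today: float, water_factor_lai: float,
               params: CanopyParams) -> float:
    """New LAI after one day, by physiostat stage.

    Stages 1-2 expand by ``dd_lai_factor x dd0_today`` scaled by the
    water-stress factor and capped at ``lai_max``; stages 3-4 shed
    ``lai_senescence_rate x peak LAI`` per day (or a fraction of current
    LAI in exponential mode); stages 0 and 5 carry no canopy.
    """
    if state.stage in (1, 2):
        gain = params.dd_lai_factor * max(0.0, dd0_today) * water_factor_lai
        return min(params.lai_max, state.lai + gain)
    if state.stage in (3, 4):
        if params.senescence_mode == "exponential":
            loss = params.lai_senescence_rate * state.lai
        else:
            peak = state.peak_lai if state.peak_lai > 0.0 else state.lai
            loss = params.lai_senescence_rate * peak
        return max(0.0, state.lai - loss)
    return 0.0


def daily_dm_increment(rue_max: float, tvf: float, water_factor_rue: float,
                       fipar: float, par: float) -> float:
    """Daily dry-matter gain in Mg ha-1.

    ``rue_max x TVF x water factor x intercepted-PAR fraction x PAR`` gives
    g DM m-2; the 0.01 factor converts to Mg ha-1.  All multipliers must
    lie in [0, 1] and PAR must be non-negative.
    """
    for name, v in (("tvf", tvf), ("water_factor_rue", water_factor_rue),
                    ("fipar", fipar)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} outside [0, 1]")
    if par < 0.0 or rue_max <= 0.0:
        raise ValueError("par must be >= 0 and rue_max > 0")
    return rue_max * tvf * water_factor_rue * fipar * par * _G_M2_TO_MG_HA
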