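"""Soil-water bucket with a Campbell retention curve.

The plant-available water in soil is tracked as a single free-draining
bucket over the rooted profile.  The retention curve is Campbell's power
law, theta(psi) = theta_s (psi/psi_e)^(-1/b), parameterised from texture
with the Cosby et al. (1984) regressions for the exponent ``b`` and the
air-entry potential ``psi_e``, and total porosity from bulk density with
an organic-matter particle-density correction.

Water stress acts on the plant through a downregulation factor that is
linear in ln|psi| between field capacity (-10 kPa, factor 1) and a
process-specific stop potential (factor 0): -1 MPa for leaf expansion,
-2 MPa (the wilt point) for photosynthesis.  Actual evapotranspiration is
a fraction of PET set by canopy cover (Beer's-law form plus a bare-soil
floor) and the photosynthesis stress factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SoilProfile",
    "RetentionParams",
    "SoilWaterState",
    "campbell_parameters",
    "theta_at_potential",
    "water_potential",
    "downregulation_factor",
    "canopy_cover_factor",
    "actual_evapotranspiration",
    "update_water_balance",
    "initial_state",
    "PSI_FC",
    "PSI_WP",
    "PSI_FLOOR",
]

PSI_FC = -10.0        # kPa, field capacity anchor
PSI_WP = -2000.0      # kPa, wilt point / photosynthesis stop
PSI_FLOOR = -11000.0  # kPa, necrosis bound; lower limit of extractable water

#: extinction coefficient of the canopy-cover factor in the AET model
DEFAULT_K_AET = 0.36
#: bare-soil evaporation fraction of PET under zero canopy
DEFAULT_BARE_SOIL_FRACTION = 0.2

_CM_H2O_TO_KPA = 0.0980665
_MINERAL_PARTICLE_DENSITY = 2.65   # g cm-3
_ORGANIC_PARTICLE_DENSITY = 1.30   # g cm-3
_SOC_TO_SOM = 1.724                # van Bemmelen factor


@dataclass(frozen=True)
class SoilProfile:
    """Texture and structure of the rooted soil profile.

    sand/silt/clay are mass fractions summing to one, ``soc`` the organic
    carbon mass fraction, ``bulk_density`` g cm-3 and ``depth`` the rooted
    depth in mm.
    """

    sand: float
    silt: float
    clay: float
    soc: float = 0.01
    bulk_density: float = 1.3
    depth: float = 1000.0

    def __post_init__(self) -> None:
        fracs = (self.sand, self.silt, self.clay)
        if any(f < 0.0 or f > 1.0 for f in fracs):
            raise ValueError("texture fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 0.01:
            raise ValueError("sand + silt + clay must sum to 1 (±0.01)")
        if not 0.0 <= self.soc < 0.6:
            raise ValueError("implausible organic-carbon fraction")
        if not 0.5 < self.bulk_density < 2.2:
            raise ValueError("bulk density outside (0.5, 2.2) g cm-3")
        if self.depth <= 0.0:
            raise ValueError("profile depth must be positive")


@dataclass(frozen=True)
class RetentionParams:
    """Campbell retention-curve parameters and the derived anchors."""

    theta_s: float      # saturated volumetric content, m3 m-3
    psi_e: float        # air-entry potential, kPa (negative)
    b: float            # Campbell exponent
    theta_fc: float     # content at -10 kPa
    theta_wp: float     # content at -2 MPa
    theta_floor: float  # content at -11 MPa

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_floor < self.theta_wp < self.theta_fc \
                < self.theta_s:
            raise ValueError("retention anchors out of order")
        if self.b <= 0.0 or self.psi_e >= 0.0:
            raise ValueError("need b > 0 and psi_e < 0")


@dataclass(frozen=True)
class SoilWaterState:
    """Evolving bucket state: stored water, matric potential, deficit."""

    swc: float  # mm over the profile
    psi: float  # kPa, negative
    swd: float  # mm below field capacity, >= 0


def campbell_parameters(profile: SoilProfile) -> RetentionParams:
    """Pedotransfer from texture to Campbell retention parameters.

    * porosity from bulk density with an organic/mineral particle-density
      mix (organic matter = 1.724 x SOC),
    * ``b = 2.91 + 0.159 x clay%`` and
      ``|psi_e| = 0.0981 x 10^(1.88 - 0.0131 x sand%)`` kPa
      (Cosby et al. 1984 regressions, cm-of-water intercept converted),
    * anchors evaluated on the curve at -10 kPa, -2 MPa and -11 MPa.
    """
    som = min(_SOC_TO_SOM * profile.soc, 0.99)
    particle_density = 1.0 / (som / _ORGANIC_PARTICLE_DENSITY
                              + (1.0 - som) / _MINERAL_PARTICLE_DENSITY)
    theta_s = 1.0 - profile.bulk_density / particle_density
    theta_s = float(np.clip(theta_s, 0.25, 0.85))

    clay_pct = 100.0 * profile.clay
    sand_pct = 100.0 * profile.sand
    b = 2.91 + 0.159 * clay_pct
    psi_e = -_CM_H2O_TO_KPA * 10.0 ** (1.88 - 0.0131 * sand_pct)

    def theta_at(psi: float) -> float:
        return theta_s * (psi / psi_e) ** (-1.0 / b)

    return RetentionParams(
        theta_s=theta_s, psi_e=psi_e, b=b,
        theta_fc=theta_at(PSI_FC),
        theta_wp=theta_at(PSI_WP),
        theta_floor=theta_at(PSI_FLOOR),
    )


def theta_at_potential(psi, params: RetentionParams):
    """Volumetric water content on the Campbell curve at potential psi (kPa)."""
    psi = np.asarray(psi, dtype=float)
    if np.any(psi >= 0.0):
        raise ValueError("matric potential must be negative")
    ratio = np.minimum(psi / params.psi_e, np.inf)
    theta = params.theta_s * np.where(ratio <= 1.0, 1.0,
                                      ratio ** (-1.0 / params.b))
    return float(theta) if theta.ndim == 0 else theta


def water_potential(swc: float, params: RetentionParams,
                    depth: float) -> float:
    """Matric potential (kPa) for a bucket holding ``swc`` mm over ``depth`` mm.

    Inverts the Campbell curve, psi = psi_e (theta/theta_s)^(-b).  Contents
    outside the physical range are clamped to it (wetter than saturation
    reads psi_e; drier than the -11 MPa floor reads the floor potential).
    """
    theta = swc / depth
    theta = float(np.clip(theta, params.theta_floor, params.theta_s))
    return params.psi_e * (theta / params.theta_s) ** (-params.b)


def downregulation_factor(psi: float, psi_full: float = PSI_FC,
                          psi_stop: float = PSI_WP) -> float:
    """Water-stress multiplier, linear in ln|psi|, clipped to [0, 1].

    Equals 1 at ``psi_full`` (field capacity) and 0 at ``psi_stop``; used
    with psi_stop = -1 MPa for leaf expansion and -2 MPa for
    photosynthesis.
    """
    if psi >= 0.0 or psi_full >= 0.0 or psi_stop >= 0.0:
        raise ValueError("potentials must be negative")
    if not psi_stop < psi_full:
        raise ValueError("psi_full must be wetter (less negative) than psi_stop")
    f = ((np.log(-psi_stop) - np.log(-psi))
         / (np.log(-psi_stop) - np.log(-psi_full)))
    return float(np.clip(f, 0.0, 1.0))


def canopy_cover_factor(lai: float, k_aet: float = DEFAULT_K_AET,
                        bare_soil_fraction: float = DEFAULT_BARE_SOIL_FRACTION
                        ) -> float:
    """Fraction of PET demanded by the surface at leaf area ``lai``.

    Beer's-law canopy transpiration share plus a bare-soil evaporation
    floor: ``e_s + (1 - e_s)(1 - exp(-k lai))``, in (0, 1].
    """
    return bare_soil_fraction + (1.0 - bare_soil_fraction) * (
        1.0 - float(np.exp(-k_aet * lai)))


def actual_evapotranspiration(pet: float, lai: float, psi: float,
                              psi_full: float = PSI_FC,
                              psi_stop: float = PSI_WP,
                              k_aet: float = DEFAULT_K_AET,
                              bare_soil_fraction: float =
                              DEFAULT_BARE_SOIL_FRACTION) -> float:
    """AET (mm) as PET x canopy cover x water-stress factor; 0 <= AET <= PET."""
    if pet < 0.0 or lai < 0.0:
        raise ValueError("pet and lai must be non-negative")
    cover = canopy_cover_factor(lai, k_aet, bare_soil_fraction)
    f_w = downregulation_factor(psi, psi_full, psi_stop)
    return pet * cover * f_w


def _derive_state(swc: float, params: RetentionParams,
                  depth: float) -> SoilWaterState:
    psi = water_potential(swc, params, depth)
    fc_mm = params.theta_fc * depth
    return SoilWaterState(swc=swc, psi=psi, swd=max(0.0, fc_mm - swc))


def initial_state(params: RetentionParams, depth: float,
                  fraction_of_fc: float = 1.0) -> SoilWaterState:
    """Bucket initialised at a fraction of field capacity (default: at FC)."""
    swc = fraction_of_fc * params.theta_fc * depth
    swc = float(np.clip(swc, params.theta_floor * depth,
                        params.theta_s * depth))
    return _derive_state(swc, params, depth)


def update_water_balance(state: SoilWaterState, precip: float, pet: float,
                         lai: float, params: RetentionParams, depth: float,
                         psi_full: float = PSI_FC,
                         psi_stop: float = PSI_WP,
                         k_aet: float = DEFAULT_K_AET,
                         bare_soil_fraction: float =
                         DEFAULT_BARE_SOIL_FRACTION
                         ) -> tuple[SoilWaterState, float, float]:
    """One daily step of the free-draining bucket.

    Order of operations: add precipitation, withdraw AET (limited so the
    store never drops below the -11 MPa floor), then drain any excess above
    field capacity instantly.  Returns ``(new_state, aet, drainage)``; the
    balance ``precip - aet - drainage == swc' - swc`` closes to machine
    precision.
    """
    if precip < 0.0:
        raise ValueError("negative precipitation")
    floor_mm = params.theta_floor * depth
    fc_mm = params.theta_fc * depth

    demand = actual_evapotranspiration(pet, lai, state.psi, psi_full,
                                       psi_stop, k_aet, bare_soil_fraction)
    available = state.swc + precip - floor_mm
    aet = min(demand, max(0.0, available))
    drainage = max(0.0, state.swc + precip - aet - fc_mm)
    swc_new = state.swc + precip - aet - drainage
    return _derive_state(swc_new, params, depth), aet, drainage
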