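# Methods

This note documents the model as implemented: its governing equations,
the parameter values and why they hold, the numerical and design choices
made where the formulation was genuinely open, what the synthetic forcing
does and does not emulate, and known limitations.

## Model structure

The simulator advances one day at a time in a fixed order — forcing
derivation, soil-water bucket, phenology, canopy/dry matter, event
checks — over a contiguous multi-year weather series. A season runs from
the spring harvest/reset date (1 March, northern hemisphere) to the
next; seasons whose harvest falls outside the series are not booked.

### Forcing

Mean temperature is (Tmin + Tmax)/2. Two thermal clocks accumulate from
each annual reset: DD10 (base 10 °C) drives the phenology state machine
and DD0 (base 0 °C) drives leaf expansion. Day length comes from the
standard sunrise geometry cos h = −tan φ tan δ with declination
δ = −23.44° cos(2π(doy+10)/365); PAR defaults to 0.5 × global radiation
(configurable — a common crop-model convention). PET uses FAO-56
Penman–Monteith (grass reference, albedo 0.23, daily soil heat flux 0)
when wind and humidity (RH % or vapour pressure) are available, else
Thornthwaite's monthly formulation with the heat index formed per
calendar year and monthly PET spread uniformly over true month lengths;
the method actually used is recorded on the run. The relative-shortwave
ratio in the net-longwave term is bounded to [0.3, 1] so dark or
overcast days cannot produce a spurious nocturnal energy gain.

### Soil water

One free-draining bucket over the rooted profile (default 1000 mm; no
layering, runoff, snow or groundwater). Retention is Campbell's
θ(ψ) = θs (ψ/ψe)^(−1/b) with θs from bulk density (particle density
mixed between 2.65 mineral and 1.30 organic via organic matter =
1.724 × SOC) and the Cosby texture regressions b = 2.91 + 0.159 clay%,
|ψe| = 0.0981 × 10^(1.88 − 0.0131 sand%) kPa. The exact pedotransfer
source is a configuration choice: only "the Campbell method" is fixed by
the model lineage, so the regression constants live in one function and
are swappable.

Anchors: field capacity at −10 kPa, wilt point at −2 MPa, and an
extractable-water floor at −11 MPa — the potential at which switchgrass
suffers necrosis in chamber studies. Water stress downregulates
processes by a factor linear in ln|ψ|, 1 at field capacity and 0 at the
process's stop potential: −1 MPa for leaf expansion, −2 MPa for
photosynthesis, so leaf growth always halts at a wetter potential than
carbon gain as soil dries.

AET = PET × C(LAI) × f_w(ψ), with canopy cover
C = e_s + (1 − e_s)(1 − e^(−k·LAI)), bare-soil fraction e_s = 0.2 and
k_aet = 0.36 (both configurable; the lineage model states only that AET
depends on the LAI–deficit interaction, so the simplest closure with the
same extinction coefficient is used, and no additional crop coefficient
is applied). The daily update adds precipitation, withdraws AET limited
by the −11 MPa floor, and drains any excess above field capacity
instantly; the balance closes to machine precision by construction.

### Phenology

Six physiostat stages with DD10 thresholds (Alamo/lowland
105/168/1174/1566/1694; Cave-In-Rock/upland 80/125/1085/1395/1488).
Additional gates and brakes:

* emergence (0→1) requires ψ ≥ −300 kPa (seedling emergence collapses
  around −0.3 MPa in chamber experiments) and a frost-free day;
* senescence onset (2→3) fires early on LAI reaching its maximum, the
  first autumn frost (Tmin < 0 after the solstice), soil drier than the
  leaf-expansion stop, or — when enabled — day length below 12.5 h. The
  photoperiod brake ships disabled because the day-length trigger has no
  published threshold; an explicit flag is cleaner than a threshold
  tuned never to fire;
* plant senescence (3→4) fires on the DD threshold or a killing frost
  (Tmin < −5 °C); the peak dry matter is frozen at this onset;
* one transition per day, never backward within a season; the annual
  reset zeroes clocks, LAI and standing matter, and preserves only the
  alive flag.

Because the upland thresholds are uniformly lower, upland reaches every
stage no later than lowland on identical forcing — asserted in tests.

### Canopy and dry matter

ΔDM (Mg ha⁻¹) = RUEmax · TVF · f_w · (1 − e^(−0.36·LAI)) · PAR · 0.01,
accumulated during stages 2–3; the peak is taken at the 3→4 transition
(growth continues through leaf senescence until *plant* senescence).
RUEmax is 5.05 (lowland) / 3.19 (upland) g DM per MJ intercepted PAR,
the recorded cultivar maxima. The TVF is
exp(−[(T_day − T_opt)² + (T_leaf − T_opt)²]/(2σ²)) with T_opt 28/23 °C
and σ = 8 °C; the bivariate-Gaussian form and width are this package's
parameterisation of a response documented only graphically in the
lineage, normalised to 1 at the optimum and calibratable through σ.
T_leaf is the 30-day running mean of daily mean temperature (window
configurable), a simple proxy for "temperature over the leaf-formation
period" that is cheap and stage-independent.

LAI: expansion 0.004/0.006 × DD0 per day scaled by the leaf-expansion
stress factor and capped at 12/7; senescence as a linear loss of
(0.03/0.049) × attained peak LAI per day, reading the published
"day⁻¹" rates as a fraction of peak per day (an exponential-decay
alternative is selectable). The extinction coefficient is 0.36 for both
ecotypes — the median of 34 published values; negative signs in some
sources are reporting conventions, so absolute values are used.

### Events and harvest

Winter kill is count-based over the dormant season (1 Nov to harvest):
≥ 60 days (threshold configurable) with Tmin below the hardiness limit
(−23.3 / −34.4 °C) kills the stand. Counting non-consecutive days was
chosen because the one documented field kill corresponds to 61 sub-zero
days that were not strictly consecutive. Because the literal
absolute-threshold rule cannot reproduce that kill at a site whose
minima never reached −23.3 °C, an alternative chill-day mode (days below
0 °C against the same count) is selectable via `winterkill_mode`; the
absolute rule is the default as the rule is literally stated. A killed
season yields zero (the dead stand's biomass is not booked) and the
replant season that follows also yields zero — the same policy applied
after a drought plant death, realising "plant death also zeroes the
following establishment year".

Drought: 30 consecutive growing-season days below the wilt point
(threshold a package default; no published value) terminate the season
as shoot death — the stand regrows next year and the harvest is limited
to 0.832 × the peak at termination; any day at or below −11 MPa is
plant death. In-season frost kill uses soil temperature at 10 cm,
approximated by an exponentially damped running mean of air temperature
(damping 0.2 day⁻¹) since no soil-temperature forcing is defined; three
consecutive days below −2 °C force premature senescence. Exactly one
event class is booked per season (first to fire).

Harvest: 0.832 × peak dry matter for both ecotypes, booked at 1 March;
between senescence onset and harvest, the standing matter declines
linearly from peak to that value (the decline rate is computed at onset
from the days remaining, so the trajectory lands exactly on
0.832 × peak). If a cool season ends without reaching stage 4, the
ratio is applied to the season's running peak at harvest.

### Mapping

`run_grid` executes the site model per cell of an xarray cube (daily
weather on time × y × x plus co-registered soil bands) and books the
mean annual yield; a cell whose fraction of plant-death seasons exceeds
a configurable limit (default: any) is NoData — outside the adaptation
zone. `optimal_map` takes the cell-wise maximum with winner labels (0
upland, 1 lowland; ties to upland, the more widely adapted ecotype);
`apply_mask` drops unmasked cells and slopes strictly above 15°;
`aggregate_totals` produces Tg totals, area-weighted means and live
area, with cosine-rule cell areas on geographic grids or a constant for
equal-area grids. NoData is NaN in memory (−9999 only if exported to
integer formats). Grid I/O uses NetCDF through xarray's scipy backend
and in-memory numpy rasters; no GeoTIFF/CRS machinery is bundled.

## Synthetic forcing

The generator emulates the statistical shape of gridded daily forcing:
a seasonal sinusoid with AR(1) noise (ρ = 0.7, σ = 2 °C) for mean
temperature, a fixed diurnal range, a two-state Markov occurrence chain
with gamma amounts (shape 0.7) calibrated to the annual total, and
radiation as extraterrestrial × transmissivity with a wet-day reduction.
Presets: `loess-semiarid` (9 °C, 450 mm — temperate continental),
`warm-humid` (16 °C, 1100 mm) and `cold-continental` (0 °C mean,
24 °C amplitude, so winter minima sit below −24 °C for well over 60
days while summers remain warm enough for an upland crop). All
randomness flows through one seeded generator; series are reproducible
bit-for-bit.

What it does **not** emulate: persistence beyond AR(1)/two-state
structure, radiation–temperature covariance, humidity and wind fields
(so synthetic runs use Thornthwaite PET), interannual modes, or any real
station's climate. Passing tests on synthetic forcing therefore
demonstrate internal correctness and directional
genotype-by-environment behaviour, not site-level predictive skill;
skill is represented by the packaged multi-site field-trial pairs.

## Validation statistics

r² is the squared Pearson correlation of modelled vs measured (the
regression definition); an alternative modelling-efficiency statistic
about the 1:1 line (1 − SSE/SST, bias-sensitive, possibly negative) is
reported separately. RMSE and mean bias as usual. The upland pair set
contains one extreme outlier (Yangling 2010, measured 30.2 vs modelled
8.9 Mg ha⁻¹) whose inclusion in the original regression is ambiguous;
statistics are always computed and reported under both policies rather
than silently choosing one.

## Problem sizes and numerical choices

Default test and acceptance runs use 5–10 year single-site simulations
and 3×3 grids over 2–3 years — sizes chosen so the whole suite
completes in seconds while still exercising multi-season bookkeeping; a
ten-year single-site run takes well under a second. Tolerances: water
balance asserted to 1e-9 mm, closed forms to 1e-9 or better, published
statistics at the transcription precision of their sources. Degenerate
inputs are rejected early (inverted temperature extremes, gapped or
duplicated dates, texture fractions not summing to 1, non-negative
potentials); bucket contents are clamped to the physical range with the
retention curve kept consistent. Ties in the optimal map go to upland;
stage transitions are limited to one per day.

## Limitations

No nitrogen limitation (named in the lineage but unparameterised), no
harvest moisture content, no multi-layer hydrology, snow insulation,
tillering/organ morphology or calibration machinery. Parameters are
ecotype-level, not cultivar-level: within-ecotype cultivar differences
are folded into the two default sets, though every constant is exposed
for reparameterisation via `apply_overrides` or a YAML overrides file.
Regional totals computed here are for synthetic grids; producing real
regional numbers requires real gridded climate and soil inputs, which
the package reads but does not bundle.
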