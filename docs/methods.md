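# Methods

This note documents the models inside `wheatstress`, the choices made where
the design was open, and what the synthetic fixtures do and do not
demonstrate.

## Stochastic weather generator

A site is a `SiteClimateParams`: per-month means and standard deviations of
daily maximum/minimum temperature, wet/dry transition probabilities, gamma
wet-amount shape and mean, monthly mean radiation with one coefficient of
variation, a single lag-1 temperature autocorrelation, and latitude.

* **Calendar.** Years are 365 days with fixed month lengths; leap days are
  dropped on estimation. This simplifies thermal-time bookkeeping, and the
  one-day-in-four bias is negligible for 95th-percentile indices.
* **Occurrence.** Precipitation occurrence is a first-order two-state
  Markov chain with the monthly transition probabilities; a wet day is any
  day with rain > 0 mm in estimation, and generated wet amounts are
  truncated below at 0.1 mm to avoid degenerate gamma draws.
* **Temperatures.** A single standard-normal AR(1) anomaly (coefficient
  `temp_autocorr`, spun up for 100 days so the series starts at its
  stationary distribution) is scaled by the monthly sd of tmax and added to
  the monthly mean; tmin follows tmax at the month's mean diurnal range, so
  tmax ≥ tmin holds by construction. The separate monthly sd of tmin is
  estimated and stored but not used in generation — a deliberate
  simplification of the joint law.
* **Radiation.** Lognormal around the monthly mean with the stated cv,
  independent of temperature and rain.
* **Delta-change scenarios.** A `ClimateDelta` shifts the twelve monthly
  temperature means additively and scales the monthly wet-amount and
  radiation means multiplicatively, leaving all variability parameters
  untouched; deltas therefore compose exactly (temperatures add, factors
  multiply). Changes in variability and extremes that a downscaler might
  derive from climate-model output are intentionally out of scope: only the
  first moments are perturbed, and the limitation should be kept in mind
  when interpreting future-scenario tails.

Parameter estimation (`estimate_params`) uses plain sample moments,
maximum-likelihood transition counts and method-of-moments gamma shapes; an
all-dry month keeps probability 0 and NaN (undefined) amount parameters.
At least three complete years are required, and missing days are reported
by year and day-of-year.

## Host crop model

The crop model is intentionally minimal: it exposes exactly the drivers the
flowering-window stress functions consume. It is not a reimplementation of
any full wheat simulator, and its constants live in `HostConstants`, not in
code.

* **Phenology.** Thermal time Σ max(0, Tmean − base_temp) from sowing;
  anthesis at `tt_sowing_to_anthesis` (default 1100 °C·d), maturity after a
  further `tt_anthesis_to_maturity` (default 750 °C·d). No vernalization or
  photoperiod response, so warming always advances flowering.
* **Canopy.** LAI ramps linearly in thermal time to `max_lai` (6) at
  anthesis, then senesces linearly to maturity; interception is Beer's law
  with `k_light` = 0.45.
* **Biomass.** RUE of 1.2 g MJ⁻¹ on intercepted shortwave, multiplied by
  the water supply ratio and the CO₂ factor `1 + 0.30·(CO₂/CO₂_ref − 1)` —
  linear, +30 % per doubling; reference CO₂ 363.8 ppm, with 562.8 and
  1001.8 ppm as the conventional 2050/2090 concentrations.
* **Water.** One soil bucket of capacity `sawc`, started at
  `sawc − initial_smd`; the root-accessible fraction grows linearly to the
  full profile (default over 90 days). Potential ET is Priestley–Taylor
  (α = 1.26, net radiation = 0.7 × shortwave), chosen over Penman–Monteith
  because the generator produces no wind or humidity. Potential
  transpiration is the intercepted-light share of ETp; actual fluxes scale
  by min(1, RAW / (0.5 × root capacity)) and are capped at store + rain.
  The update is an exact ledger (store + rain = new store + ET + drainage),
  asserted in tests to accumulation precision.
* **Canopy temperature.** An empirical surrogate for a full energy
  balance — `tcan = tmax_air + 5 °C × (1 − Ta/Tp) × clamp(rad/25, 0, 1)` —
  warming the canopy as transpiration is curtailed. This is the model's
  largest fidelity gap: it has the right sign and rough magnitude of
  stress-induced canopy warming but no aerodynamic component.
* **Yield.** Ear mass at anthesis is `ear_mass_fraction` (0.25) of shoot
  biomass; grain number is `n_pot` (80 grains g⁻¹) × ear mass × R_D × R_H;
  grain weight is min(`w_pot` × R_W, assimilate per grain), where
  assimilate is post-anthesis growth plus 25 % retranslocation of anthesis
  biomass. With the defaults the sink term usually binds, so stress on
  grain number translates into yield loss rather than being compensated by
  heavier grains, while the assimilate cap prevents unlimited compensation.
  How a canopy-scale model converts ear mass to grain number is genuinely
  open; the fixed `ear_mass_fraction`/`n_pot` route is an explicit
  surrogate.

## Stress mechanisms and windows

The three reduction factors are defined in `stress.py` exactly as the
piecewise/clamped-linear forms in the README. Heat factors use the single
maximum canopy temperature over their window, not day-by-day products. The
DSF is the ratio of window sums of actual to potential transpiration; a
window with zero transpiration demand gives DSF = 1 (no demand → no
stress). A "15 days around flowering, 10 before to 5 after" window is
internally ambiguous by one day: the default convention is fully inclusive
(16 calendar days), and `window_convention="exclusive_anthesis"` gives the
15-day count that omits the anthesis day itself. Both are tested; indices
are insensitive to the choice beyond the third decimal on the fixtures.

The default stress block (DSGNT 0.5, DSGNS 0.1, DSGNRMax 0.2, Tᴺ 30 °C,
Sᴺ 0.06 °C⁻¹, Tᵂ 32 °C, Sᵂ 0.05 °C⁻¹) is a set of **non-calibrated
placeholders**: magnitudes are plausible for modern wheat but fitted to
nothing. Absolute DSI95p/HSI95p values from the fixtures therefore have no
empirical standing; only orderings and directions of change do.

## Paired protocol and indices

For one site × scenario, one weather series (n_years + 1 years, so
autumn-sown seasons always have a full 365-day window) is shared by three
cultivar profiles differing only in the mechanism switches: tolerant (Y),
drought-sensitive-only (Y_D), heat-sensitive-only (Y_H). Switching a
mechanism off suppresses its yield reduction but not the shared canopy
temperature and transpiration diagnostics, so indirect effects stay in the
comparison. Anthesis dates are asserted identical across profiles. Years
with zero tolerant yield are excluded and counted (indices are undefined
there); identical source-limited yields that differ only by float rounding
are snapped to an index of exactly 0.

The 95th percentile uses linear interpolation of order statistics
(rank h = 0.95·(n − 1); for 100 sorted values, x[94] + 0.05·(x[95] − x[94])).
The rule's name is carried in the output metadata because different
percentile conventions move third decimals. A minimum of 20 years is
enforced — below that a 1-in-20-year level is extrapolation. The return
period of level q is 1/(1 − q): 20 years at the 95th percentile, with
n·(1 − q) expected exceedance years.

## Aggregation

Country means are unweighted means over sites of per-site GCM-mean indices;
global means are unweighted over sites (no production weighting — an
extension hook, off by default). For country-level impact reporting the
worst site is selected per country, independently for drought and heat
(the two can and do select different sites), with ties broken toward the
lexicographically smallest site id. Rankings sort descending by the
extreme-site ensemble mean with a stable sort; ensemble spreads are the
(5, 25, 50, 75, 95) percentiles over GCMs of the country-mean index.
Global summaries use plain site means without the extreme-site
substitution, which is a country-level reporting device only.

## Synthetic fixtures: what they emulate, what they don't

The archetypes encode the contrasts that drive the stress indices:
cool/variable (sd of daily tmax 6 °C) versus hot/narrow (sd 2 °C) reproduce
the mechanism by which a climate with a *lower* mean but *wider* temperature
distribution can carry the higher 1-in-20-year heat loss; wet-temperate is
the benign control; dry-continental (90 mm soil, 30 mm initial deficit,
spring-sown) is the water-limited case. Sowing is autumn for temperate
archetypes, spring (doy 75) for continental, shifted half a year south of
the equator; the warm peak is July north / January south. Within-month
temperature autocorrelation is exposed as a free parameter (default 0.6)
rather than asserted.

Fixtures have no geographic realism beyond hemisphere phase, no
inter-variable correlation (rain and temperature anomalies are
independent), and no variability change under future deltas. Passing tests
on them shows the machinery is correct and the mechanisms point the right
way; it says nothing about absolute losses at any real site.

## Problem sizes and determinism

Simulations in the tests use 100-year series for directional/index
properties (×5-member delta ensembles where an ensemble is needed), 200
years for distributional-fidelity checks, and 20–60 years for pipeline
plumbing — sizes at which Monte-Carlo error is comfortably inside the
asserted bounds while the full suite runs in well under a minute. All
randomness flows through explicit integer seeds; per-run seeds are derived
from the master seed and the (site, scenario, GCM) labels via SHA-256 and
kept below 2³¹. Identical inputs give byte-identical outputs, asserted at
the CSV level.

## Known limitations

* The host crop model omits nitrogen, vernalization/photoperiod, frost,
  pests, irrigation and sowing-date adaptation; combined heat × drought
  interaction in a single sensitive cultivar is not evaluated.
* The canopy-temperature surrogate and the placeholder stress parameters
  cap the realism of absolute index values.
* ET is reported both as combined soil + plant flux (ETa/ETp at flowering)
  and as the pure transpiration ratio inside DSF; the two are not
  interchangeable and are kept separate in `SeasonResult`.
* Future scenarios perturb monthly means only; variability and extreme-event
  changes from climate models are not represented.
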