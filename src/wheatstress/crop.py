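"""Simplified process-based wheat season simulation.

One call to :func:`run_season` integrates a single wheat season over daily
weather: thermal-time phenology, a piecewise LAI curve, Beer's-law light
interception, radiation-use-efficiency (RUE) biomass accumulation with a
linear CO2 response, a bucket soil water balance with Priestley-Taylor
potential evapotranspiration, an empirical canopy-temperature surrogate, and
sink-limited grain yield through grain number x grain weight.  The model is
deliberately minimal: it exposes exactly the drivers the flowering-window
stress mechanisms consume (daily Ta/Tp, canopy temperature, anthesis date)
rather than reproducing any full crop model.

Yield formation: ear mass at anthesis is a fixed fraction of shoot biomass;
potential grain number is ``n_pot`` grains per gram of ear mass, reduced by
the drought (R_D) and heat (R_H) factors when the corresponding mechanism
switch is on; single-grain weight is the heat-reduced potential weight
``w_pot * R_W`` capped by the assimilate available per grain (post-anthesis
growth plus a retranslocatable share of anthesis biomass), so extreme grain
losses cannot be fully compensated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParameterError, SeasonFailureError
from .stress import (
    DEFAULT_WINDOWS,
    StressParams,
    StressWindows,
    drought_reduction_factor,
    heat_grain_number_factor,
    heat_grain_weight_factor,
    window_diagnostics,
)
from .weather import DAYS_PER_YEAR

__all__ = [
    "HostConstants",
    "SoilParams",
    "CultivarParams",
    "Management",
    "SeasonResult",
    "WaterState",
    "rue_co2_multiplier",
    "priestley_taylor_et",
    "canopy_tmax",
    "anthesis_day",
    "daily_water_balance",
    "run_season",
    "apply_profile",
    "PROFILES",
]

#: RUE gain per CO2 doubling (fractional), linear in concentration.
RUE_CO2_GAIN_PER_DOUBLING = 0.30


@dataclass(frozen=True)
class HostConstants:
    """Host-model constants, kept in configuration rather than code.

    pt_alpha : Priestley-Taylor coefficient (1.26, standard).
    net_radiation_fraction : net/incoming shortwave radiation ratio.
    latent_heat : latent heat of vaporisation, MJ kg^-1.
    psychrometric : psychrometric constant, kPa / deg C.
    f_crit : fraction of root-accessible capacity below which transpiration
        declines linearly with remaining water.
    canopy_dtmax : maximum canopy-air temperature excess (deg C) of a fully
        water-stressed canopy under saturating radiation.
    canopy_rad_ref : radiation (MJ m^-2 d^-1) at which the canopy excess
        saturates.
    retranslocation_frac : share of anthesis biomass retranslocatable to
        grain during filling.
    """

    pt_alpha: float = 1.26
    net_radiation_fraction: float = 0.7
    latent_heat: float = 2.45
    psychrometric: float = 0.066
    f_crit: float = 0.5
    canopy_dtmax: float = 5.0
    canopy_rad_ref: float = 25.0
    retranslocation_frac: float = 0.25


DEFAULT_CONSTANTS = HostConstants()


@dataclass(frozen=True)
class SoilParams:
    """Bucket-soil parameters.

    sawc : soil available water capacity over the full profile, mm.
    initial_smd : soil moisture deficit at sowing, mm (store starts at
        ``sawc - initial_smd``), carrying over the non-growing-season water
        history.
    max_root_depth_fraction_per_day : linear root-zone growth rate as a
        fraction of the full profile per day (1 => full profile accessible
        immediately).
    """

    sawc: float
    initial_smd: float = 0.0
    max_root_depth_fraction_per_day: float = 1.0 / 90.0

    def __post_init__(self) -> None:
        if self.sawc <= 0:
            raise ParameterError("sawc must be > 0 mm")
        if not 0.0 <= self.initial_smd <= self.sawc:
            raise ParameterError("initial_smd must lie in [0, sawc]")
        if self.max_root_depth_fraction_per_day <= 0:
            raise ParameterError("root growth fraction must be > 0")


@dataclass(frozen=True)
class CultivarParams:
    """Cultivar parameters: phenology, canopy, grain formation and the
    stress-response block with its two mechanism switches."""

    tt_sowing_to_anthesis: float = 1100.0  # deg C d
    tt_anthesis_to_maturity: float = 750.0  # deg C d
    base_temp: float = 0.0  # deg C
    rue_ref: float = 1.2  # g MJ^-1 at reference CO2
    k_light: float = 0.45
    max_lai: float = 6.0
    n_pot: float = 80.0  # grains g^-1 ear mass
    ear_mass_fraction: float = 0.25
    w_pot: float = 0.045  # g grain^-1
    stress: StressParams = field(default_factory=StressParams)
    drought_mech_on: bool = True
    heat_mech_on: bool = True

    def __post_init__(self) -> None:
        if self.tt_sowing_to_anthesis <= 0 or self.tt_anthesis_to_maturity <= 0:
            raise ParameterError("thermal-time requirements must be > 0")
        if not 0.0 < self.ear_mass_fraction < 1.0:
            raise ParameterError("ear_mass_fraction must lie in (0, 1)")
        if self.n_pot <= 0 or self.w_pot <= 0:
            raise ParameterError("n_pot and w_pot must be > 0")
        if self.rue_ref <= 0 or self.k_light <= 0 or self.max_lai <= 0:
            raise ParameterError("rue_ref, k_light and max_lai must be > 0")


#: profile -> (drought_mech_on, heat_mech_on)
PROFILES = {
    "sensitive_both": (True, True),
    "drought_sensitive_only": (True, False),
    "heat_sensitive_only": (False, True),
    "tolerant": (False, False),
}


def apply_profile(cultivar: CultivarParams, profile: str) -> CultivarParams:
    """Copy of ``cultivar`` with the mechanism switches set for ``profile``;
    every other field is untouched."""
    try:
        drought_on, heat_on = PROFILES[profile]
    except KeyError:
        raise ParameterError(
            f"unknown cultivar profile {profile!r}; choose from {sorted(PROFILES)}"
        ) from None
    return replace(cultivar, drought_mech_on=drought_on, heat_mech_on=heat_on)


@dataclass(frozen=True)
class Management:
    """Crop management: sowing day-of-year and atmospheric CO2 (ppm)."""

    sowing_doy: int = 274
    co2: float = 363.8
    co2_ref: float = 363.8


@dataclass
class SeasonResult:
    """Outputs of one simulated season (one weather-year x one cultivar)."""

    anthesis_das: int
    maturity_das: int
    yield_t_ha: float
    grain_number: float  # grains m^-2
    grain_weight: float  # g grain^-1
    eta_at_flowering: float  # mm, cumulative sowing -> anthesis
    etp_at_flowering: float  # mm
    raw_at_flowering: float  # mm
    dsf: float
    r_d: float
    r_h: float
    r_w: float
    tcan_max_pre: float  # deg C, max canopy temp, -10 d -> anthesis
    tcan_max_post: float  # deg C, max canopy temp, +5 -> +12 d
    biomass_at_anthesis: float = 0.0  # g m^-2 shoot dry mass
    biomass_at_maturity: float = 0.0  # g m^-2


@dataclass
class WaterState:
    """Running soil water state, with conservation ledgers (all mm)."""

    store: float
    cum_precip: float = 0.0
    cum_eta: float = 0.0
    cum_etp: float = 0.0
    cum_drainage: float = 0.0


def rue_co2_multiplier(co2: float, co2_ref: float) -> float:
    """Linear RUE response to CO2: +30% per doubling from the reference.

    ``1 + 0.30 * (co2 / co2_ref - 1)``.
    """
    if co2 <= 0 or co2_ref <= 0:
        raise ParameterError("CO2 concentrations must be > 0 ppm")
    return 1.0 + RUE_CO2_GAIN_PER_DOUBLING * (co2 / co2_ref - 1.0)


def priestley_taylor_et(tmean: float, radiation: float, const: HostConstants = DEFAULT_CONSTANTS) -> float:
    """Potential evapotranspiration (mm d^-1) by Priestley-Taylor.

    Uses the slope of the saturation vapour-pressure curve at ``tmean`` and
    a fixed net-radiation fraction of incoming shortwave; needs no wind or
    humidity input.
    """
    es = 0.6108 * math.exp(17.27 * tmean / (tmean + 237.3))
    delta = 4098.0 * es / (tmean + 237.3) ** 2
    rn = const.net_radiation_fraction * max(radiation, 0.0)
    return max(0.0, const.pt_alpha * delta / (delta + const.psychrometric) * rn / const.latent_heat)


def canopy_tmax(
    tmax_air: float,
    supply_ratio: float,
    radiation: float,
    const: HostConstants = DEFAULT_CONSTANTS,
) -> float:
    """Daily maximum canopy temperature (deg C).

    Empirical surrogate for a canopy energy balance: the canopy warms above
    the air by up to ``canopy_dtmax`` as transpiration is curtailed,
    ``tcan = tmax_air + canopy_dtmax * (1 - supply_ratio) * g(radiation)``
    with ``g`` the radiation load clamped to [0, 1].  A fully transpiring
    canopy (supply_ratio = 1) sits at air temperature.
    """
    if not 0.0 <= supply_ratio <= 1.0:
        raise ParameterError(f"supply_ratio must lie in [0, 1], got {supply_ratio}")
    g = min(1.0, max(0.0, radiation / const.canopy_rad_ref))
    return tmax_air + const.canopy_dtmax * (1.0 - supply_ratio) * g


def anthesis_day(weather: pd.DataFrame, cultivar: CultivarParams) -> int:
    """Day after sowing at which anthesis is reached.

    ``weather`` holds daily rows starting at the sowing day.  Returns the
    smallest DAS (1-based) at which cumulative ``max(0, Tmean - base_temp)``
    reaches the sowing-to-anthesis thermal time.
    """
    tmean = (weather["tmax_c"].to_numpy(float) + weather["tmin_c"].to_numpy(float)) / 2.0
    dtt = np.maximum(0.0, tmean - cultivar.base_temp)
    cum = np.cumsum(dtt)
    idx = np.searchsorted(cum, cultivar.tt_sowing_to_anthesis)
    if idx >= len(cum):
        raise SeasonFailureError(
            f"anthesis thermal time {cultivar.tt_sowing_to_anthesis} deg C d not reached "
            f"within {len(cum)} days of sowing"
        )
    return int(idx) + 1


def daily_water_balance(
    state: WaterState,
    tmean: float,
    tmax: float,
    precip: float,
    radiation: float,
    lai: float,
    root_frac: float,
    soil: SoilParams,
    k_light: float,
    const: HostConstants = DEFAULT_CONSTANTS,
) -> dict:
    """Advance the soil water store by one day; returns daily diagnostics.

    Potential ET (Priestley-Taylor) is split into potential transpiration
    ``tp`` (intercepted fraction of light) and potential soil evaporation.
    Actual fluxes are scaled by ``min(1, RAW / (f_crit * root_capacity))``
    where RAW is the root-available water, then capped so they never exceed
    store + rain.  The store update is an exact ledger:
    ``store' = clamp(store + precip - eta, 0, sawc)`` with the overflow
    booked as drainage.
    """
    etp = priestley_taylor_et(tmean, radiation, const)
    f_int = 1.0 - math.exp(-k_light * max(lai, 0.0))
    tp = f_int * etp
    esp = etp - tp

    root_frac = min(1.0, root_frac)
    root_capacity = soil.sawc * root_frac
    raw = state.store * root_frac
    if root_capacity > 0:
        supply = min(1.0, raw / (const.f_crit * root_capacity))
    else:
        supply = 0.0
    ta = tp * supply
    es = esp * supply
    eta = ta + es

    available = state.store + precip
    if eta > available:
        scale = available / eta if eta > 0 else 0.0
        ta *= scale
        es *= scale
        eta = available
    supply_actual = ta / tp if tp > 0 else 1.0

    new_store = state.store + precip - eta
    drainage = max(0.0, new_store - soil.sawc)
    new_store = min(new_store, soil.sawc)
    if new_store < -1e-9:  # bug trap: ledger must never go negative
        raise AssertionError(f"soil store went negative: {new_store}")
    state.store = max(0.0, new_store)
    state.cum_precip += precip
    state.cum_eta += eta
    state.cum_etp += etp
    state.cum_drainage += drainage

    return {
        "etp": etp,
        "tp": tp,
        "ta": ta,
        "es": es,
        "eta": eta,
        "raw": raw,
        "supply_ratio": supply_actual,
        "drainage": drainage,
    }


def run_season(
    weather: pd.DataFrame,
    cultivar: CultivarParams,
    soil: SoilParams,
    management: Management = Management(),
    windows: StressWindows = DEFAULT_WINDOWS,
    window_convention: str = "inclusive",
    const: HostConstants = DEFAULT_CONSTANTS,
) -> SeasonResult:
    """Simulate one wheat season on daily weather starting at sowing.

    ``weather`` must provide at least 365 daily rows from the sowing day
    onward (columns ``tmin_c, tmax_c, precip_mm, rad_mj_m2``); only the
    first 365 are used.  The stress mechanism switches on ``cultivar``
    control whether the drought and heat reduction factors are applied to
    grain formation; the flowering-window diagnostics (DSF, canopy-
    temperature maxima) are computed and reported regardless.
    """
    if len(weather) < DAYS_PER_YEAR:
        raise SeasonFailureError(
            f"need {DAYS_PER_YEAR} days of weather from sowing, got {len(weather)}"
        )
    w = weather.iloc[:DAYS_PER_YEAR]
    tmax = w["tmax_c"].to_numpy(float)
    tmin = w["tmin_c"].to_numpy(float)
    precip = w["precip_mm"].to_numpy(float)
    rad = w["rad_mj_m2"].to_numpy(float)
    tmean = (tmax + tmin) / 2.0

    co2_mult = rue_co2_multiplier(management.co2, management.co2_ref)
    state = WaterState(store=soil.sawc - soil.initial_smd)

    tt_cum = 0.0
    tt_post = 0.0
    anth: Optional[int] = None
    mat: Optional[int] = None
    biomass = 0.0
    biomass_at_anth = 0.0
    eta_fl = etp_fl = raw_fl = 0.0

    n = DAYS_PER_YEAR
    ta_day = np.zeros(n)
    tp_day = np.zeros(n)
    tcan_day = np.zeros(n)

    for i in range(n):
        das = i + 1
        if anth is None:
            lai = cultivar.max_lai * min(1.0, tt_cum / cultivar.tt_sowing_to_anthesis)
        else:
            lai = cultivar.max_lai * max(0.0, 1.0 - tt_post / cultivar.tt_anthesis_to_maturity)
        root_frac = min(1.0, das * soil.max_root_depth_fraction_per_day)

        d = daily_water_balance(
            state, tmean[i], tmax[i], precip[i], rad[i], lai, root_frac,
            soil, cultivar.k_light, const,
        )
        ta_day[i] = d["ta"]
        tp_day[i] = d["tp"]
        tcan_day[i] = canopy_tmax(tmax[i], d["supply_ratio"], rad[i], const)

        if mat is None:
            f_int = 1.0 - math.exp(-cultivar.k_light * lai)
            biomass += cultivar.rue_ref * co2_mult * f_int * rad[i] * d["supply_ratio"]

        dtt = max(0.0, tmean[i] - cultivar.base_temp)
        tt_cum += dtt
        if anth is None:
            if tt_cum >= cultivar.tt_sowing_to_anthesis:
                anth = das
                biomass_at_anth = biomass
                eta_fl, etp_fl, raw_fl = state.cum_eta, state.cum_etp, d["raw"]
        elif mat is None:
            tt_post += dtt
            if tt_post >= cultivar.tt_anthesis_to_maturity:
                mat = das

    if anth is None:
        raise SeasonFailureError(
            f"anthesis thermal time {cultivar.tt_sowing_to_anthesis} deg C d not reached in the season"
        )
    if mat is None:
        raise SeasonFailureError("maturity not reached within 365 days of sowing")

    dsf, tcan_pre, tcan_post = window_diagnostics(
        ta_day, tp_day, tcan_day, anth, windows, window_convention
    )

    p = cultivar.stress
    r_d = drought_reduction_factor(dsf, p) if cultivar.drought_mech_on else 1.0
    r_h = heat_grain_number_factor(tcan_pre, p) if cultivar.heat_mech_on else 1.0
    r_w = heat_grain_weight_factor(tcan_post, p) if cultivar.heat_mech_on else 1.0

    ear_mass = cultivar.ear_mass_fraction * biomass_at_anth  # g m^-2
    grain_number = cultivar.n_pot * ear_mass * r_d * r_h  # grains m^-2
    assimilate = (biomass - biomass_at_anth) + const.retranslocation_frac * biomass_at_anth
    if grain_number > 0:
        grain_weight = min(cultivar.w_pot * r_w, assimilate / grain_number)
    else:
        grain_weight = 0.0
    yield_t_ha = grain_number * grain_weight * 0.01  # g m^-2 -> t ha^-1

    return SeasonResult(
        anthesis_das=anth,
        maturity_das=mat,
        yield_t_ha=yield_t_ha,
        grain_number=grain_number,
        grain_weight=grain_weight,
        eta_at_flowering=eta_fl,
        etp_at_flowering=etp_fl,
        raw_at_flowering=raw_fl,
        dsf=dsf,
        r_d=r_d,
        r_h=r_h,
        r_w=r_w,
        tcan_max_pre=tcan_pre,
        tcan_max_post=tcan_post,
        biomass_at_anthesis=biomass_at_anth,
        biomass_at_maturity=biomass,
    )
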