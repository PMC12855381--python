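"""Self-contained synthetic site / soil / cultivar / GCM-delta fixtures.

Real multi-site weather archives and GCM projections are large and not
redistributable, so every downstream stage is exercised on fixtures that
emulate their statistical structure instead.  Four climate archetypes span
the contrasts that matter for flowering-window stress:

* ``cool_variable`` — cool temperate climate with a wide day-to-day
  temperature distribution: moderate mean, fat warm tail.
* ``hot_narrow`` — hot climate with a flat, narrow temperature
  distribution: high mean, thin tail.
* ``wet_temperate`` — maritime, rain-rich, mild.
* ``dry_continental`` — large seasonal amplitude, little rain,
  spring-sown; the water-limited case.

Monthly temperature means follow a sinusoid of a stated amplitude around the
annual mean, with the warm peak in July north of the equator and January
south of it — the minimal structure able to reproduce a cool-but-variable
versus hot-but-narrow contrast.  Fixture generation is a pure function of
its inputs: identical spec -> identical parameters.

Default cultivar stress parameters are NON-CALIBRATED placeholders of
plausible magnitude; they make the pipeline runnable, not predictive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .crop import CultivarParams, Management, SoilParams, apply_profile
from .errors import ParameterError
from .stress import StressParams
from .weather import ClimateDelta, SiteClimateParams

__all__ = [
    "ARCHETYPES",
    "SiteFixtureSpec",
    "site_spec",
    "make_site_params",
    "make_delta_ensemble",
    "make_cultivar",
    "default_cultivar",
    "default_soil",
    "default_management",
]

#: Archetype presets: (mean_annual_tmax, seasonal_amplitude, tmax_sd,
#: wet_day_prob, mean_wet_amount_mm, radiation_annual_mean, diurnal_range,
#: sowing_doy for the northern hemisphere).
_ARCHETYPE_PRESETS: Dict[str, dict] = {
    "cool_variable": dict(
        mean_annual_tmax=13.0, seasonal_amplitude=9.0, tmax_sd=6.0,
        wet_day_prob=0.45, mean_wet_amount=4.0, radiation_annual_mean=13.0,
        diurnal_range=9.0, sowing_doy=274,
    ),
    "hot_narrow": dict(
        mean_annual_tmax=27.0, seasonal_amplitude=5.0, tmax_sd=2.0,
        wet_day_prob=0.25, mean_wet_amount=4.0, radiation_annual_mean=18.0,
        diurnal_range=12.0, sowing_doy=315,
    ),
    "wet_temperate": dict(
        mean_annual_tmax=15.0, seasonal_amplitude=8.0, tmax_sd=4.0,
        wet_day_prob=0.50, mean_wet_amount=5.0, radiation_annual_mean=12.0,
        diurnal_range=8.0, sowing_doy=274,
    ),
    "dry_continental": dict(
        mean_annual_tmax=14.0, seasonal_amplitude=12.0, tmax_sd=5.0,
        wet_day_prob=0.22, mean_wet_amount=3.0, radiation_annual_mean=15.0,
        diurnal_range=12.0, sowing_doy=75,
    ),
}

ARCHETYPES = tuple(_ARCHETYPE_PRESETS)

_JULY, _JANUARY = 6, 0  # 0-based warm-peak months by hemisphere


@dataclass
class SiteFixtureSpec:
    """Compact description of one synthetic site's climate."""

    site_id: str
    latitude: float
    climate_archetype: str
    seasonal_amplitude: float
    mean_annual_tmax: float
    tmax_sd_by_month: np.ndarray
    wet_day_prob_by_month: np.ndarray
    mean_wet_amount_by_month: np.ndarray
    radiation_annual_mean: float
    seed: int = 0
    diurnal_range: float = 10.0
    temp_autocorr: float = 0.6  # within-month day-to-day persistence, free parameter
    radiation_cv: float = 0.25
    wet_amount_shape: float = 0.75

    def __post_init__(self) -> None:
        if self.climate_archetype not in _ARCHETYPE_PRESETS:
            raise ParameterError(
                f"unknown climate archetype {self.climate_archetype!r}; choose from {list(ARCHETYPES)}"
            )
        for name in ("tmax_sd_by_month", "wet_day_prob_by_month", "mean_wet_amount_by_month"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise ParameterError(f"{name} must have 12 monthly entries")
            setattr(self, name, arr)
        if np.any(self.tmax_sd_by_month < 0):
            raise ParameterError("tmax_sd_by_month must be >= 0")
        if np.any((self.wet_day_prob_by_month < 0) | (self.wet_day_prob_by_month > 1)):
            raise ParameterError("wet_day_prob_by_month must lie in [0, 1]")
        if np.any(self.mean_wet_amount_by_month <= 0):
            raise ParameterError("mean_wet_amount_by_month must be > 0")


def site_spec(archetype: str, site_id: str, latitude: float = 45.0, seed: int = 0) -> SiteFixtureSpec:
    """Fixture spec for a named archetype with its preset monthly structure."""
    if archetype not in _ARCHETYPE_PRESETS:
        raise ParameterError(
            f"unknown climate archetype {archetype!r}; choose from {list(ARCHETYPES)}"
        )
    p = _ARCHETYPE_PRESETS[archetype]
    return SiteFixtureSpec(
        site_id=site_id,
        latitude=latitude,
        climate_archetype=archetype,
        seasonal_amplitude=p["seasonal_amplitude"],
        mean_annual_tmax=p["mean_annual_tmax"],
        tmax_sd_by_month=np.full(12, p["tmax_sd"]),
        wet_day_prob_by_month=np.full(12, p["wet_day_prob"]),
        mean_wet_amount_by_month=np.full(12, p["mean_wet_amount"]),
        radiation_annual_mean=p["radiation_annual_mean"],
        diurnal_range=p["diurnal_range"],
        seed=seed,
    )


def make_site_params(spec: SiteFixtureSpec) -> SiteClimateParams:
    """Expand a fixture spec into full weather-generator parameters.

    Monthly tmax means are a sinusoid of the stated amplitude around the
    annual mean, peaking in July for latitude >= 0 and January otherwise;
    tmin trails tmax by the archetype's diurnal range.  Wet/dry transition
    probabilities are chosen so the chain's stationary wet probability
    equals the stated monthly wet-day probability, with wet spells more
    persistent than chance.  Deterministic: no randomness is consumed.
    """
    months = np.arange(12)
    peak = _JULY if spec.latitude >= 0 else _JANUARY
    phase = np.cos(2.0 * np.pi * (months - peak) / 12.0)
    mm_tmax = spec.mean_annual_tmax + spec.seasonal_amplitude * phase
    mm_tmin = mm_tmax - spec.diurnal_range

    pi = spec.wet_day_prob_by_month
    pww = np.clip(pi + 0.3, 0.0, 0.95)
    with np.errstate(divide="ignore", invalid="ignore"):
        pwd = np.where(pi < 1.0, pi * (1.0 - pww) / (1.0 - pi), 1.0)
    pwd = np.clip(np.nan_to_num(pwd, nan=1.0), 0.0, 1.0)

    rel_amp = float(np.clip(abs(spec.latitude) / 90.0 * 1.1, 0.05, 0.45))
    mm_rad = spec.radiation_annual_mean * (1.0 + rel_amp * phase)

    return SiteClimateParams(
        monthly_mean_tmax=mm_tmax,
        monthly_mean_tmin=mm_tmin,
        monthly_sd_tmax=spec.tmax_sd_by_month.copy(),
        monthly_sd_tmin=spec.tmax_sd_by_month.copy(),
        temp_autocorr=spec.temp_autocorr,
        p_wet_given_dry=pwd,
        p_wet_given_wet=pww,
        wet_amount_shape=np.full(12, spec.wet_amount_shape),
        wet_amount_mean=spec.mean_wet_amount_by_month.copy(),
        monthly_mean_radiation=mm_rad,
        radiation_cv=spec.radiation_cv,
        latitude=spec.latitude,
    )


def make_delta_ensemble(
    n_gcms: int,
    warming_mean: float,
    warming_spread: float,
    precip_factor_range: Tuple[float, float],
    co2: float,
    seed: int,
    radiation_factor_range: Tuple[float, float] = (0.98, 1.02),
) -> List[ClimateDelta]:
    """GCM-like ensemble of delta-change scenarios.

    Each member draws 12 monthly temperature offsets from a normal
    distribution around ``warming_mean`` (the same offset applied to tmax
    and tmin) and monthly precipitation/radiation factors uniformly within
    the stated ranges; all members share the given CO2.  Reproducible under
    ``seed``.
    """
    if n_gcms < 1:
        raise ParameterError("n_gcms must be >= 1")
    if warming_spread < 0:
        raise ParameterError("warming_spread must be >= 0")
    lo, hi = precip_factor_range
    if lo <= 0 or hi < lo:
        raise ParameterError("precip_factor_range must be a positive (low, high) pair")
    rng = np.random.default_rng(seed)
    out: List[ClimateDelta] = []
    for i in range(n_gcms):
        dt = rng.normal(warming_mean, warming_spread, 12)
        pf = rng.uniform(lo, hi, 12)
        rf = rng.uniform(radiation_factor_range[0], radiation_factor_range[1], 12)
        out.append(
            ClimateDelta(
                d_tmax=dt,
                d_tmin=dt.copy(),
                precip_factor=pf,
                radiation_factor=rf,
                co2=co2,
                label=f"gcm{i + 1:02d}",
            )
        )
    return out


def make_cultivar(profile: str, base: CultivarParams) -> CultivarParams:
    """Copy of ``base`` with the drought/heat mechanism switches set for
    ``profile`` (``sensitive_both``, ``drought_sensitive_only``,
    ``heat_sensitive_only`` or ``tolerant``); no other field changes."""
    return apply_profile(base, profile)


def default_cultivar() -> CultivarParams:
    """Generic winter-wheat-like cultivar with placeholder stress block.

    The stress-response values are NOT calibrated against any experiment;
    they are plausible-magnitude placeholders so the pipeline runs end to
    end.
    """
    return CultivarParams(stress=StressParams())


_SOIL_PRESETS: Dict[str, SoilParams] = {
    "cool_variable": SoilParams(sawc=150.0, initial_smd=20.0),
    "hot_narrow": SoilParams(sawc=120.0, initial_smd=40.0),
    "wet_temperate": SoilParams(sawc=180.0, initial_smd=0.0),
    "dry_continental": SoilParams(sawc=90.0, initial_smd=30.0),
}


def default_soil(archetype: str) -> SoilParams:
    """Archetype-matched soil: capacity and sowing-time moisture deficit."""
    try:
        return _SOIL_PRESETS[archetype]
    except KeyError:
        raise ParameterError(f"unknown climate archetype {archetype!r}") from None


def default_management(archetype: str, latitude: float = 45.0, co2: float = 363.8) -> Management:
    """Archetype-matched sowing date (autumn for temperate archetypes,
    spring for continental), shifted half a year south of the equator."""
    if archetype not in _ARCHETYPE_PRESETS:
        raise ParameterError(f"unknown climate archetype {archetype!r}")
    doy = _ARCHETYPE_PRESETS[archetype]["sowing_doy"]
    if latitude < 0:
        doy = (doy + 182 - 1) % 365 + 1
    return Management(sowing_doy=doy, co2=co2)
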