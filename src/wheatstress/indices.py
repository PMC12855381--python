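"""Paired-simulation protocol and the DSI/HSI extreme-stress indices.

The drought and heat stress indices isolate the yield impact of
flowering-window extremes by comparing, on byte-identical weather, a
cultivar sensitive to one stress mechanism with a fully tolerant one
(both mechanisms switched off):

    HSI = 1 - Y_H / Y        DSI = 1 - Y_D / Y

where Y is the tolerant water-limited yield, Y_H the yield of the
heat-only-sensitive cultivar, and Y_D of the drought-only-sensitive one.
Over a 100-year stochastic series the 95th percentile of each index
(DSI95p, HSI95p) is the relative yield loss expected once every 20 years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .crop import (
    DEFAULT_CONSTANTS,
    CultivarParams,
    HostConstants,
    Management,
    SeasonResult,
    SoilParams,
    apply_profile,
    run_season,
)
from .errors import ParameterError, SeasonFailureError, UndefinedIndexError
from .stress import DEFAULT_WINDOWS, StressWindows
from .weather import DAYS_PER_YEAR, ClimateDelta, SiteClimateParams, apply_delta, generate_series

__all__ = [
    "StressIndexSet",
    "dsi",
    "hsi",
    "percentile_95",
    "empirical_percentile",
    "return_period",
    "expected_exceedances",
    "season_slice",
    "run_paired_protocol",
]

PERCENTILE_RULE = "linear interpolation of order statistics (h = q/100 * (n-1))"
MIN_YEARS_FOR_PERCENTILE = 20


def dsi(y_d: float, y: float) -> float:
    """Drought Stress Index for one year: ``1 - Y_D / Y``.

    ``y`` is the tolerant-cultivar yield, ``y_d`` the yield of the cultivar
    sensitive to flowering-window drought only.  Undefined when the
    tolerant yield is zero.
    """
    if y <= 0:
        raise UndefinedIndexError("tolerant yield is zero; stress index undefined for this year")
    return 1.0 - y_d / y


def hsi(y_h: float, y: float) -> float:
    """Heat Stress Index for one year: ``1 - Y_H / Y`` (see :func:`dsi`)."""
    if y <= 0:
        raise UndefinedIndexError("tolerant yield is zero; stress index undefined for this year")
    return 1.0 - y_h / y


def empirical_percentile(values: Sequence[float], q: float) -> float:
    """Empirical percentile by linear interpolation of order statistics.

    For the sorted sample ``x[0..n-1]`` the rank is ``h = q/100 * (n - 1)``
    and the result interpolates linearly between ``x[floor(h)]`` and
    ``x[floor(h) + 1]``.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ParameterError("cannot take a percentile of an empty vector")
    if not 0.0 <= q <= 100.0:
        raise ParameterError("percentile level must lie in [0, 100]")
    h = q / 100.0 * (n - 1)
    lo = int(math.floor(h))
    if lo >= n - 1:
        return float(x[-1])
    frac = h - lo
    return float(x[lo] + frac * (x[lo + 1] - x[lo]))


def percentile_95(values: Sequence[float]) -> float:
    """95th percentile of a per-year index vector.

    Requires at least 20 years: below that, a 1-in-20-year return level is
    extrapolation, not estimation.
    """
    values = np.asarray(values, dtype=float)
    if values.size < MIN_YEARS_FOR_PERCENTILE:
        raise ParameterError(
            f"need >= {MIN_YEARS_FOR_PERCENTILE} values for a 95th percentile "
            f"(a 1-in-20-year return level), got {values.size}"
        )
    return empirical_percentile(values, 95.0)


@dataclass(frozen=True)
class ReturnPeriod:
    """Return period of a percentile level, with the expected number of
    exceedance years in a series of ``n_years`` when given."""

    years: float
    expected_exceedances: Optional[float] = None


def return_period(percentile_level: float, n_years: Optional[int] = None) -> ReturnPeriod:
    """Return period ``1 / (1 - level)`` of exceeding a percentile level.

    Level 0.95 corresponds to a 1-in-20-year event; with ``n_years`` given,
    also reports the expected exceedance count ``n_years * (1 - level)``.
    """
    if not 0.0 < percentile_level < 1.0:
        raise ParameterError("percentile level must lie strictly in (0, 1)")
    years = 1.0 / (1.0 - percentile_level)
    exceed = n_years * (1.0 - percentile_level) if n_years is not None else None
    return ReturnPeriod(years=years, expected_exceedances=exceed)


def expected_exceedances(percentile_level: float, n_years: int) -> float:
    """Expected number of years exceeding the given percentile level."""
    return return_period(percentile_level, n_years).expected_exceedances


@dataclass
class StressIndexSet:
    """Per-year DSI/HSI vectors and their 95th percentiles for one
    site x scenario, plus bookkeeping of excluded years."""

    site_id: str
    scenario_label: str
    dsi_by_year: np.ndarray
    hsi_by_year: np.ndarray
    dsi95p: float
    hsi95p: float
    n_years: int
    exclusions: int = 0
    excluded_years: List[int] = field(default_factory=list)
    percentile_rule: str = PERCENTILE_RULE


def season_slice(series: pd.DataFrame, year_index: int, sowing_doy: int) -> pd.DataFrame:
    """365-day season window starting at ``sowing_doy`` of simulated year
    ``year_index`` (0-based) of a multi-year daily series.

    Autumn-sown seasons run into the following simulated year, so the
    series must extend one year beyond the last season requested.
    """
    start = year_index * DAYS_PER_YEAR + (sowing_doy - 1)
    stop = start + DAYS_PER_YEAR
    if stop > len(series):
        raise SeasonFailureError(
            f"weather series too short for season {year_index} sown on doy {sowing_doy}"
        )
    return series.iloc[start:stop]


def run_paired_protocol(
    site_params: SiteClimateParams,
    soil: SoilParams,
    cultivar: CultivarParams,
    management: Management,
    delta: Optional[ClimateDelta] = None,
    n_years: int = 100,
    seed: int = 0,
    site_id: str = "site",
    scenario_label: str = "baseline",
    windows: StressWindows = DEFAULT_WINDOWS,
    window_convention: str = "inclusive",
    const: HostConstants = DEFAULT_CONSTANTS,
) -> StressIndexSet:
    """Run the three-profile paired protocol for one site x scenario.

    One weather series is generated (after applying ``delta`` when given,
    whose CO2 also overrides the management CO2) and shared byte-identically
    by three cultivar profiles: tolerant (both mechanisms off, yield Y),
    drought-sensitive-only (Y_D) and heat-sensitive-only (Y_H).  Per-year
    DSI/HSI and their 95th percentiles follow.  Years whose tolerant yield
    is zero are excluded from the vectors and counted; a failed season
    raises with its year index.
    """
    params = apply_delta(site_params, delta) if delta is not None else site_params
    co2 = delta.co2 if delta is not None else management.co2
    mgmt = Management(sowing_doy=management.sowing_doy, co2=co2, co2_ref=management.co2_ref)

    # one extra year so autumn-sown seasons have a full 365-day window
    series = generate_series(params, n_years + 1, seed)

    tol = apply_profile(cultivar, "tolerant")
    dro = apply_profile(cultivar, "drought_sensitive_only")
    hot = apply_profile(cultivar, "heat_sensitive_only")

    dsi_vals: List[float] = []
    hsi_vals: List[float] = []
    excluded: List[int] = []
    for y in range(n_years):
        season = season_slice(series, y, mgmt.sowing_doy)
        try:
            res_t = run_season(season, tol, soil, mgmt, windows, window_convention, const)
            res_d = run_season(season, dro, soil, mgmt, windows, window_convention, const)
            res_h = run_season(season, hot, soil, mgmt, windows, window_convention, const)
        except SeasonFailureError as e:
            raise SeasonFailureError(f"site {site_id}, scenario {scenario_label}, year {y}: {e}") from e
        # mechanisms act only after anthesis determination, so phenology
        # must be identical across profiles on shared weather
        assert res_t.anthesis_das == res_d.anthesis_das == res_h.anthesis_das
        if res_t.yield_t_ha <= 0:
            excluded.append(y)
            continue
        # identical source-limited yields can differ by float rounding;
        # snap those to an exact zero index
        d_val = dsi(res_d.yield_t_ha, res_t.yield_t_ha)
        h_val = hsi(res_h.yield_t_ha, res_t.yield_t_ha)
        dsi_vals.append(0.0 if abs(d_val) < 1e-12 else d_val)
        hsi_vals.append(0.0 if abs(h_val) < 1e-12 else h_val)

    if not dsi_vals:
        raise SeasonFailureError(
            f"site {site_id}, scenario {scenario_label}: every year excluded (tolerant yield zero)"
        )

    dsi_arr = np.asarray(dsi_vals)
    hsi_arr = np.asarray(hsi_vals)
    return StressIndexSet(
        site_id=site_id,
        scenario_label=scenario_label,
        dsi_by_year=dsi_arr,
        hsi_by_year=hsi_arr,
        dsi95p=percentile_95(dsi_arr),
        hsi95p=percentile_95(hsi_arr),
        n_years=n_years,
        exclusions=len(excluded),
        excluded_years=excluded,
    )
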