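"""Stochastic daily weather generation and delta-change scenarios.

A site is summarised by monthly climate statistics (:class:`SiteClimateParams`)
estimated from observed daily records.  Long synthetic series are then drawn
from those statistics:

* precipitation occurrence follows a first-order two-state (wet/dry) Markov
  chain with monthly transition probabilities;
* wet-day amounts are gamma distributed with a monthly shape and mean;
* daily maximum temperature is a stationary AR(1) Gaussian anomaly around the
  monthly mean, and minimum temperature follows at a fixed per-month diurnal
  range (so ``tmax >= tmin`` holds by construction);
* daily solar radiation is lognormal around the monthly mean with a single
  coefficient of variation, independent of temperature.

Years are 365 days with fixed month lengths (no leap days).  Future scenarios
are built by the delta-change method: monthly temperature means are shifted
additively and monthly precipitation/radiation means scaled multiplicatively
(:func:`apply_delta`), leaving variability parameters untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ParameterError, WeatherDataError

__all__ = [
    "MONTH_LENGTHS",
    "MONTH_OF_DOY",
    "DAYS_PER_YEAR",
    "SiteClimateParams",
    "ClimateDelta",
    "estimate_params",
    "generate_series",
    "apply_delta",
]

#: Fixed month lengths of the 365-day model calendar.
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
DAYS_PER_YEAR = 365
#: 0-based month index for each day-of-year (1..365).
MONTH_OF_DOY = np.repeat(np.arange(12), MONTH_LENGTHS)

#: Columns of a daily weather frame, in canonical order.
WEATHER_COLUMNS = ["year", "doy", "tmin_c", "tmax_c", "precip_mm", "rad_mj_m2"]

#: Generated wet-day amounts are truncated below at this depth (mm) to avoid
#: degenerate near-zero gamma draws.
MIN_WET_AMOUNT = 0.1

_TEMP_BURN_IN = 100  # AR(1) spin-up days discarded before the series proper


def _as12(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (12,):
        raise ParameterError(f"{name} must have 12 monthly entries, got shape {arr.shape}")
    return arr


@dataclass
class SiteClimateParams:
    """Monthly climate statistics driving the stochastic generator.

    Wet-amount parameters may be NaN for months whose wet probability is
    zero (they are then never sampled); this is how an all-dry month is
    flagged as having undefined amount statistics.
    """

    monthly_mean_tmax: np.ndarray
    monthly_mean_tmin: np.ndarray
    monthly_sd_tmax: np.ndarray
    monthly_sd_tmin: np.ndarray
    temp_autocorr: float
    p_wet_given_dry: np.ndarray
    p_wet_given_wet: np.ndarray
    wet_amount_shape: np.ndarray
    wet_amount_mean: np.ndarray
    monthly_mean_radiation: np.ndarray
    radiation_cv: float
    latitude: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "monthly_mean_tmax",
            "monthly_mean_tmin",
            "monthly_sd_tmax",
            "monthly_sd_tmin",
            "p_wet_given_dry",
            "p_wet_given_wet",
            "wet_amount_shape",
            "wet_amount_mean",
            "monthly_mean_radiation",
        ):
            setattr(self, name, _as12(getattr(self, name), name))
        if np.any(self.monthly_mean_tmax < self.monthly_mean_tmin):
            raise ParameterError("monthly mean tmax must be >= monthly mean tmin")
        if np.any(self.monthly_sd_tmax < 0) or np.any(self.monthly_sd_tmin < 0):
            raise ParameterError("temperature standard deviations must be >= 0")
        for name in ("p_wet_given_dry", "p_wet_given_wet"):
            p = getattr(self, name)
            if np.any((p < 0) | (p > 1)):
                raise ParameterError(f"{name} entries must lie in [0, 1]")
        if not -1.0 < float(self.temp_autocorr) < 1.0:
            raise ParameterError("temp_autocorr must lie in (-1, 1)")
        p_wet_possible = (self.p_wet_given_dry > 0) | (self.p_wet_given_wet > 0)
        shape_def = self.wet_amount_shape[p_wet_possible]
        mean_def = self.wet_amount_mean[p_wet_possible]
        if np.any(~np.isfinite(shape_def)) or np.any(shape_def <= 0):
            raise ParameterError("wet_amount_shape must be finite and > 0 where rain can occur")
        if np.any(~np.isfinite(mean_def)) or np.any(mean_def < 0):
            raise ParameterError("wet_amount_mean must be finite and >= 0 where rain can occur")
        if np.any(self.monthly_mean_radiation < 0) or float(self.radiation_cv) < 0:
            raise ParameterError("radiation parameters must be >= 0")

    def to_dict(self) -> dict:
        out = {}
        for name, val in self.__dict__.items():
            out[name] = val.tolist() if isinstance(val, np.ndarray) else float(val)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SiteClimateParams":
        return cls(**d)


@dataclass
class ClimateDelta:
    """One GCM x period delta-change scenario.

    Temperature offsets are additive (deg C); precipitation and radiation
    factors are multiplicative, applied to the monthly means only.
    """

    d_tmax: np.ndarray
    d_tmin: np.ndarray
    precip_factor: np.ndarray
    radiation_factor: np.ndarray
    co2: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("d_tmax", "d_tmin", "precip_factor", "radiation_factor"):
            setattr(self, name, _as12(getattr(self, name), name))
        if np.any(self.precip_factor < 0) or np.any(self.radiation_factor < 0):
            raise ParameterError("delta factors must be >= 0")
        if float(self.co2) <= 0:
            raise ParameterError("co2 must be > 0 ppm")

    @classmethod
    def identity(cls, co2: float, label: str = "baseline") -> "ClimateDelta":
        """The no-change delta (zero offsets, unit factors)."""
        z, o = np.zeros(12), np.ones(12)
        return cls(d_tmax=z, d_tmin=z.copy(), precip_factor=o, radiation_factor=o.copy(), co2=co2, label=label)

    def to_dict(self) -> dict:
        return {
            "d_tmax": self.d_tmax.tolist(),
            "d_tmin": self.d_tmin.tolist(),
            "precip_factor": self.precip_factor.tolist(),
            "radiation_factor": self.radiation_factor.tolist(),
            "co2": float(self.co2),
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClimateDelta":
        return cls(**d)


def estimate_params(observed: pd.DataFrame, latitude: float = 0.0) -> SiteClimateParams:
    """Estimate site climate parameters from observed daily weather.

    Parameters
    ----------
    observed
        Daily records with columns ``year, doy, tmin_c, tmax_c, precip_mm,
        rad_mj_m2``.  Each year must be complete (day-of-year 1..365); a
        day 366 is dropped so that ordinary leap-year records can be fed in.
    latitude
        Site latitude in degrees, stored on the result (not estimable from
        the weather itself).

    Monthly temperature and radiation moments are the sample statistics of
    the input; wet/dry transition probabilities are maximum-likelihood
    counts of day-to-day transitions per month; gamma shapes come from the
    method of moments on wet-day amounts.  A wet day is any day with
    precipitation > 0 mm.
    """
    missing_cols = [c for c in WEATHER_COLUMNS if c not in observed.columns]
    if missing_cols:
        raise WeatherDataError(f"observed weather is missing columns {missing_cols}")
    df = observed[observed["doy"] <= DAYS_PER_YEAR].sort_values(["year", "doy"]).reset_index(drop=True)

    years = df["year"].unique()
    if len(years) < 3:
        raise WeatherDataError(f"need >= 3 complete years of daily weather, got {len(years)}")
    full = set(range(1, DAYS_PER_YEAR + 1))
    for y, g in df.groupby("year"):
        gap = sorted(full - set(g["doy"]))
        if gap:
            raise WeatherDataError(f"year {y} is missing day-of-year {gap[:10]}{'...' if len(gap) > 10 else ''}")
        if g["doy"].duplicated().any():
            raise WeatherDataError(f"year {y} has duplicated day-of-year entries")

    month = MONTH_OF_DOY[df["doy"].to_numpy() - 1]
    tmax = df["tmax_c"].to_numpy(float)
    tmin = df["tmin_c"].to_numpy(float)
    precip = df["precip_mm"].to_numpy(float)
    rad = df["rad_mj_m2"].to_numpy(float)

    mm_tmax = np.zeros(12)
    mm_tmin = np.zeros(12)
    sd_tmax = np.zeros(12)
    sd_tmin = np.zeros(12)
    mm_rad = np.zeros(12)
    pwd = np.zeros(12)
    pww = np.zeros(12)
    amt_mean = np.full(12, np.nan)
    amt_shape = np.full(12, np.nan)

    wet = precip > 0.0
    prev_wet = np.concatenate(([False], wet[:-1]))
    valid_prev = np.arange(len(df)) > 0  # first day has no predecessor

    for m in range(12):
        sel = month == m
        mm_tmax[m] = tmax[sel].mean()
        mm_tmin[m] = tmin[sel].mean()
        sd_tmax[m] = tmax[sel].std()
        sd_tmin[m] = tmin[sel].std()
        mm_rad[m] = rad[sel].mean()

        vp = sel & valid_prev
        n_dry = np.count_nonzero(vp & ~prev_wet)
        n_wet = np.count_nonzero(vp & prev_wet)
        pwd[m] = np.count_nonzero(vp & ~prev_wet & wet) / n_dry if n_dry else 0.0
        pww[m] = np.count_nonzero(vp & prev_wet & wet) / n_wet if n_wet else 0.0

        amounts = precip[sel & wet]
        if amounts.size:
            amt_mean[m] = amounts.mean()
            var = amounts.var()
            amt_shape[m] = amounts.mean() ** 2 / var if (amounts.size > 1 and var > 0) else 1.0
        # else: all-dry month; amount parameters stay NaN (undefined)

    anom = tmax - mm_tmax[month]
    sd_all = anom.std()
    if sd_all > 0:
        rho = float(np.corrcoef(anom[:-1], anom[1:])[0, 1])
        rho = float(np.clip(rho, -0.99, 0.99))
    else:
        rho = 0.0

    rel = rad / np.where(mm_rad[month] > 0, mm_rad[month], 1.0)
    radiation_cv = float(rel.std()) if np.any(mm_rad > 0) else 0.0

    return SiteClimateParams(
        monthly_mean_tmax=mm_tmax,
        monthly_mean_tmin=mm_tmin,
        monthly_sd_tmax=sd_tmax,
        monthly_sd_tmin=sd_tmin,
        temp_autocorr=rho,
        p_wet_given_dry=pwd,
        p_wet_given_wet=pww,
        wet_amount_shape=amt_shape,
        wet_amount_mean=amt_mean,
        monthly_mean_radiation=mm_rad,
        radiation_cv=radiation_cv,
        latitude=latitude,
    )


def generate_series(params: SiteClimateParams, n_years: int, seed: int) -> pd.DataFrame:
    """Generate ``n_years`` of synthetic daily weather.

    Returns a frame with columns ``year, doy, tmin_c, tmax_c, precip_mm,
    rad_mj_m2`` and ``365 * n_years`` rows.  Identical ``(params, n_years,
    seed)`` give an identical frame.
    """
    if n_years < 1:
        raise ParameterError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    n_days = DAYS_PER_YEAR * n_years
    month = np.tile(MONTH_OF_DOY, n_years)

    # --- precipitation occurrence: two-state Markov chain
    u = rng.random(n_days)
    pwd = params.p_wet_given_dry
    pww = params.p_wet_given_wet
    wet = np.zeros(n_days, dtype=bool)
    prev = False
    for i in range(n_days):
        m = month[i]
        wet[i] = u[i] < (pww[m] if prev else pwd[m])
        prev = wet[i]

    precip = np.zeros(n_days)
    wet_idx = np.flatnonzero(wet)
    if wet_idx.size:
        k = params.wet_amount_shape[month[wet_idx]]
        scale = params.wet_amount_mean[month[wet_idx]] / k
        precip[wet_idx] = np.maximum(rng.gamma(k, scale), MIN_WET_AMOUNT)

    # --- temperature: stationary AR(1) anomaly, fixed diurnal range
    rho = float(params.temp_autocorr)
    eps = rng.standard_normal(n_days + _TEMP_BURN_IN)
    z = lfilter([np.sqrt(1.0 - rho**2)], [1.0, -rho], eps)[_TEMP_BURN_IN:]
    tmax = params.monthly_mean_tmax[month] + params.monthly_sd_tmax[month] * z
    diurnal = params.monthly_mean_tmax - params.monthly_mean_tmin
    tmin = tmax - diurnal[month]

    # --- radiation: lognormal around the monthly mean
    cv = float(params.radiation_cv)
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        rad = params.monthly_mean_radiation[month] * np.exp(
            rng.standard_normal(n_days) * sigma - 0.5 * sigma**2
        )
    else:
        rad = params.monthly_mean_radiation[month].copy()

    idx = np.arange(n_days)
    return pd.DataFrame(
        {
            "year": 1 + idx // DAYS_PER_YEAR,
            "doy": 1 + idx % DAYS_PER_YEAR,
            "tmin_c": tmin,
            "tmax_c": tmax,
            "precip_mm": precip,
            "rad_mj_m2": rad,
        }
    )


def apply_delta(params: SiteClimateParams, delta: ClimateDelta) -> SiteClimateParams:
    """Perturb site parameters by a delta-change scenario.

    Monthly temperature means shift additively; monthly wet-day amount and
    radiation means scale multiplicatively.  Variability parameters
    (standard deviations, autocorrelation, transition probabilities, gamma
    shapes) are unchanged, so successive deltas compose exactly:
    temperatures add, precipitation/radiation factors multiply.
    """
    return replace(
        params,
        monthly_mean_tmax=params.monthly_mean_tmax + delta.d_tmax,
        monthly_mean_tmin=params.monthly_mean_tmin + delta.d_tmin,
        wet_amount_mean=params.wet_amount_mean * delta.precip_factor,
        monthly_mean_radiation=params.monthly_mean_radiation * delta.radiation_factor,
    )
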