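"""Shared fixtures: engineered weather frames and benign/stressed site
parameter sets used across the test modules."""

import numpy as np
import pandas as pd
import pytest

from wheatstress.crop import CultivarParams, Management, SoilParams
from wheatstress.stress import StressParams
from wheatstress.weather import DAYS_PER_YEAR, SiteClimateParams


def constant_weather(
    n_days: int,
    tmax: float = 18.0,
    tmin: float = 8.0,
    precip: float = 0.0,
    rad: float = 12.0,
    wet_every: int = 0,
) -> pd.DataFrame:
    """Constant daily weather; ``wet_every=k`` makes every k-th day wet."""
    p = np.zeros(n_days)
    if wet_every:
        p[::wet_every] = precip
    else:
        p[:] = precip
    idx = np.arange(n_days)
    return pd.DataFrame(
        {
            "year": 1 + idx // DAYS_PER_YEAR,
            "doy": 1 + idx % DAYS_PER_YEAR,
            "tmin_c": np.full(n_days, tmin),
            "tmax_c": np.full(n_days, tmax),
            "precip_mm": p,
            "rad_mj_m2": np.full(n_days, rad),
        }
    )


@pytest.fixture
def benign_weather() -> pd.DataFrame:
    """A mild, well-watered 365-day season: frequent rain, cool days, no
    flowering-window extremes of any kind."""
    return constant_weather(DAYS_PER_YEAR, tmax=18.0, tmin=8.0, precip=9.0, rad=12.0, wet_every=2)


@pytest.fixture
def cultivar() -> CultivarParams:
    return CultivarParams()


@pytest.fixture
def soil() -> SoilParams:
    return SoilParams(sawc=150.0, initial_smd=0.0)


@pytest.fixture
def management() -> Management:
    return Management(sowing_doy=1)


def benign_site_params() -> SiteClimateParams:
    """Stochastic but benign site: mild temperatures with little spread,
    rain on most days; no year should see a flowering-window extreme."""
    return SiteClimateParams(
        monthly_mean_tmax=np.full(12, 18.0),
        monthly_mean_tmin=np.full(12, 8.0),
        monthly_sd_tmax=np.full(12, 0.8),
        monthly_sd_tmin=np.full(12, 0.8),
        temp_autocorr=0.5,
        p_wet_given_dry=np.full(12, 0.6),
        p_wet_given_wet=np.full(12, 0.6),
        wet_amount_shape=np.full(12, 2.0),
        wet_amount_mean=np.full(12, 6.0),
        monthly_mean_radiation=np.full(12, 12.0),
        radiation_cv=0.1,
    )


@pytest.fixture
def benign_params() -> SiteClimateParams:
    return benign_site_params()
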