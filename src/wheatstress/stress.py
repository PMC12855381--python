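"""Flowering-window extreme-drought and extreme-heat response functions.

Wheat is most stress-susceptible around anthesis.  Three multiplicative
reduction factors, each in [0, 1], act on grain set and potential grain
weight:

* ``R_D`` — drought reduction of primary fertile grain number, a piecewise
  linear function of the drought stress factor DSF (the ratio of actual to
  potential transpiration over a window from 10 d before to 5 d after
  anthesis);
* ``R_H`` — heat reduction of grain number, a clamped linear function of the
  maximum canopy temperature over the 10 d before anthesis up to anthesis
  (meiosis and fertilisation);
* ``R_W`` — heat reduction of the potential single-grain weight, the same
  clamped linear form driven by the maximum canopy temperature 5-12 d after
  anthesis (early endosperm development).

All windows are inclusive of both endpoints.  The drought window may also be
evaluated excluding the anthesis day itself (a 15-day count instead of 16),
selected by ``window_convention="exclusive_anthesis"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .errors import ParameterError, SeasonFailureError

__all__ = [
    "StressParams",
    "StressWindows",
    "DEFAULT_WINDOWS",
    "drought_reduction_factor",
    "heat_grain_number_factor",
    "heat_grain_weight_factor",
    "window_diagnostics",
    "drought_window_day_count",
]

WINDOW_CONVENTIONS = ("inclusive", "exclusive_anthesis")


@dataclass(frozen=True)
class StressParams:
    """Cultivar stress-response parameters.

    dsgnt / dsgns / dsgnr_max
        Threshold, saturation and floor of the piecewise drought response:
        no grain loss for DSF above the threshold, maximal loss (grain
        number multiplied by ``dsgnr_max``) at or below saturation, linear
        in between with slope ``(1 - dsgnr_max) / (dsgnt - dsgns)``.
    t_n, s_n
        Canopy-temperature threshold (deg C) and per-degree slope (1/deg C)
        of the grain-number heat response.
    t_w, s_w
        Threshold and slope of the potential grain-weight heat response.

    The shipped defaults (see :func:`wheatstress.synthetic.default_cultivar`)
    are non-calibrated placeholders of plausible magnitude, not values fitted
    to any experiment.
    """

    dsgnt: float = 0.5
    dsgns: float = 0.1
    dsgnr_max: float = 0.2
    t_n: float = 30.0
    s_n: float = 0.06
    t_w: float = 32.0
    s_w: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.dsgns < self.dsgnt <= 1.0):
            raise ParameterError(
                f"need 0 <= dsgns < dsgnt <= 1, got dsgns={self.dsgns}, dsgnt={self.dsgnt}"
            )
        if not 0.0 <= self.dsgnr_max <= 1.0:
            raise ParameterError("dsgnr_max must lie in [0, 1]")
        if self.s_n < 0 or self.s_w < 0:
            raise ParameterError("heat-response slopes must be >= 0")

    @property
    def drought_slope(self) -> float:
        """Slope S of the linear segment, derived (never stored)."""
        return (1.0 - self.dsgnr_max) / (self.dsgnt - self.dsgns)


@dataclass(frozen=True)
class StressWindows:
    """Day-offset intervals around anthesis, inclusive of both endpoints."""

    drought_window: Tuple[int, int] = (-10, 5)
    heat_number_window: Tuple[int, int] = (-10, 0)
    heat_weight_window: Tuple[int, int] = (5, 12)


DEFAULT_WINDOWS = StressWindows()


def drought_window_day_count(convention: str = "inclusive", windows: StressWindows = DEFAULT_WINDOWS) -> int:
    """Number of days in the drought window under the given convention.

    ``inclusive`` counts every day from 10 d before to 5 d after anthesis
    (16 days); ``exclusive_anthesis`` omits the anthesis day itself, giving
    the conventional 15-day count.
    """
    lo, hi = windows.drought_window
    n = hi - lo + 1
    if convention == "exclusive_anthesis":
        return n - (1 if lo <= 0 <= hi else 0)
    if convention != "inclusive":
        raise ParameterError(f"unknown window convention {convention!r}")
    return n


def drought_reduction_factor(dsf: float, p: StressParams) -> float:
    """Drought reduction factor R_D on primary fertile grain number.

    Piecewise linear in the drought stress factor (DSF = Ta/Tp over the
    flowering window): 1 above the threshold ``dsgnt``, the floor
    ``dsgnr_max`` at or below the saturation ``dsgns``, linear in between.
    """
    if not 0.0 <= dsf <= 1.0:
        raise ParameterError(f"DSF must lie in [0, 1], got {dsf}")
    if dsf > p.dsgnt:
        return 1.0
    if dsf <= p.dsgns:
        return p.dsgnr_max
    return p.dsgnr_max + p.drought_slope * (dsf - p.dsgns)


def heat_grain_number_factor(tcan_max: float, p: StressParams) -> float:
    """Heat reduction factor R_H on grain number.

    ``max(0, min(1, 1 - (tcan_max - t_n) * s_n))`` — unity at or below the
    threshold, falling linearly to zero above it.
    """
    return max(0.0, min(1.0, 1.0 - (tcan_max - p.t_n) * p.s_n))


def heat_grain_weight_factor(tcan_max: float, p: StressParams) -> float:
    """Heat reduction factor R_W on potential single-grain weight,
    same clamped linear form with threshold ``t_w`` and slope ``s_w``."""
    return max(0.0, min(1.0, 1.0 - (tcan_max - p.t_w) * p.s_w))


def _window_slice(anthesis_das: int, lo: int, hi: int, n: int, what: str) -> slice:
    a, b = anthesis_das + lo, anthesis_das + hi
    if a < 1 or b > n:
        raise SeasonFailureError(
            f"{what} window [{a}, {b}] falls outside the simulated season (1..{n}); "
            "anthesis too close to a season edge"
        )
    return slice(a - 1, b)  # DAS is 1-based


def window_diagnostics(
    ta: Sequence[float],
    tp: Sequence[float],
    tcan: Sequence[float],
    anthesis_das: int,
    windows: StressWindows = DEFAULT_WINDOWS,
    convention: str = "inclusive",
) -> Tuple[float, float, float]:
    """Compute (dsf, tcan_max_pre, tcan_max_post) from daily series.

    ``ta``, ``tp`` and ``tcan`` are daily actual transpiration, potential
    transpiration and maximum canopy temperature, indexed by day after
    sowing starting at DAS 1.  DSF is the ratio of the window sums of Ta
    and Tp; a window with zero potential transpiration gives DSF = 1 (no
    demand, no stress).
    """
    if convention not in WINDOW_CONVENTIONS:
        raise ParameterError(f"unknown window convention {convention!r}")
    ta = np.asarray(ta, dtype=float)
    tp = np.asarray(tp, dtype=float)
    tcan = np.asarray(tcan, dtype=float)
    n = len(tp)

    lo, hi = windows.drought_window
    sl = _window_slice(anthesis_das, lo, hi, n, "drought")
    ta_w, tp_w = ta[sl], tp[sl]
    if convention == "exclusive_anthesis" and lo <= 0 <= hi:
        keep = np.arange(sl.start, sl.stop) != anthesis_das - 1
        ta_w, tp_w = ta_w[keep], tp_w[keep]
    tp_sum = tp_w.sum()
    dsf = float(ta_w.sum() / tp_sum) if tp_sum > 0 else 1.0
    dsf = min(1.0, max(0.0, dsf))

    lo, hi = windows.heat_number_window
    tcan_max_pre = float(tcan[_window_slice(anthesis_das, lo, hi, n, "heat grain-number")].max())
    lo, hi = windows.heat_weight_window
    tcan_max_post = float(tcan[_window_slice(anthesis_das, lo, hi, n, "heat grain-weight")].max())
    return dsf, tcan_max_pre, tcan_max_post
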