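"""Country-level and global summaries of site x scenario x GCM indices.

Input is the long-format index table produced by the pipeline (one row per
site x scenario x GCM with ``dsi95p``/``hsi95p`` columns).  Country means
average unweighted over a country's sites; GCM-ensemble statistics are taken
over per-GCM values; country-level impact reporting uses the most extreme
site per country, selected independently for drought and heat to reflect the
worst-case exposure within the country.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "CountrySummary",
    "Change",
    "global_mean",
    "select_extreme_site",
    "summarize_countries",
    "rank_countries",
    "relative_change",
]

STRESS_COLUMNS = {"drought": "dsi95p", "heat": "hsi95p"}
SPREAD_LEVELS = (5, 25, 50, 75, 95)


def global_mean(per_site_values: Mapping[str, float]) -> float:
    """Unweighted arithmetic mean of a per-site quantity."""
    if not per_site_values:
        raise ParameterError("cannot average an empty site map")
    return float(np.mean(list(per_site_values.values())))


def select_extreme_site(country_sites: Mapping[str, float], stress_kind: str = "") -> str:
    """Site with the largest (GCM-mean) index in a country.

    Ties break toward the lexicographically smallest site id, so the
    selection is deterministic.  ``stress_kind`` is informational only (the
    drought and heat selections are run independently by the caller).
    """
    if not country_sites:
        raise ParameterError("cannot select an extreme site from an empty map")
    return max(sorted(country_sites), key=lambda s: country_sites[s])


@dataclass
class CountrySummary:
    """Per-country, per-stress-kind summary across scenarios.

    ``mean_index_by_scenario`` averages the GCM-mean index over the
    country's sites; ``extreme_site_by_scenario`` / ``extreme_index_by_scenario``
    hold the worst site and its GCM-mean index; ``ensemble_spread`` gives the
    (5, 25, 50, 75, 95) percentiles of the country-mean index across GCMs.
    """

    country: str
    stress_kind: str
    n_sites: int
    mean_index_by_scenario: Dict[str, float] = field(default_factory=dict)
    extreme_site_by_scenario: Dict[str, str] = field(default_factory=dict)
    extreme_index_by_scenario: Dict[str, float] = field(default_factory=dict)
    ensemble_spread: Dict[str, Tuple[float, float, float, float, float]] = field(default_factory=dict)


def summarize_countries(index_df: pd.DataFrame, stress_kind: str) -> List[CountrySummary]:
    """Build per-country summaries from a long-format index table.

    ``index_df`` needs columns ``site, country, scenario, gcm`` and the
    index column for ``stress_kind`` (``dsi95p`` or ``hsi95p``).
    """
    if stress_kind not in STRESS_COLUMNS:
        raise ParameterError(f"stress_kind must be one of {sorted(STRESS_COLUMNS)}")
    col = STRESS_COLUMNS[stress_kind]
    required = {"site", "country", "scenario", "gcm", col}
    missing = required - set(index_df.columns)
    if missing:
        raise ParameterError(f"index table is missing columns {sorted(missing)}")
    if index_df.empty:
        raise ParameterError("index table is empty")

    out: List[CountrySummary] = []
    for country, cdf in index_df.groupby("country", sort=True):
        summary = CountrySummary(
            country=str(country),
            stress_kind=stress_kind,
            n_sites=cdf["site"].nunique(),
        )
        for scenario, sdf in cdf.groupby("scenario", sort=True):
            per_site = sdf.groupby("site")[col].mean().to_dict()  # GCM-mean per site
            summary.mean_index_by_scenario[scenario] = global_mean(per_site)
            extreme = select_extreme_site(per_site, stress_kind)
            summary.extreme_site_by_scenario[scenario] = extreme
            summary.extreme_index_by_scenario[scenario] = per_site[extreme]
            per_gcm = sdf.groupby("gcm")[col].mean()  # country mean per GCM
            summary.ensemble_spread[scenario] = tuple(
                float(np.percentile(per_gcm, q)) for q in SPREAD_LEVELS
            )
        out.append(summary)
    return out


def rank_countries(
    summaries: List[CountrySummary],
    scenario: str,
    baseline_scenario: Optional[str] = None,
) -> pd.DataFrame:
    """Rank countries by their extreme-site GCM-ensemble-mean index.

    Descending, stable (equal values keep input order).  When
    ``baseline_scenario`` is given, a ``rank_change`` column reports
    baseline rank minus scenario rank (positive = moved up the ranking).
    """
    if not summaries:
        raise ParameterError("no country summaries to rank")
    rows = []
    for s in summaries:
        rows.append(
            {
                "country": s.country,
                "scenario": scenario,
                "stress": s.stress_kind,
                "extreme_site": s.extreme_site_by_scenario.get(scenario, ""),
                "ensemble_mean": s.extreme_index_by_scenario.get(scenario, np.nan),
                **{
                    f"p{q:02d}": s.ensemble_spread.get(scenario, (np.nan,) * 5)[i]
                    for i, q in enumerate(SPREAD_LEVELS)
                },
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values("ensemble_mean", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)

    if baseline_scenario is not None:
        base_order = sorted(
            range(len(summaries)),
            key=lambda i: -summaries[i].extreme_index_by_scenario.get(baseline_scenario, np.nan),
        )
        base_rank = {summaries[i].country: r + 1 for r, i in enumerate(base_order)}
        df["rank_change"] = df["country"].map(base_rank) - df["rank"]
    return df


@dataclass(frozen=True)
class Change:
    """A future-vs-baseline change: percent is None when the baseline is
    zero (undefined relative change); the absolute difference always holds."""

    percent: Optional[float]
    absolute: float

    @property
    def defined(self) -> bool:
        return self.percent is not None


def relative_change(future: float, baseline: float) -> Change:
    """Relative change ``100 * (future - baseline) / baseline`` in percent.

    A zero baseline makes the relative change undefined; the result is then
    flagged and carries the absolute difference instead.
    """
    absolute = future - baseline
    if baseline == 0:
        return Change(percent=None, absolute=absolute)
    return Change(percent=100.0 * absolute / baseline, absolute=absolute)
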