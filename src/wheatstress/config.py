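"""Run configuration, YAML (de)serialisation and provenance helpers.

A run is described by one top-level YAML config naming per-site files and
per-scenario delta files.  A site file bundles everything local: climate
parameters, soil, cultivar (with its stress block) and management.  All
tabular outputs are CSV with ``#``-prefixed provenance header lines (tool
version, config digest, master seed), so a result file alone identifies the
run that produced it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from .crop import CultivarParams, Management, SoilParams
from .errors import ParameterError
from .stress import WINDOW_CONVENTIONS, StressParams
from .weather import ClimateDelta, SiteClimateParams

__all__ = [
    "SiteConfig",
    "ScenarioConfig",
    "RunConfig",
    "load_config",
    "load_site",
    "save_site",
    "load_delta",
    "save_delta",
    "derive_seed",
    "write_csv_with_provenance",
    "read_csv_with_provenance",
]

CO2_BASELINE_DEFAULT = 363.8  # ppm


@dataclass
class SiteConfig:
    """One study site: identity plus all local parameter blocks."""

    site_id: str
    country: str
    climate: SiteClimateParams
    soil: SoilParams
    cultivar: CultivarParams
    management: Management
    path: Optional[Path] = None


@dataclass
class ScenarioConfig:
    """A named future period with its GCM delta files (baseline is implied
    and never listed)."""

    label: str
    delta_paths: List[Path]


@dataclass
class RunConfig:
    """Top-level pipeline configuration."""

    sites: List[Path]
    scenarios: List[ScenarioConfig] = field(default_factory=list)
    n_years: int = 100
    seed: int = 1
    co2_baseline: float = CO2_BASELINE_DEFAULT
    output_dir: Path = Path("out")
    percentile_rule: str = "linear"
    window_convention: str = "inclusive"
    path: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.n_years < 20:
            raise ParameterError("n_years must be >= 20 for 95th-percentile indices")
        if self.window_convention not in WINDOW_CONVENTIONS:
            raise ParameterError(f"window_convention must be one of {WINDOW_CONVENTIONS}")
        if not self.sites:
            raise ParameterError("config lists no sites")
        for p in list(self.sites) + [p for s in self.scenarios for p in s.delta_paths]:
            if not Path(p).exists():
                raise ParameterError(f"referenced path does not exist: {p}")

    def digest(self) -> str:
        """Short digest of the config content, for provenance headers."""
        if self.path is not None and Path(self.path).exists():
            data = Path(self.path).read_bytes()
        else:
            data = repr(self).encode()
        return hashlib.sha256(data).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent
    scenarios = [
        ScenarioConfig(label=s["label"], delta_paths=[base / p for p in s.get("deltas", [])])
        for s in raw.get("scenarios", [])
    ]
    return RunConfig(
        sites=[base / p for p in raw.get("sites", [])],
        scenarios=scenarios,
        n_years=int(raw.get("n_years", 100)),
        seed=int(raw.get("seed", 1)),
        co2_baseline=float(raw.get("co2_baseline", CO2_BASELINE_DEFAULT)),
        output_dir=base / raw.get("output_dir", "out"),
        percentile_rule=raw.get("percentile_rule", "linear"),
        window_convention=raw.get("window_convention", "inclusive"),
        path=path,
    )


def _cultivar_to_dict(c: CultivarParams) -> dict:
    d = {k: v for k, v in c.__dict__.items() if k != "stress"}
    d["stress"] = dict(c.stress.__dict__)
    return d


def _cultivar_from_dict(d: dict) -> CultivarParams:
    d = dict(d)
    stress = StressParams(**d.pop("stress", {}))
    return CultivarParams(stress=stress, **d)


def load_site(path: str | Path) -> SiteConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    try:
        return SiteConfig(
            site_id=raw["site_id"],
            country=raw.get("country", raw["site_id"]),
            climate=SiteClimateParams.from_dict(raw["climate"]),
            soil=SoilParams(**raw["soil"]),
            cultivar=_cultivar_from_dict(raw["cultivar"]),
            management=Management(**raw.get("management", {})),
            path=path,
        )
    except KeyError as e:
        raise ParameterError(f"site file {path} is missing section {e}") from None


def save_site(site: SiteConfig, path: str | Path) -> None:
    path = Path(path)
    doc = {
        "site_id": site.site_id,
        "country": site.country,
        "climate": site.climate.to_dict(),
        "soil": dict(site.soil.__dict__),
        "cultivar": _cultivar_to_dict(site.cultivar),
        "management": dict(site.management.__dict__),
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def load_delta(path: str | Path) -> ClimateDelta:
    return ClimateDelta.from_dict(yaml.safe_load(Path(path).read_text()))


def save_delta(delta: ClimateDelta, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(delta.to_dict(), sort_keys=False))


def derive_seed(master: int, *tokens: object) -> int:
    """Deterministic per-stream seed below 2**31 from a master seed and a
    sequence of identifying tokens (site id, scenario, GCM label, ...)."""
    h = hashlib.sha256("|".join(str(t) for t in tokens).encode()).digest()
    mix = int.from_bytes(h[:4], "big")
    return (int(master) * 2654435761 + mix) % (2**31)


def write_csv_with_provenance(df: pd.DataFrame, path: str | Path, meta: Dict[str, object]) -> None:
    """Write a CSV with ``# key: value`` provenance header lines."""
    from . import __version__

    path = Path(path)
    lines = [f"# tool: wheatstress {__version__}"]
    lines += [f"# {k}: {v}" for k, v in meta.items()]
    path.write_text("\n".join(lines) + "\n" + df.to_csv(index=False))


def read_csv_with_provenance(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
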