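"""YAML pipeline configuration: validated sections for every stage.

An empty file (or no file) yields the all-defaults configuration, whose
constants are the study defaults: GDU base/max 10/30, planting threshold
4.4, emergence 70 GDU, 170-day cycle limit, 0 degC frost rule, 7 t/ha
cap, 75 km band, 16 clusters, 6.1% set-aside, 10% wheat replacement,
7.1 t/ha wheat, 1.39 kg CO2e/kg imports, 3.6 t C/ha/yr sequestration and
7:1 milk substitution.  Unknown keys are rejected with the section and
key named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import FailureRules
from .growth import GrowthConfig
from .phenology import MaturityTargets, PhenologyConfig
from .regionalize import ClusteringConfig
from .scenarios import ScenarioCoefficients

__all__ = ["ConfigError", "SyntheticConfig", "PipelineConfig",
           "load_config", "dump_config"]


class ConfigError(ValueError):
    """Configuration failure naming section, key and constraint."""


@dataclass
class SyntheticConfig:
    """Synthetic-run geometry: grid size, years and archetype band edges."""

    n_lat: int = 6
    n_lon: int = 7
    resolution_deg: float = 0.5
    n_years: int = 5
    start_year: int = 2000
    # latitude band edges assigning archetypes south -> north
    mediterranean_below_lat: float = 44.0
    continental_below_lat: float = 50.0
    maritime_below_lat: float = 57.0

    def __post_init__(self):
        if self.n_lat < 1 or self.n_lon < 1 or self.n_years < 1:
            raise ValueError("grid dimensions and n_years must be >= 1")
        if self.resolution_deg <= 0:
            raise ValueError("resolution_deg must be > 0")


_SECTION_TYPES = {
    "synthetic": SyntheticConfig,
    "phenology": PhenologyConfig,
    "growth": GrowthConfig,
    "failure": FailureRules,
    "clustering": ClusteringConfig,
    "scenarios": ScenarioCoefficients,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "eurosoy_output"
    log_level: str = "INFO"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    phenology: PhenologyConfig = field(default_factory=PhenologyConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    failure: FailureRules = field(default_factory=FailureRules)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    scenarios: ScenarioCoefficients = field(default_factory=ScenarioCoefficients)


def _build_section(name: str, cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"section {name!r}: unknown keys {sorted(unknown)}")
    kwargs = dict(data)
    if name == "phenology" and "mg_targets" in kwargs:
        kwargs["mg_targets"] = {
            mg: MaturityTargets(**spec) for mg, spec in kwargs["mg_targets"].items()
        }
    if name == "phenology":
        for key in ("earliest_planting", "latest_planting"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"section {name!r}: {exc}") from exc


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a pipeline configuration from YAML.

    ``None`` or an empty file gives the all-defaults configuration.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("top level of the config file must be a mapping")

    known_top = {"seed", "output_dir", "log_level", *_SECTION_TYPES}
    unknown = set(data) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")

    sections = {
        name: _build_section(name, cls, data.get(name, {}) or {})
        for name, cls in _SECTION_TYPES.items()
    }
    return PipelineConfig(
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", "eurosoy_output")),
        log_level=str(data.get("log_level", "INFO")),
        **sections,
    )


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Serialize a configuration back to YAML (round-trips through
    :func:`load_config`)."""
    data = {
        "seed": cfg.seed,
        "output_dir": cfg.output_dir,
        "log_level": cfg.log_level,
    }
    for name in _SECTION_TYPES:
        data[name] = _as_plain(getattr(cfg, name))
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
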