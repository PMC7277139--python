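"""Run configuration: YAML parsing and validation.

A run config collects everything a full assessment needs: the accident
scenario, the meteorology source (CSV file or synthetic generator), the
fate parameters, the endpoint rule and the risk parameters.  See
``examples/ulsan_benzyl_chloride.yaml`` for the packaged example.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .endpoint import MOLAR_VOLUME_25C_L
from .exposure import DEFAULT_FACTORS, ExposureFactors, ZoneThresholds, load_factors_csv
from .fate import SoilParameters
from .meteo import AccidentScenario, ChemicalProperties, GridSpec

__all__ = ["ConfigError", "MeteoConfig", "FateConfig", "EndpointConfig",
           "RiskConfig", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or unresolvable run configuration."""


@dataclass(frozen=True)
class MeteoConfig:
    source: str = "synthetic"               # "synthetic" | "file"
    path: str | None = None
    seed: int = 0
    prevailing_from_direction: float = 315.0
    direction_spread: float = 35.0
    speed_mean: float = 2.5
    speed_sd: float = 1.2
    stability_weights: tuple[float, ...] = (0.05, 0.10, 0.15, 0.40, 0.15, 0.15)

    def __post_init__(self) -> None:
        if self.source not in ("synthetic", "file"):
            raise ConfigError(f"meteo source must be synthetic or file, got {self.source!r}")
        if self.source == "file" and not self.path:
            raise ConfigError("meteo source 'file' requires a path")


@dataclass(frozen=True)
class FateConfig:
    n_substeps: int = 6
    soil: SoilParameters = field(default_factory=SoilParameters)
    revolatilization_rate: float = 0.0      # 1/day, off by default
    export_buffer_m: float = 5000.0

    def __post_init__(self) -> None:
        if self.n_substeps < 1:
            raise ConfigError("n_substeps must be at least 1")
        if self.revolatilization_rate < 0 or self.export_buffer_m < 0:
            raise ConfigError("fate rates and buffer must be non-negative")


@dataclass(frozen=True)
class EndpointConfig:
    background_ppb: float | None = None     # None: take from the chemical
    molar_volume_l: float = MOLAR_VOLUME_25C_L


@dataclass(frozen=True)
class RiskConfig:
    csf: float | None = None                # None: take from the chemical
    thresholds: ZoneThresholds = field(default_factory=ZoneThresholds)
    factors: tuple[ExposureFactors, ...] = DEFAULT_FACTORS


@dataclass(frozen=True)
class RunConfig:
    scenario: AccidentScenario
    meteo: MeteoConfig = field(default_factory=MeteoConfig)
    fate: FateConfig = field(default_factory=FateConfig)
    endpoint: EndpointConfig = field(default_factory=EndpointConfig)
    risk: RiskConfig = field(default_factory=RiskConfig)
    out_dir: str = "chemrisk_out"

    def background_ppb(self) -> float:
        if self.endpoint.background_ppb is not None:
            return self.endpoint.background_ppb
        return self.scenario.chemical.background_air_ppb

    def csf(self) -> float:
        if self.risk.csf is not None:
            return self.risk.csf
        return self.scenario.chemical.csf_oral


def _require(mapping: dict, key: str, where: str):
    try:
        return mapping[key]
    except KeyError:
        raise ConfigError(f"missing key {key!r} in {where}") from None


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return config_from_dict(raw, base_dir=path.parent)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def config_from_dict(raw: dict, base_dir: Path | None = None) -> RunConfig:
    base_dir = Path(base_dir) if base_dir is not None else Path.cwd()
    sc = _require(raw, "scenario", "config")
    chem = ChemicalProperties(**_require(sc, "chemical", "scenario"))
    grid_raw = dict(_require(sc, "grid", "scenario"))
    for key in ("origin", "source_cell"):
        if key in grid_raw:
            grid_raw[key] = tuple(grid_raw[key])
    grid = GridSpec(**grid_raw)
    scenario = AccidentScenario(
        chemical=chem,
        release_mass=float(_require(sc, "release_mass_kg", "scenario")),
        release_duration=float(_require(sc, "release_duration_h", "scenario")),
        start_time=pd.Timestamp(_require(sc, "start_time", "scenario")),
        grid=grid,
        horizon_days=int(_require(sc, "horizon_days", "scenario")),
    )

    m = dict(raw.get("meteo", {}))
    if "stability_weights" in m:
        m["stability_weights"] = tuple(m["stability_weights"])
    if m.get("path"):
        p = base_dir / m["path"]
        if not p.exists():
            raise ConfigError(f"meteo file not found: {p}")
        m["path"] = str(p)
    meteo = MeteoConfig(**m)

    f = dict(raw.get("fate", {}))
    if "soil" in f:
        f["soil"] = SoilParameters(**f["soil"])
    fate = FateConfig(**f)

    endpoint = EndpointConfig(**raw.get("endpoint", {}))

    r = dict(raw.get("risk", {}))
    if "thresholds" in r:
        r["thresholds"] = ZoneThresholds(**r["thresholds"])
    if "factors_path" in r:
        p = base_dir / r.pop("factors_path")
        if not p.exists():
            raise ConfigError(f"factors file not found: {p}")
        r["factors"] = load_factors_csv(p)
    risk = RiskConfig(**r)

    return RunConfig(
        scenario=scenario, meteo=meteo, fate=fate, endpoint=endpoint, risk=risk,
        out_dir=str(raw.get("out_dir", "chemrisk_out")),
    )
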