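"""End-to-end orchestration: simulate -> endpoint -> assess -> report.

``run_pipeline`` chains the stages, persists every product as plain
text (ASCII grids, CSV tables, a JSON manifest) and quarantines partial
output under ``failed/`` when a stage aborts.  ``make_fixture`` builds
a miniature scenario used throughout the test suite.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .endpoint import EndpointResult, determine_endpoint, ppb_to_mg_m3
from .exposure import assess, summary_table
from .fate import ConcentrationHistory, run_simulation
from .meteo import (
    AccidentScenario,
    BENZYL_CHLORIDE,
    GridSpec,
    MeteoSeries,
    generate_synthetic_meteo,
    read_meteo_csv,
    wind_rose,
    write_meteo_csv,
)
from .rasters import read_ascii_grid, write_ascii_grid

__all__ = [
    "PipelineError",
    "resolve_meteo",
    "write_history",
    "read_history",
    "run_pipeline",
    "make_fixture",
]


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def resolve_meteo(config: RunConfig, seed: int | None = None) -> MeteoSeries:
    """Produce the meteorology the config asks for (file or synthetic)."""
    n_hours = config.scenario.horizon_days * 24
    mc = config.meteo
    if mc.source == "file":
        return read_meteo_csv(mc.path)
    return generate_synthetic_meteo(
        seed=mc.seed if seed is None else seed,
        n_hours=n_hours,
        prevailing_from_direction=mc.prevailing_from_direction,
        direction_spread=mc.direction_spread,
        speed_mean=mc.speed_mean,
        speed_sd=mc.speed_sd,
        stability_weights=mc.stability_weights,
        start_time=config.scenario.start_time,
    )


def write_history(history: ConcentrationHistory, out_dir) -> Path:
    """Persist daily air/soil fields as ASCII grids plus an index CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for day in range(history.n_days):
        for medium, arr in (("air", history.air_daily), ("soil", history.soil_daily)):
            name = f"{medium}_day{day + 1:03d}.asc"
            write_ascii_grid(arr[day], history.grid, out_dir / name)
            rows.append({"day": day + 1, "medium": medium, "path": name})
    pd.DataFrame(rows).to_csv(out_dir / "index.csv", index=False)
    meta = {
        "n_days": history.n_days,
        "grid": asdict(history.grid),
        "ledger": asdict(history.ledger),
    }
    (out_dir / "history_meta.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def read_history(history_dir) -> ConcentrationHistory:
    """Reload a persisted ConcentrationHistory (ledger restored from meta)."""
    history_dir = Path(history_dir)
    meta = json.loads((history_dir / "history_meta.json").read_text())
    grid_raw = meta["grid"]
    grid_raw["origin"] = tuple(grid_raw["origin"])
    grid_raw["source_cell"] = tuple(grid_raw["source_cell"])
    grid = GridSpec(**grid_raw)
    index = pd.read_csv(history_dir / "index.csv")
    n_days = meta["n_days"]
    air = np.zeros((n_days,) + grid.shape)
    soil = np.zeros_like(air)
    for _, row in index.iterrows():
        arr, _ = read_ascii_grid(history_dir / row["path"])
        (air if row["medium"] == "air" else soil)[int(row["day"]) - 1] = arr
    history = ConcentrationHistory(air_daily=air, soil_daily=soil, grid=grid)
    for key, val in meta.get("ledger", {}).items():
        setattr(history.ledger, key, val)
    return history


def _config_digest(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    out_dir=None,
    seed: int | None = None,
    write_daily_rasters: bool = True,
) -> dict:
    """Run the full chain and write the report bundle.

    Products under ``out_dir``: ``history/`` daily rasters + index,
    ``endpoint.csv`` (day + threshold), ``exceedance_profile.csv``,
    per-group ECR and zone rasters, ``summary.csv``, ``windrose.csv``
    and ``manifest.json``.  Deterministic given config and seed.
    Returns a dict with the in-memory results and paths.
    """
    out_dir = Path(out_dir if out_dir is not None else config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "meteo"
    try:
        t0 = time.perf_counter()
        meteo = resolve_meteo(config, seed=seed)
        rose = wind_rose(meteo, n_sectors=16)
        rose.to_csv(out_dir / "windrose.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "simulate"
        t0 = time.perf_counter()
        history = run_simulation(
            config.scenario,
            meteo,
            soil_params=config.fate.soil,
            n_substeps=config.fate.n_substeps,
            revolatilization_rate=config.fate.revolatilization_rate,
            export_buffer_m=config.fate.export_buffer_m,
        )
        if write_daily_rasters:
            write_history(history, out_dir / "history")
        timings[stage] = time.perf_counter() - t0

        stage = "endpoint"
        t0 = time.perf_counter()
        background = ppb_to_mg_m3(
            config.background_ppb(),
            config.scenario.chemical.molecular_weight,
            config.endpoint.molar_volume_l,
        )
        ep = determine_endpoint(history, background)
        pd.DataFrame(
            {
                "day": np.arange(1, history.n_days + 1),
                "any_cell_exceeds_background": ep.exceedance_profile.astype(int),
            }
        ).to_csv(out_dir / "exceedance_profile.csv", index=False)
        pd.DataFrame(
            [{"endpoint_day": ep.endpoint_day, "background_mg_m3": ep.background_mg_m3}]
        ).to_csv(out_dir / "endpoint.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "assess"
        t0 = time.perf_counter()
        maps = assess(
            history, ep,
            factors_table=config.risk.factors,
            csf=config.csf(),
            thresholds=config.risk.thresholds,
        )
        for m in maps:
            tag = m.group.group_label.replace(">", "gt").replace("-", "_")
            write_ascii_grid(m.ecr, history.grid, out_dir / f"ecr_{tag}.asc")
            write_ascii_grid(
                m.zones.astype(float), history.grid, out_dir / f"zones_{tag}.asc"
            )
        summary = summary_table(maps)
        summary.to_csv(out_dir / "summary.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "manifest"
        manifest = {
            "package": "chemrisk",
            "version": __version__,
            "config_sha256": _config_digest(config),
            "seed": seed,
            "config": json.loads(json.dumps(asdict(config), default=str)),
            "endpoint_day": ep.endpoint_day,
            "mass_ledger": asdict(history.ledger),
            "timings_s": timings,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except BaseException as exc:
        failed = out_dir / "failed"
        failed.mkdir(exist_ok=True)
        for item in list(out_dir.iterdir()):
            if item.name != "failed":
                shutil.move(str(item), str(failed / item.name))
        if isinstance(exc, (KeyboardInterrupt, SystemExit)):
            raise
        raise PipelineError(stage, exc) from exc

    return {
        "out_dir": out_dir,
        "meteo": meteo,
        "history": history,
        "endpoint": ep,
        "risk_maps": maps,
        "summary": summary,
    }


def make_fixture(seed: int = 0) -> tuple[AccidentScenario, MeteoSeries]:
    """Miniature scenario for fast end-to-end runs.

    A 20 x 15 grid of 100 m cells, 5 t of benzyl chloride over one hour
    from a cell in the north-west quadrant, a 10-day horizon and a
    synthetic north-westerly wind, so the plume crosses the small
    domain toward the south-east within hours.
    """
    grid = GridSpec(nx=20, ny=15, dx=100.0, dy=100.0, mixing_height=10.0,
                    source_cell=(4, 10))
    scenario = AccidentScenario(
        chemical=BENZYL_CHLORIDE,
        release_mass=5000.0,
        release_duration=1.0,
        start_time=pd.Timestamp("2017-01-01 00:00"),
        grid=grid,
        horizon_days=10,
    )
    meteo = generate_synthetic_meteo(
        seed=seed, n_hours=scenario.horizon_days * 24,
        prevailing_from_direction=315.0, direction_spread=20.0,
        speed_mean=2.5, speed_sd=0.8,
        start_time=scenario.start_time,
    )
    return scenario, meteo


def write_fixture_files(out_dir, seed: int = 0) -> Path:
    """Materialise the fixture as a config YAML + meteo CSV (CLI helper)."""
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenario, meteo = make_fixture(seed)
    write_meteo_csv(meteo, out_dir / "meteo.csv")
    raw = {
        "scenario": {
            "chemical": asdict(scenario.chemical),
            "release_mass_kg": scenario.release_mass,
            "release_duration_h": scenario.release_duration,
            "start_time": str(scenario.start_time),
            "horizon_days": scenario.horizon_days,
            "grid": {
                "nx": scenario.grid.nx, "ny": scenario.grid.ny,
                "dx": scenario.grid.dx, "dy": scenario.grid.dy,
                "mixing_height": scenario.grid.mixing_height,
                "origin": list(scenario.grid.origin),
                "source_cell": list(scenario.grid.source_cell),
            },
        },
        "meteo": {"source": "file", "path": "meteo.csv"},
        "out_dir": str(out_dir / "run"),
    }
    (out_dir / "scenario.yaml").write_text(yaml.safe_dump(raw, sort_keys=False))
    return out_dir
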