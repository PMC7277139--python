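from pathlib import Path

import numpy as np
import pytest

from chemrisk import (
    ConcentrationHistory,
    GridSpec,
    load_config,
    make_fixture,
    ppb_to_mg_m3,
    resolve_meteo,
    run_simulation,
)
from chemrisk.endpoint import determine_endpoint

EXAMPLES = Path(__file__).resolve().parents[1] / "examples"


@pytest.fixture(scope="session")
def fixture_run():
    """Miniature scenario simulated once for the whole session."""
    scenario, meteo = make_fixture(seed=0)
    history = run_simulation(scenario, meteo)
    return scenario, meteo, history


@pytest.fixture(scope="session")
def ulsan_run():
    """The packaged full-scale example: simulate, endpoint, assess."""
    from chemrisk.exposure import assess

    cfg = load_config(EXAMPLES / "ulsan_benzyl_chloride.yaml")
    meteo = resolve_meteo(cfg)
    history = run_simulation(
        cfg.scenario,
        meteo,
        soil_params=cfg.fate.soil,
        n_substeps=cfg.fate.n_substeps,
        revolatilization_rate=cfg.fate.revolatilization_rate,
        export_buffer_m=cfg.fate.export_buffer_m,
    )
    background = ppb_to_mg_m3(
        cfg.background_ppb(), cfg.scenario.chemical.molecular_weight,
        cfg.endpoint.molar_volume_l,
    )
    ep = determine_endpoint(history, background)
    maps = assess(history, ep, factors_table=cfg.risk.factors, csf=cfg.csf(),
                  thresholds=cfg.risk.thresholds)
    return cfg, history, ep, maps


def history_from_air_series(values, grid: GridSpec | None = None) -> ConcentrationHistory:
    """History whose per-day grid maximum equals ``values`` (one hot cell)."""
    if grid is None:
        grid = GridSpec(nx=3, ny=2)
    values = np.asarray(values, dtype=float)
    air = np.zeros((len(values),) + grid.shape)
    air[:, 0, 0] = values
    soil = np.zeros_like(air)
    return ConcentrationHistory(air_daily=air, soil_daily=soil, grid=grid)
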