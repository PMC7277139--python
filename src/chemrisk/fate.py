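"""Multimedia fate and transport: air dispersion and soil accumulation.

The released mass travels as Gaussian puffs advected by the hourly wind.
Within the shallow surface layer (``GridSpec.mixing_height``) each puff
is treated as vertically well mixed, so its ground-level concentration
is a two-dimensional Gaussian:

    C(r) = m_mg * exp(-r^2 / (2 sigma_y^2)) / (2 pi sigma_y^2 * H)

with ``r`` the horizontal distance from the puff centre, ``sigma_y`` the
lateral spread (Pasquill-Gifford, Briggs open-country power laws) and
``H`` the mixing height.  Airborne mass is lost to first-order decay, to
export once a puff drifts past a buffer beyond the domain, and to dry
deposition onto surface soil at a constant deposition velocity.  Soil
concentrations decay first-order per day and may optionally return to
air through a re-volatilization hook.

Every transfer is booked in a :class:`MassLedger`; the identity

    released = airborne + exported + decayed_in_air + (deposited - revolatilized)

holds to floating-point accuracy at every step, which the simulation
verifies as it runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .meteo import AccidentScenario, ChemicalProperties, GridSpec, MeteoSeries

__all__ = [
    "Puff",
    "SoilParameters",
    "MassLedger",
    "ConcentrationHistory",
    "pg_sigmas",
    "concentration_field",
    "step_hour",
    "deposit_hour",
    "decay_soil_day",
    "run_simulation",
]

# Briggs (open country) interpolation of the Pasquill-Gifford curves:
# sigma = a*x / (1 + b*x)^0.5, x in metres.
_BRIGGS_Y = {
    "A": (0.22, 1e-4), "B": (0.16, 1e-4), "C": (0.11, 1e-4),
    "D": (0.08, 1e-4), "E": (0.06, 1e-4), "F": (0.04, 1e-4),
}
_BRIGGS_Z = {
    "A": (0.20, 0.0), "B": (0.12, 0.0), "C": (0.08, 2e-4),
    "D": (0.06, 1.5e-3), "E": (0.03, 3e-4), "F": (0.016, 3e-4),
}


def pg_sigmas(stability_class: str, downwind_distance_m: float) -> tuple[float, float]:
    """Lateral and vertical dispersion parameters (m) at a travel distance.

    Uses the Briggs open-country power laws for Pasquill classes A-F.
    Both sigmas grow monotonically with distance and unstable classes
    spread faster than stable ones.
    """
    if downwind_distance_m <= 0:
        raise ValueError("downwind_distance_m must be positive")
    try:
        ay, by = _BRIGGS_Y[stability_class]
        az, bz = _BRIGGS_Z[stability_class]
    except KeyError:
        raise ValueError(f"unknown stability class {stability_class!r}") from None
    x = downwind_distance_m
    sigma_y = ay * x / math.sqrt(1.0 + by * x)
    sigma_z = az * x / math.sqrt(1.0 + bz * x) if bz else az * x
    return sigma_y, sigma_z


@dataclass
class Puff:
    """One parcel of released mass.

    ``x``/``y`` are planar metres (east/north of the grid origin);
    ``travel_distance`` accumulates advection and drives the sigma
    growth; ``sigma_z`` is carried for completeness but unused by the
    well-mixed vertical treatment.
    """

    mass: float                 # kg
    x: float
    y: float
    sigma_y: float = 1.0
    sigma_z: float = 1.0
    age: float = 0.0            # hours
    travel_distance: float = 0.0


@dataclass(frozen=True)
class SoilParameters:
    """Surface-soil receptor: bulk density (kg/m3) and mixing depth (m)."""

    bulk_density: float = 1300.0
    mixing_depth: float = 0.01

    def __post_init__(self) -> None:
        if self.bulk_density <= 0 or self.mixing_depth <= 0:
            raise ValueError("bulk_density and mixing_depth must be positive")

    def areal_mass(self) -> float:
        """kg of soil per m2 of surface."""
        return self.bulk_density * self.mixing_depth


@dataclass
class MassLedger:
    """Running mass account of the simulation, all in kg."""

    released: float = 0.0
    airborne: float = 0.0
    exported: float = 0.0
    decayed_air: float = 0.0
    deposited: float = 0.0
    revolatilized: float = 0.0
    max_closure_error: float = 0.0   # worst relative imbalance seen

    def closure_error(self) -> float:
        """Relative imbalance of the mass identity (0 when nothing released)."""
        if self.released == 0:
            return 0.0
        balance = (
            self.airborne
            + self.exported
            + self.decayed_air
            + self.deposited
            - self.revolatilized
        )
        return abs(self.released - balance) / self.released


@dataclass
class ConcentrationHistory:
    """Daily-average air (mg/m3) and end-of-day soil (mg/kg) fields.

    Arrays are shaped ``(n_days, ny, nx)`` with row 0 at the southern
    edge.  Day 1 of the accident is index 0.
    """

    air_daily: np.ndarray
    soil_daily: np.ndarray
    grid: GridSpec
    ledger: MassLedger = field(default_factory=MassLedger)

    def __post_init__(self) -> None:
        for name, arr in (("air_daily", self.air_daily), ("soil_daily", self.soil_daily)):
            if arr.ndim != 3:
                raise ValueError(f"{name} must be (n_days, ny, nx)")
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValueError(f"{name} must be finite and non-negative")
        if self.air_daily.shape != self.soil_daily.shape:
            raise ValueError("air_daily and soil_daily shapes differ")
        if self.air_daily.shape[1:] != self.grid.shape:
            raise ValueError("fields do not match the grid")

    @property
    def n_days(self) -> int:
        return self.air_daily.shape[0]

    def daily_air_max(self) -> np.ndarray:
        return self.air_daily.max(axis=(1, 2))

    def daily_soil_max(self) -> np.ndarray:
        return self.soil_daily.max(axis=(1, 2))

    def daily_soil_min(self) -> np.ndarray:
        return self.soil_daily.min(axis=(1, 2))


def _transport_unit_vector(wind_from_deg: float) -> tuple[float, float]:
    # Wind FROM theta transports TOWARD theta + 180 (compass bearing).
    bearing = math.radians(wind_from_deg + 180.0)
    return math.sin(bearing), math.cos(bearing)


def concentration_field(puffs: list[Puff], grid: GridSpec) -> np.ndarray:
    """Ground-layer air concentration (mg/m3) from a set of puffs.

    Evaluates the well-mixed Gaussian-puff kernel at every cell centre.
    """
    xc = grid.x_centres()[None, :]
    yc = grid.y_centres()[:, None]
    out = np.zeros(grid.shape)
    for p in puffs:
        if p.mass <= 0:
            continue
        r2 = (xc - p.x) ** 2 + (yc - p.y) ** 2
        out += (
            p.mass * 1e6
            * np.exp(-r2 / (2.0 * p.sigma_y**2))
            / (2.0 * math.pi * p.sigma_y**2 * grid.mixing_height)
        )
    return out


def _pg_sigma_y_array(stability_class: str, x: np.ndarray) -> np.ndarray:
    ay, by = _BRIGGS_Y[stability_class]
    return ay * x / np.sqrt(1.0 + by * x)


def _segment_kernel(
    grid: GridSpec,
    x0: float, y0: float, t0: float,
    x1: float, y1: float, t1: float,
    stability_class: str,
    sigma_floor: float,
) -> np.ndarray:
    """Column-weight field of a puff averaged along one advection segment.

    A puff can cross many cells in one sub-step, so evaluating its kernel
    only at the end point would leave a punctate deposit track.  Sampling
    the kernel at midpoints spaced at most half a cell apart along the
    segment (with the sigma growing along it) integrates the passage the
    way a slug/line-segment source would.
    """
    step = math.hypot(x1 - x0, y1 - y0)
    n = max(1, math.ceil(step / (grid.dx / 2.0)))
    f = (np.arange(n) + 0.5) / n
    xs = x0 + f * (x1 - x0)
    ys = y0 + f * (y1 - y0)
    travels = np.maximum(t0 + f * (t1 - t0), 1.0)
    sy = np.maximum(_pg_sigma_y_array(stability_class, travels), sigma_floor)
    xc = grid.x_centres()
    yc = grid.y_centres()
    r2 = (xc[None, None, :] - xs[:, None, None]) ** 2 + (
        yc[None, :, None] - ys[:, None, None]
    ) ** 2
    sy = sy[:, None, None]
    w = np.exp(-r2 / (2.0 * sy**2)) * (grid.cell_area / (2.0 * math.pi * sy**2))
    return w.mean(axis=0)


def step_hour(
    puffs: list[Puff],
    meteo_record,
    chemical: ChemicalProperties,
    grid: GridSpec,
    dt_hours: float = 1.0,
    export_buffer_m: float = 5000.0,
    sigma_floor: float | None = None,
) -> tuple[list[Puff], np.ndarray, dict]:
    """Advance puffs by one interval and evaluate the air field.

    Each puff is advected ``wind_speed * 3600 * dt_hours`` metres toward
    ``wind_direction + 180``, its sigmas are refreshed from the
    cumulative travel distance under the current stability class, and
    its mass decays by ``exp(-air_decay_rate * dt_hours)``.  Puffs whose
    centre leaves the domain by more than ``export_buffer_m`` are
    dropped and their mass booked as exported.

    Returns the surviving puffs, the concentration field (mg/m3) and a
    diagnostics dict with ``exported_kg`` and ``decayed_kg``.
    """
    if sigma_floor is None:
        sigma_floor = grid.dx / 2.0
    u = float(meteo_record["wind_speed"])
    theta = float(meteo_record["wind_direction"])
    sclass = str(meteo_record["stability_class"])
    ex, ey = _transport_unit_vector(theta)
    step = u * 3600.0 * dt_hours
    decay_factor = math.exp(-chemical.air_decay_rate * dt_hours)

    x_lo = grid.origin[0] - export_buffer_m
    x_hi = grid.origin[0] + grid.nx * grid.dx + export_buffer_m
    y_lo = grid.origin[1] - export_buffer_m
    y_hi = grid.origin[1] + grid.ny * grid.dy + export_buffer_m

    kept: list[Puff] = []
    exported = 0.0
    decayed = 0.0
    for p in puffs:
        p.x += step * ex
        p.y += step * ey
        p.travel_distance += step
        p.age += dt_hours
        decayed += p.mass * (1.0 - decay_factor)
        p.mass *= decay_factor
        sy, sz = pg_sigmas(sclass, max(p.travel_distance, 1.0))
        p.sigma_y = max(sy, sigma_floor)
        p.sigma_z = max(sz, 1.0)
        if x_lo <= p.x <= x_hi and y_lo <= p.y <= y_hi:
            kept.append(p)
        else:
            exported += p.mass
    field_mg_m3 = concentration_field(kept, grid)
    return kept, field_mg_m3, {"exported_kg": exported, "decayed_kg": decayed}


def deposit_hour(
    air_field: np.ndarray,
    chemical: ChemicalProperties,
    soil_params: SoilParameters,
    soil_field: np.ndarray,
    dt_s: float = 3600.0,
) -> np.ndarray:
    """Add one interval of dry deposition to the soil field.

    Per cell the deposition flux is ``deposition_velocity * C`` (mg/m2/s);
    over ``dt_s`` seconds the soil concentration increment is
    ``v_d * C * dt_s / (bulk_density * mixing_depth)`` mg/kg.
    """
    if air_field.shape != soil_field.shape:
        raise ValueError("air and soil fields must share a shape")
    increment = (
        chemical.deposition_velocity * air_field * dt_s / soil_params.areal_mass()
    )
    return soil_field + increment


def decay_soil_day(soil_field: np.ndarray, chemical: ChemicalProperties) -> np.ndarray:
    """Apply one day of first-order soil loss."""
    return soil_field * math.exp(-chemical.soil_decay_rate)


def run_simulation(
    scenario: AccidentScenario,
    meteo: MeteoSeries,
    soil_params: SoilParameters | None = None,
    n_substeps: int = 6,
    revolatilization_rate: float = 0.0,
    export_buffer_m: float = 5000.0,
) -> ConcentrationHistory:
    """Simulate the accident and return daily air and soil fields.

    The release is emitted as one puff per sub-step over
    ``release_duration``.  Each hour is integrated in ``n_substeps``
    explicit sub-steps so that the surface-loss rate ``v_d / H`` (1.8/h
    at the defaults) never removes more mass than a parcel holds.  Daily
    air fields are the mean of the 24 hourly fields; soil is recorded at
    the end of each day after its daily decay.

    ``revolatilization_rate`` (1/day, default off) returns a first-order
    fraction of each cell's soil burden to the local air column, where a
    ventilation box model (wind floored at 0.5 m/s) converts the flux to
    a concentration before the mass is vented (booked as exported).
    Deterministic given scenario and meteorology.
    """
    if soil_params is None:
        soil_params = SoilParameters()
    grid = scenario.grid
    chem = scenario.chemical
    n_hours = scenario.horizon_days * 24
    if len(meteo) < n_hours:
        raise ValueError(
            f"meteorology covers {len(meteo)} h but the horizon needs {n_hours} h"
        )

    air_daily = np.zeros((scenario.horizon_days,) + grid.shape)
    soil_daily = np.zeros_like(air_daily)
    soil = np.zeros(grid.shape)
    ledger = MassLedger()
    puffs: list[Puff] = []
    src_x, src_y = grid.source_xy()
    dt_h = 1.0 / n_substeps
    dt_s = 3600.0 * dt_h
    k_dep = chem.deposition_velocity / grid.mixing_height   # 1/s
    cell_soil_kg = soil_params.areal_mass() * grid.cell_area
    revol_frac_hour = 1.0 - math.exp(-revolatilization_rate / 24.0)
    wind = meteo.df["wind_speed"].to_numpy()

    for day in range(scenario.horizon_days):
        day_sum = np.zeros(grid.shape)
        for hh in range(24):
            h = day * 24 + hh
            record = meteo.record(h)
            releasing = h < scenario.release_duration
            hour_field = np.zeros(grid.shape)
            if releasing or puffs:
                u = float(record["wind_speed"])
                sclass = str(record["stability_class"])
                ex, ey = _transport_unit_vector(float(record["wind_direction"]))
                step = u * 3600.0 * dt_h
                decay_factor = math.exp(-chem.air_decay_rate * dt_h)
                sigma_floor = grid.dx / 2.0
                x_lo = grid.origin[0] - export_buffer_m
                x_hi = grid.origin[0] + grid.nx * grid.dx + export_buffer_m
                y_lo = grid.origin[1] - export_buffer_m
                y_hi = grid.origin[1] + grid.ny * grid.dy + export_buffer_m
                for s in range(n_substeps):
                    t_h = h + s * dt_h
                    if t_h < scenario.release_duration:
                        emit = (
                            scenario.release_mass
                            * min(dt_h, scenario.release_duration - t_h)
                            / scenario.release_duration
                        )
                        puffs.append(Puff(mass=emit, x=src_x, y=src_y,
                                          sigma_y=sigma_floor))
                        ledger.released += emit
                    kept: list[Puff] = []
                    dep_mg = np.zeros(grid.shape)
                    for p in puffs:
                        x0, y0, t0 = p.x, p.y, p.travel_distance
                        p.x += step * ex
                        p.y += step * ey
                        p.travel_distance += step
                        p.age += dt_h
                        ledger.decayed_air += p.mass * (1.0 - decay_factor)
                        p.mass *= decay_factor
                        sy, sz = pg_sigmas(sclass, max(p.travel_distance, 1.0))
                        p.sigma_y = max(sy, sigma_floor)
                        p.sigma_z = max(sz, 1.0)
                        if not (x_lo <= p.x <= x_hi and y_lo <= p.y <= y_hi):
                            ledger.exported += p.mass
                            continue
                        w = _segment_kernel(
                            grid, x0, y0, t0, p.x, p.y, p.travel_distance,
                            sclass, sigma_floor,
                        )
                        hour_field += (
                            p.mass * 1e6 * w
                            / (grid.cell_area * grid.mixing_height * n_substeps)
                        )
                        cell_dep = p.mass * 1e6 * k_dep * dt_s * w
                        debit = cell_dep.sum() * 1e-6
                        p.mass -= debit
                        ledger.deposited += debit
                        dep_mg += cell_dep
                        kept.append(p)
                    puffs = kept
                    soil += dep_mg / cell_soil_kg

            if revolatilization_rate > 0.0 and soil.any():
                emitted_mg = soil * cell_soil_kg * revol_frac_hour
                soil = soil * (1.0 - revol_frac_hour)
                u_eff = max(float(wind[h]), 0.5)
                ventilation_m3 = u_eff * 3600.0 * grid.dx * grid.mixing_height
                hour_field = hour_field + emitted_mg / ventilation_m3
                vented = emitted_mg.sum() * 1e-6
                ledger.revolatilized += vented
                ledger.exported += vented

            day_sum += hour_field
            ledger.airborne = sum(p.mass for p in puffs)
            ledger.max_closure_error = max(
                ledger.max_closure_error, ledger.closure_error()
            )
        air_daily[day] = day_sum / 24.0
        soil = decay_soil_day(soil, chem)
        soil_daily[day] = soil

    return ConcentrationHistory(
        air_daily=air_daily, soil_daily=soil_daily, grid=grid, ledger=ledger
    )
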