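"""Accident scenario definition and hourly meteorology.

The dispersion and deposition stages are driven by an hourly series of
wind speed, wind direction and Pasquill stability class.  Real archives
(e.g. a national weather service export) are read from CSV; for
controlled experiments a seeded parametric generator produces a series
with a configurable prevailing direction.

Directions follow the meteorological convention throughout: degrees the
wind blows FROM, 0 deg = north, increasing clockwise.  A plume is
therefore transported toward ``direction + 180``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STABILITY_CLASSES",
    "GridSpec",
    "ChemicalProperties",
    "AccidentScenario",
    "MeteoSeries",
    "MeteoParseError",
    "BENZYL_CHLORIDE",
    "ulsan_grid",
    "ulsan_scenario",
    "generate_synthetic_meteo",
    "read_meteo_csv",
    "write_meteo_csv",
    "wind_rose",
]

#: Pasquill stability categories, most unstable (A) to most stable (F).
STABILITY_CLASSES = ("A", "B", "C", "D", "E", "F")

METEO_COLUMNS = ["timestamp", "wind_speed", "wind_direction", "stability_class"]


class MeteoParseError(ValueError):
    """A meteorology CSV failed validation; the message names the row."""


@dataclass(frozen=True)
class GridSpec:
    """Regular planar raster on which concentrations are evaluated.

    Cell (0, 0) sits at the south-west corner; cell centres are at
    ``origin + (i + 0.5) * dx`` (east) and ``origin + (j + 0.5) * dy``
    (north).  ``mixing_height`` is the vertical extent of the surface
    layer within which airborne mass is treated as uniformly mixed.
    """

    nx: int
    ny: int
    dx: float = 100.0
    dy: float = 100.0
    mixing_height: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)
    source_cell: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")
        if self.dx <= 0 or self.dy <= 0 or self.mixing_height <= 0:
            raise ValueError("dx, dy and mixing_height must be positive")
        i, j = self.source_cell
        if not (0 <= i < self.nx and 0 <= j < self.ny):
            raise ValueError(f"source_cell {self.source_cell} outside grid")

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(ny, nx)``: rows are south-to-north."""
        return (self.ny, self.nx)

    def x_centres(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.nx) + 0.5) * self.dx

    def y_centres(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.ny) + 0.5) * self.dy

    def source_xy(self) -> tuple[float, float]:
        i, j = self.source_cell
        return (
            self.origin[0] + (i + 0.5) * self.dx,
            self.origin[1] + (j + 0.5) * self.dy,
        )


@dataclass(frozen=True)
class ChemicalProperties:
    """Physicochemical and toxicological constants of the released substance.

    Parameters
    ----------
    molecular_weight
        g/mol; used to convert the ppb background threshold to mg/m3.
    csf_oral
        Oral cancer slope factor, per mg/kg-day.
    background_air_ppb
        Ambient air concentration absent the accident; the extinction
        endpoint compares simulated air levels against it.
    air_decay_rate
        First-order loss in air, 1/h (photo-oxidation etc.).
    soil_decay_rate
        First-order loss in surface soil, 1/day (hydrolysis etc.).
    deposition_velocity
        Dry-deposition proportionality between air concentration and
        surface flux, m/s.
    """

    name: str
    molecular_weight: float
    csf_oral: float = 0.0
    background_air_ppb: float = 0.0
    air_decay_rate: float = 0.0
    soil_decay_rate: float = 0.0
    deposition_velocity: float = 0.005

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        for attr in (
            "csf_oral",
            "background_air_ppb",
            "air_decay_rate",
            "soil_decay_rate",
            "deposition_velocity",
        ):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")


#: Benzyl chloride (C7H7Cl).  Slope factor and air background from the
#: standard oral dose-response assessment; decay rates are screening-level
#: first-order constants (see docs/methods.md for the derivation).
BENZYL_CHLORIDE = ChemicalProperties(
    name="benzyl chloride",
    molecular_weight=126.58,
    csf_oral=0.17,
    background_air_ppb=0.01,
    air_decay_rate=0.0144,   # ~2-day half-life vs. OH radicals
    soil_decay_rate=0.06,    # ~12-day surface-soil half-life
    deposition_velocity=0.005,
)


@dataclass(frozen=True)
class AccidentScenario:
    """A release event: what, how much, where, when, and for how long."""

    chemical: ChemicalProperties
    release_mass: float          # kg
    release_duration: float      # hours
    start_time: pd.Timestamp
    grid: GridSpec
    horizon_days: int

    def __post_init__(self) -> None:
        if self.release_mass < 0:
            raise ValueError("release_mass must be non-negative")
        if self.release_duration <= 0:
            raise ValueError("release_duration must be positive")
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be at least 1")


def ulsan_grid() -> GridSpec:
    """16 km x 12 km domain of 100 m cells, 10 m surface layer, central source."""
    return GridSpec(
        nx=160, ny=120, dx=100.0, dy=100.0, mixing_height=10.0,
        source_cell=(80, 60),
    )


def ulsan_scenario(horizon_days: int = 100) -> AccidentScenario:
    """Packaged example: 40 t of benzyl chloride over 1 h, midnight start."""
    return AccidentScenario(
        chemical=BENZYL_CHLORIDE,
        release_mass=40_000.0,
        release_duration=1.0,
        start_time=pd.Timestamp("2017-01-01 00:00"),
        grid=ulsan_grid(),
        horizon_days=horizon_days,
    )


@dataclass
class MeteoSeries:
    """Gap-free hourly meteorology.

    Wraps a DataFrame with columns ``timestamp`` (hourly, monotone),
    ``wind_speed`` (m/s, >= 0), ``wind_direction`` (deg from, [0, 360))
    and ``stability_class`` (A-F).
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _validate_meteo_frame(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeteoSeries):
            return NotImplemented
        return self.df.equals(other.df)

    def record(self, hour: int) -> pd.Series:
        return self.df.iloc[hour]


def _validate_meteo_frame(df: pd.DataFrame) -> None:
    missing = [c for c in METEO_COLUMNS if c not in df.columns]
    if missing:
        raise MeteoParseError(f"missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise MeteoParseError("meteorology series is empty")
    ts = pd.to_datetime(df["timestamp"])
    deltas = ts.diff().dropna()
    bad = deltas[deltas != pd.Timedelta(hours=1)]
    if len(bad):
        row = bad.index[0]
        raise MeteoParseError(
            f"non-hourly step at row {row} ({ts.iloc[row - 1]} -> {ts.iloc[row]})"
        )
    if (df["wind_speed"] < 0).any():
        row = int(df.index[df["wind_speed"] < 0][0])
        raise MeteoParseError(f"negative wind_speed at row {row}")
    out = (df["wind_direction"] < 0) | (df["wind_direction"] >= 360)
    if out.any():
        row = int(df.index[out][0])
        raise MeteoParseError(
            f"wind_direction out of [0, 360) at row {row} "
            f"({df['wind_direction'].iloc[row]})"
        )
    unknown = ~df["stability_class"].isin(STABILITY_CLASSES)
    if unknown.any():
        row = int(df.index[unknown][0])
        raise MeteoParseError(
            f"unknown stability_class {df['stability_class'].iloc[row]!r} at row {row}"
        )


def generate_synthetic_meteo(
    seed: int,
    n_hours: int,
    prevailing_from_direction: float = 315.0,
    direction_spread: float = 35.0,
    speed_mean: float = 2.5,
    speed_sd: float = 1.2,
    stability_weights: Sequence[float] = (0.05, 0.10, 0.15, 0.40, 0.15, 0.15),
    start_time: pd.Timestamp | str = "2017-01-01 00:00",
) -> MeteoSeries:
    """Generate a seeded synthetic hourly wind series.

    Directions are drawn from a wrapped normal around
    ``prevailing_from_direction`` (so a 315 deg prevailing wind blows from
    the north-west and transports the plume south-east); speeds from a
    normal truncated at zero; stability classes from the categorical
    distribution ``stability_weights`` over A..F.  Identical arguments
    give a bit-identical series.
    """
    if n_hours < 1:
        raise ValueError("n_hours must be at least 1")
    if speed_mean <= 0:
        raise ValueError("speed_mean must be positive")
    if direction_spread < 0:
        raise ValueError("direction_spread must be non-negative")
    weights = np.asarray(stability_weights, dtype=float)
    if weights.shape != (6,) or (weights < 0).any() or weights.sum() == 0:
        raise ValueError(
            "stability_weights must be six non-negative values, not all zero"
        )

    rng = np.random.default_rng(seed)
    directions = (
        prevailing_from_direction + rng.normal(0.0, direction_spread, n_hours)
    ) % 360.0
    if speed_sd > 0:
        a = (0.0 - speed_mean) / speed_sd
        speeds = stats.truncnorm.rvs(
            a, np.inf, loc=speed_mean, scale=speed_sd, size=n_hours, random_state=rng
        )
    else:
        speeds = np.full(n_hours, speed_mean)
    classes = rng.choice(
        np.array(STABILITY_CLASSES), size=n_hours, p=weights / weights.sum()
    )
    timestamps = pd.date_range(pd.Timestamp(start_time), periods=n_hours, freq="h")
    return MeteoSeries(
        pd.DataFrame(
            {
                "timestamp": timestamps,
                "wind_speed": speeds,
                "wind_direction": directions,
                "stability_class": classes,
            }
        )
    )


def read_meteo_csv(path) -> MeteoSeries:
    """Read and validate an hourly meteorology CSV.

    Expected header: ``timestamp,wind_speed,wind_direction,stability_class``
    with ISO-8601 timestamps, one row per hour, no gaps.
    """
    df = pd.read_csv(path)
    missing = [c for c in METEO_COLUMNS if c not in df.columns]
    if missing:
        raise MeteoParseError(f"{path}: missing column(s): {', '.join(missing)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as exc:
        raise MeteoParseError(f"{path}: unparseable timestamp ({exc})") from exc
    dup = df["timestamp"].duplicated()
    if dup.any():
        t = df["timestamp"][dup].iloc[0]
        raise MeteoParseError(f"{path}: duplicated hour {t}")
    try:
        return MeteoSeries(df)
    except MeteoParseError as exc:
        raise MeteoParseError(f"{path}: {exc}") from exc


def write_meteo_csv(series: MeteoSeries, path) -> None:
    out = series.df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False)


def wind_rose(series: MeteoSeries, n_sectors: int = 16) -> pd.DataFrame:
    """Bin wind directions into equal sectors.

    Sector ``k`` is centred on ``k * 360 / n_sectors`` and spans half a
    sector width either side (wrapped), so sector 0 of a 16-sector rose
    covers [348.75, 11.25).  Frequencies sum to one.
    """
    if n_sectors < 4:
        raise ValueError("n_sectors must be at least 4")
    if len(series) == 0:
        raise ValueError("empty meteorology series")
    width = 360.0 / n_sectors
    d = np.asarray(series.df["wind_direction"], dtype=float)
    k = np.floor(d / width + 0.5).astype(int) % n_sectors
    counts = np.bincount(k, minlength=n_sectors)
    return pd.DataFrame(
        {
            "sector_centre_deg": np.arange(n_sectors) * width,
            "count": counts,
            "frequency": counts / counts.sum(),
        }
    )
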