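"""Soil-ingestion dose and excess cancer risk.

For each grid cell and age group the lifetime average daily dose from
incidental soil ingestion, accumulated from the accident to the
extinction endpoint, is

    LADD (mg/kg/d) = IR_soil * sum_{n=1..C_LT} C_soil(n) / (BW * LT)

with ``IR_soil`` the soil intake rate (kg/d), ``C_soil(n)`` the soil
concentration ``n`` days after the accident (mg/kg), ``C_LT`` the
endpoint day, ``BW`` the body weight (kg) and ``LT`` the lifetime in
days.  Excess cancer risk is ``ECR = LADD * CSF`` and cells are
classified into red (>= 1e-6), orange ([1e-7, 1e-6)) and green
(< 1e-7) zones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .endpoint import EndpointResult
from .fate import ConcentrationHistory

__all__ = [
    "ExposureFactors",
    "ZoneThresholds",
    "RiskSummary",
    "RiskMap",
    "DEFAULT_FACTORS",
    "load_factors_csv",
    "compute_ladd",
    "compute_ecr",
    "classify_zone",
    "classify_zones",
    "assess",
    "summary_table",
]

#: Raster codes for the risk zones.
ZONE_RED, ZONE_ORANGE, ZONE_GREEN = 2, 1, 0
ZONE_LABELS = {ZONE_RED: "red", ZONE_ORANGE: "orange", ZONE_GREEN: "green"}


@dataclass(frozen=True)
class ExposureFactors:
    """Age-group exposure parameters.

    ``soil_intake`` is stored in kg/d (tables usually print mg/d).
    """

    group_label: str
    soil_intake: float       # kg/d
    body_weight: float       # kg
    lifetime_days: float

    def __post_init__(self) -> None:
        if min(self.soil_intake, self.body_weight, self.lifetime_days) <= 0:
            raise ValueError("exposure factors must all be positive")


#: Korean exposure-factor handbook values used by the packaged example:
#: soil intake 80 mg/d for ages 0-18, 40 mg/d for adults; life expectancy
#: 30,186 days shared by all groups.
DEFAULT_FACTORS: tuple[ExposureFactors, ...] = (
    ExposureFactors("0-9", 80 * 1e-6, 13.3, 30186.0),
    ExposureFactors("10-18", 80 * 1e-6, 53.6, 30186.0),
    ExposureFactors("19-65", 40 * 1e-6, 63.3, 30186.0),
    ExposureFactors(">65", 40 * 1e-6, 60.7, 30186.0),
)


def load_factors_csv(path) -> tuple[ExposureFactors, ...]:
    """Read an exposure-factor table.

    Columns: ``group,soil_intake_mg_per_day,body_weight_kg,lifetime_days``.
    """
    df = pd.read_csv(path)
    required = {"group", "soil_intake_mg_per_day", "body_weight_kg", "lifetime_days"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    return tuple(
        ExposureFactors(
            group_label=str(row["group"]),
            soil_intake=float(row["soil_intake_mg_per_day"]) * 1e-6,
            body_weight=float(row["body_weight_kg"]),
            lifetime_days=float(row["lifetime_days"]),
        )
        for _, row in df.iterrows()
    )


@dataclass(frozen=True)
class ZoneThresholds:
    """ECR cut points; red at or above ``red``, orange at or above ``orange``."""

    red: float = 1e-6
    orange: float = 1e-7

    def __post_init__(self) -> None:
        if not (self.red > self.orange > 0):
            raise ValueError("thresholds must satisfy red > orange > 0")


@dataclass(frozen=True)
class RiskSummary:
    """Whole-domain summary for one age group.

    Percentages partition 100 exactly: green is defined as the
    complement of red and orange.
    """

    max_ecr: float
    mean_ecr: float
    pct_red: float
    pct_orange: float
    pct_green: float


@dataclass
class RiskMap:
    """Per-cell dose and risk for one age group."""

    group: ExposureFactors
    ladd: np.ndarray          # mg/kg/d
    ecr: np.ndarray           # dimensionless
    zones: np.ndarray         # int8 codes, see ZONE_LABELS
    summary: RiskSummary


def compute_ladd(
    soil_daily_series: np.ndarray, endpoint_day: int, factors: ExposureFactors
) -> float:
    """Lifetime average daily dose for one cell's daily soil series.

    Only days 1..``endpoint_day`` contribute; anything after the
    extinction endpoint is ignored.
    """
    series = np.asarray(soil_daily_series, dtype=float)
    if endpoint_day < 1 or endpoint_day > series.shape[0]:
        raise ValueError(
            f"endpoint_day {endpoint_day} outside series of length {series.shape[0]}"
        )
    cumulative = series[:endpoint_day].sum()
    return float(
        factors.soil_intake * cumulative / (factors.body_weight * factors.lifetime_days)
    )


def compute_ecr(ladd, csf: float):
    """Excess cancer risk: LADD times the cancer slope factor."""
    ladd = np.asarray(ladd, dtype=float)
    if (ladd < 0).any() or csf < 0:
        raise ValueError("ladd and csf must be non-negative")
    out = ladd * csf
    return float(out) if out.ndim == 0 else out


def classify_zone(ecr: float, thresholds: ZoneThresholds = ZoneThresholds()) -> str:
    """Zone label for a single ECR value."""
    if ecr < 0:
        raise ValueError("ecr must be non-negative")
    if ecr >= thresholds.red:
        return "red"
    if ecr >= thresholds.orange:
        return "orange"
    return "green"


def classify_zones(
    ecr: np.ndarray, thresholds: ZoneThresholds = ZoneThresholds()
) -> np.ndarray:
    """Vectorised zone coding (2 = red, 1 = orange, 0 = green)."""
    ecr = np.asarray(ecr, dtype=float)
    if (ecr < 0).any():
        raise ValueError("ecr must be non-negative")
    zones = np.zeros(ecr.shape, dtype=np.int8)
    zones[ecr >= thresholds.orange] = ZONE_ORANGE
    zones[ecr >= thresholds.red] = ZONE_RED
    return zones


def _summarise(ecr: np.ndarray, zones: np.ndarray) -> RiskSummary:
    n = zones.size
    pct_red = 100.0 * int((zones == ZONE_RED).sum()) / n
    pct_orange = 100.0 * int((zones == ZONE_ORANGE).sum()) / n
    # green as the complement of (red + orange) keeps the three-way sum
    # at exactly 100.0 in floating point
    return RiskSummary(
        max_ecr=float(ecr.max()),
        mean_ecr=float(ecr.mean()),
        pct_red=pct_red,
        pct_orange=pct_orange,
        pct_green=100.0 - (pct_red + pct_orange),
    )


def assess(
    history: ConcentrationHistory,
    endpoint_result: EndpointResult,
    factors_table: Sequence[ExposureFactors] = DEFAULT_FACTORS,
    csf: float = 0.17,
    thresholds: ZoneThresholds = ZoneThresholds(),
) -> list[RiskMap]:
    """Cell-wise LADD, ECR, zones and summary for every age group.

    Because LADD is linear in ``IR/BW`` with a shared lifetime, the ECR
    fields of any two groups differ by the exact scalar
    ``(IR_a/BW_a) / (IR_b/BW_b)``; maxima and means inherit the same
    ratio.  Summaries are taken over all grid cells.
    """
    if len(factors_table) == 0:
        raise ValueError("factors_table is empty")
    day = endpoint_result.endpoint_day
    if day > history.n_days:
        raise ValueError("endpoint_day exceeds the simulated horizon")
    cumulative_soil = history.soil_daily[:day].sum(axis=0)   # mg/kg * days
    maps = []
    for fac in factors_table:
        ladd = fac.soil_intake * cumulative_soil / (fac.body_weight * fac.lifetime_days)
        ecr = compute_ecr(ladd, csf)
        zones = classify_zones(ecr, thresholds)
        maps.append(
            RiskMap(group=fac, ladd=ladd, ecr=ecr, zones=zones,
                    summary=_summarise(ecr, zones))
        )
    return maps


def _round_half_up(x: float, decimals: int = 2) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summary_table(maps: Sequence[RiskMap]) -> pd.DataFrame:
    """Report-ready table: one row per group, percentages to 2 decimals."""
    rows = []
    for m in maps:
        s = m.summary
        rows.append(
            {
                "group": m.group.group_label,
                "max_ecr": s.max_ecr,
                "mean_ecr": s.mean_ecr,
                "pct_red": _round_half_up(s.pct_red),
                "pct_orange": _round_half_up(s.pct_orange),
                "pct_green": _round_half_up(s.pct_green),
            }
        )
    return pd.DataFrame(rows)
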