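"""Exposure-endpoint determination.

The chronic dose is accumulated only while the accident still matters:
from the release until the *extinction endpoint*, the day after which
the air concentration never again exceeds the chemical's atmospheric
background anywhere in the domain.  Because deposition and
re-volatilization can make the air series rebound (a dip below
background followed by a later exceedance), the endpoint is defined as
the LAST day with an exceedance, not the first crossing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fate import ConcentrationHistory

__all__ = [
    "MOLAR_VOLUME_25C_L",
    "HorizonTooShortError",
    "EndpointResult",
    "ppb_to_mg_m3",
    "determine_endpoint",
]

#: Molar volume of an ideal gas at 25 degC and 1 atm, litres per mole.
MOLAR_VOLUME_25C_L = 24.45


class HorizonTooShortError(RuntimeError):
    """The final simulated day still exceeds background: endpoint not reached."""


@dataclass(frozen=True)
class EndpointResult:
    """Outcome of the endpoint scan.

    ``endpoint_day`` is 1-based (day 1 = accident day) and equals the
    last day on which any cell exceeded ``background_mg_m3``, or 1 if no
    day ever did.  ``exceedance_profile[d]`` flags whether day ``d+1``
    had an exceedance anywhere.
    """

    endpoint_day: int
    background_mg_m3: float
    exceedance_profile: np.ndarray


def ppb_to_mg_m3(
    ppb: float, molecular_weight: float, molar_volume_l: float = MOLAR_VOLUME_25C_L
) -> float:
    """Convert a gas-phase mixing ratio (ppb) to mg/m3.

    ``mg/m3 = ppb * MW / V_m / 1000`` with ``V_m`` in L/mol (24.45 at
    25 degC, 1 atm).
    """
    if ppb < 0:
        raise ValueError("ppb must be non-negative")
    if molecular_weight <= 0:
        raise ValueError("molecular_weight must be positive")
    if molar_volume_l <= 0:
        raise ValueError("molar_volume_l must be positive")
    return ppb * molecular_weight / molar_volume_l / 1000.0


def determine_endpoint(
    history: ConcentrationHistory, background_mg_m3: float
) -> EndpointResult:
    """Find the extinction endpoint of a simulated accident.

    A day exceeds when any cell's daily-average air concentration is
    strictly above ``background_mg_m3`` (a level exactly at background
    counts as extinct).  Raises :class:`HorizonTooShortError` if the
    final simulated day still exceeds, since the accumulation window
    would otherwise be silently truncated.
    """
    if background_mg_m3 <= 0:
        raise ValueError("background_mg_m3 must be positive")
    if history.n_days == 0:
        raise ValueError("history is empty")
    profile = (history.air_daily > background_mg_m3).any(axis=(1, 2))
    if profile[-1]:
        raise HorizonTooShortError(
            f"day {history.n_days} still exceeds background "
            f"{background_mg_m3:g} mg/m3; extend the simulation horizon"
        )
    exceeding = np.flatnonzero(profile)
    endpoint_day = int(exceeding[-1]) + 1 if exceeding.size else 1
    return EndpointResult(
        endpoint_day=endpoint_day,
        background_mg_m3=background_mg_m3,
        exceedance_profile=profile,
    )
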