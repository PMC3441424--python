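"""Closed-form lactate-contribution analysis under fixed glycolysis.

At steady state the oxidative flux is fed by two pyruvate sources,
``J_PDH = J_MCT + J_glyco``.  Write ``r = J_MCT,0 / J_glyco,0`` for the basal
supply ratio.  If glycolysis stays fixed and transport rises by a fraction
``gamma``, flux balance alone fixes the fractional rise ``alpha`` of the
oxidative flux:

    alpha = gamma * r / (1 + r)

independent of any kinetic detail.  This module evaluates the formula, its
inverse (the transport increase needed to sustain a target oxidative
increase), and regenerates the full (r, gamma) reference grid with the
published banding (below 10%, 10–29%, 29% and above).
"""

from __future__ import annotations

import math
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Band",
    "alpha_increase",
    "gamma_required",
    "round_as_printed",
    "assign_band",
    "generate_table1",
    "R_GRID",
    "GAMMA_GRID",
]

R_GRID = tuple(np.round(np.arange(0.1, 3.41, 0.3), 10))      # 0.1 .. 3.4
GAMMA_GRID = tuple(np.round(np.arange(0.1, 0.81, 0.1), 10))  # 0.1 .. 0.8


class Band(str, Enum):
    """Published banding of the oxidative-flux increase."""

    BELOW_10 = "below_10"
    MID_10_29 = "mid_10_29"
    ABOVE_29 = "above_29"


def alpha_increase(r: float, gamma: float) -> float:
    """Fractional increase in oxidative flux for a transport increase gamma.

    ``alpha = gamma * r / (1 + r)`` with ``r`` the basal ratio of lactate- to
    glycolysis-derived pyruvate supply.
    """
    if not r > 0:
        raise ValueError(f"r must be > 0, got {r!r}")
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma!r}")
    return gamma * r / (1.0 + r)


def gamma_required(r: float, alpha: float) -> float:
    """Transport increase needed to sustain an oxidative increase alpha.

    Exact inverse of :func:`alpha_increase`: ``gamma = alpha * (1 + r) / r``.
    """
    if not r > 0:
        raise ValueError(f"r must be > 0, got {r!r}")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha!r}")
    return alpha * (1.0 + r) / r


def round_as_printed(alpha: float) -> float:
    """Round alpha the way the reference table prints it.

    Two significant figures below 0.10 (0.0091, 0.073, ...), two decimals at
    and above (0.11, 0.30, ...).
    """
    if alpha == 0:
        return 0.0
    if alpha < 0.0995:
        exponent = math.floor(math.log10(abs(alpha)))
        return round(alpha, -exponent + 1)
    return round(alpha, 2)


def assign_band(alpha_rounded: float) -> Band:
    """Band from the *rounded* value, so 0.29 is mid and 0.30 is above."""
    if alpha_rounded < 0.10:
        return Band.BELOW_10
    if alpha_rounded < 0.295:  # rounded values are on a 0.01 grid here
        return Band.MID_10_29
    return Band.ABOVE_29


def generate_table1() -> pd.DataFrame:
    """Regenerate the (r, gamma) contribution grid with banding.

    Returns a long-format DataFrame with 96 rows (12 supply ratios x 8
    transport increases) and columns ``r, gamma, alpha, band`` where ``alpha``
    carries the printed rounding.
    """
    rows = []
    for r in R_GRID:
        for gamma in GAMMA_GRID:
            alpha = round_as_printed(alpha_increase(r, gamma))
            rows.append(
                {"r": r, "gamma": gamma, "alpha": alpha,
                 "band": assign_band(alpha).value}
            )
    return pd.DataFrame(rows)
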