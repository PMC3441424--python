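"""2-D parameter sweeps with constraint masking and phenotype classification.

A scan solves the steady state on a rectangular grid over two parameter (or
environment) axes, optionally expressed as multiples of a reference set,
records fluxes and derived ratios at every node, masks nodes violating the
physiological constraint windows, and classifies each node's metabolic
phenotype from the sign of the steady-state lactate transport flux:

* net import  (``J_MCT > eps``)  -> oxidative phenotype,
* net export  (``J_MCT < -eps``) -> glycolytic phenotype,
* within the dead band            -> balanced.

Iso-curves (contours of constant flux across the plane) are extracted with
marching squares.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage import measure

from .model import DEFAULT_OPTIONS, Environment, KineticParameters, ModelOptions
from .scenarios import Scenario, apply_scenario
from .steady_state import (
    ConstraintSet,
    ConvergenceError,
    SteadyStateResult,
    check_constraints,
    solve_steady_state,
)

__all__ = [
    "GridSpec",
    "ScanResult",
    "PhenotypeLabel",
    "ScanError",
    "scan_2d",
    "classify_phenotype",
    "extract_isocurves",
]

BALANCED_EPS = 1e-6  # mM/s dead band around zero transport flux


class ScanError(RuntimeError):
    pass


class PhenotypeLabel(str, Enum):
    IMPORTER_OXIDATIVE = "importer_oxidative"
    EXPORTER_GLYCOLYTIC = "exporter_glycolytic"
    BALANCED = "balanced"


@dataclass(frozen=True)
class GridSpec:
    """Two scan axes: (field name, strictly increasing values).

    With ``normalized=True`` the axis values are multiplicative factors
    applied to the reference parameter set (the published sweeps express
    both axes as multiples of the oxidative reference).
    """

    axis1: Tuple[str, Sequence[float]]
    axis2: Tuple[str, Sequence[float]]
    normalized: bool = True

    def __post_init__(self) -> None:
        if len(self.axis1[1]) * len(self.axis2[1]) < 2:
            raise ValueError("grid needs at least 2 nodes")
        for name, values in (self.axis1, self.axis2):
            arr = np.asarray(values, dtype=float)
            if arr.size < 1 or np.any(np.diff(arr) <= 0):
                raise ValueError(
                    f"axis {name!r}: need strictly increasing values"
                )

    @staticmethod
    def uniform(field1: str, field2: str, lo: float = 0.05, hi: float = 2.0,
                n: int = 20) -> "GridSpec":
        vals = np.linspace(lo, hi, n)
        return GridSpec(axis1=(field1, vals), axis2=(field2, vals))


@dataclass(frozen=True)
class ScanResult:
    grid: GridSpec
    J_MCT: np.ndarray
    J_PDH: np.ndarray
    r: np.ndarray
    lp_ratio: np.ndarray
    redox: np.ndarray
    constraint_mask: np.ndarray  # True = physiological
    phenotype: np.ndarray        # dtype=object, PhenotypeLabel values
    unconverged: np.ndarray      # True where no steady state was found

    _QUANTITIES = ("J_MCT", "J_PDH", "r", "lp_ratio", "redox")

    def matrix(self, quantity: str) -> np.ndarray:
        if quantity not in self._QUANTITIES:
            raise KeyError(f"unknown scan quantity {quantity!r}")
        return getattr(self, quantity)

    def to_frame(self):
        """Long-format table: one row per grid node."""
        import pandas as pd

        a1_name, a1 = self.grid.axis1
        a2_name, a2 = self.grid.axis2
        rows = []
        for i, v1 in enumerate(a1):
            for j, v2 in enumerate(a2):
                rows.append({
                    a1_name: v1, a2_name: v2,
                    "J_MCT": self.J_MCT[i, j], "J_PDH": self.J_PDH[i, j],
                    "r": self.r[i, j], "lp_ratio": self.lp_ratio[i, j],
                    "redox": self.redox[i, j],
                    "mask": bool(self.constraint_mask[i, j]),
                    "phenotype": self.phenotype[i, j].value
                    if self.phenotype[i, j] is not None else "unconverged",
                })
        return pd.DataFrame(rows)


def classify_phenotype(
    result: SteadyStateResult, eps: float = BALANCED_EPS
) -> PhenotypeLabel:
    """Phenotype from the sign of the steady-state transport flux."""
    if not result.converged:
        raise ValueError("phenotype classification requires a converged result")
    if result.fluxes.J_MCT > eps:
        return PhenotypeLabel.IMPORTER_OXIDATIVE
    if result.fluxes.J_MCT < -eps:
        return PhenotypeLabel.EXPORTER_GLYCOLYTIC
    return PhenotypeLabel.BALANCED


def scan_2d(
    params: KineticParameters,
    env: Environment,
    options: ModelOptions = DEFAULT_OPTIONS,
    grid: Optional[GridSpec] = None,
    constraints: Optional[ConstraintSet] = None,
    eps: float = BALANCED_EPS,
    max_unconverged_frac: float = 0.10,
) -> ScanResult:
    """Solve the steady state over a 2-D grid, warm-starting from neighbours.

    Raises :class:`ScanError` when more than ``max_unconverged_frac`` of the
    nodes fail to converge.
    """
    if grid is None:
        grid = GridSpec.uniform("k_shuttle", "v_max_PDH")
    a1_name, a1 = grid.axis1
    a2_name, a2 = grid.axis2
    n1, n2 = len(a1), len(a2)

    shape = (n1, n2)
    mats = {q: np.full(shape, np.nan) for q in ScanResult._QUANTITIES}
    mask = np.zeros(shape, dtype=bool)
    unconv = np.zeros(shape, dtype=bool)
    phen = np.empty(shape, dtype=object)

    warm_rows: List[Optional[object]] = [None] * n2
    for i, v1 in enumerate(a1):
        warm = None
        for j, v2 in enumerate(a2):
            if grid.normalized:
                sc = Scenario(name="scan_node",
                              multipliers={a1_name: float(v1), a2_name: float(v2)})
                p_ij, e_ij = apply_scenario(params, env, sc)
            else:
                p_kw = {k: v for k, v in ((a1_name, v1), (a2_name, v2))
                        if hasattr(params, k)}
                e_kw = {k: v for k, v in ((a1_name, v1), (a2_name, v2))
                        if k in ("L_e", "Glc", "H_i", "H_e")}
                p_ij = dataclasses.replace(params, **p_kw) if p_kw else params
                e_ij = dataclasses.replace(env, **e_kw) if e_kw else env
            guess = warm or warm_rows[j]
            try:
                res = solve_steady_state(p_ij, e_ij, options, initial_guess=guess)
            except ConvergenceError:
                unconv[i, j] = True
                phen[i, j] = None
                continue
            warm = res.state
            warm_rows[j] = res.state
            for q in ScanResult._QUANTITIES:
                mats[q][i, j] = getattr(res, q) if q not in ("J_MCT", "J_PDH") \
                    else getattr(res.fluxes, q)
            phen[i, j] = classify_phenotype(res, eps)
            if constraints is not None:
                mask[i, j] = check_constraints(res, constraints).passed
            else:
                mask[i, j] = True

    frac_bad = unconv.mean()
    if frac_bad > max_unconverged_frac:
        raise ScanError(
            f"{frac_bad:.0%} of grid nodes failed to converge "
            f"({int(unconv.sum())}/{unconv.size})"
        )
    return ScanResult(
        grid=grid, constraint_mask=mask, phenotype=phen, unconverged=unconv,
        **mats,
    )


def extract_isocurves(
    scan: ScanResult, quantity: str, levels: Sequence[float]
) -> Dict[float, List[np.ndarray]]:
    """Marching-squares contour polylines in grid (axis-value) coordinates.

    Returns ``{level: [polyline, ...]}`` where each polyline is an (n, 2)
    array of (axis1 value, axis2 value) vertices; levels outside the data
    range yield empty lists.
    """
    z = scan.matrix(quantity)
    a1 = np.asarray(scan.grid.axis1[1], dtype=float)
    a2 = np.asarray(scan.grid.axis2[1], dtype=float)
    out: Dict[float, List[np.ndarray]] = {}
    for level in levels:
        polylines = []
        finite = np.isfinite(z)
        if (min(z.shape) >= 2 and finite.any()
                and np.nanmin(z) <= level <= np.nanmax(z)):
            for contour in measure.find_contours(z, level):
                # fractional indices -> axis coordinates
                xs = np.interp(contour[:, 0], np.arange(len(a1)), a1)
                ys = np.interp(contour[:, 1], np.arange(len(a2)), a2)
                polylines.append(np.column_stack([xs, ys]))
        out[float(level)] = polylines
    return out
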