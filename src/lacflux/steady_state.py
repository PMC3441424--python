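"""Steady-state solution, physiological constraint checking, derived ratios.

The steady state is the root of the three balance equations.  We solve the
reduced 3-dimensional system (NAD+ eliminated by pool conservation) with a
quasi-Newton root finder on transformed variables that keep the iterate
inside the physical box ``L_i > 0, P > 0, 0 < NADH < N_tot``; if the root
finder does not converge, we fall back to stiff time integration to
``t = 1e5 s`` and re-polish.  A converged result has ``max |rhs| < 1e-10``
mM/s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.special import expit, logit

from .model import (
    CellState,
    DEFAULT_OPTIONS,
    Environment,
    FluxVector,
    InvalidStateError,
    KineticParameters,
    ModelOptions,
    compute_fluxes,
    rhs_array,
)

__all__ = [
    "SteadyStateResult",
    "ConstraintSet",
    "ConstraintReport",
    "ConvergenceError",
    "solve_steady_state",
    "find_steady_states",
    "check_constraints",
    "pyruvate_source_ratio",
]

RESIDUAL_TOL = 1e-10  # mM/s


class ConvergenceError(RuntimeError):
    """No steady state found; carries the best iterate seen."""

    def __init__(self, message: str, best: Optional["SteadyStateResult"] = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class SteadyStateResult:
    state: CellState
    fluxes: FluxVector
    r: float                 # J_MCT / J_glyco, lactate- vs glycolysis-derived pyruvate
    lp_ratio: float          # L_i / P
    redox: float             # NADH / NAD+
    residual: float          # max |rhs|, mM/s
    converged: bool
    n_iterations: int
    multistable: bool = False

    def summary_row(self) -> dict:
        row = {"L_i": self.state.L_i, "P": self.state.P, "NADH": self.state.NADH}
        row.update(self.fluxes.as_dict())
        row.update(
            r=self.r, lp_ratio=self.lp_ratio, redox=self.redox,
            residual=self.residual, converged=self.converged,
        )
        return row


@dataclass(frozen=True)
class ConstraintSet:
    """Physiological windows on the basal steady state.

    The bundled reference config carries the default windows (intracellular
    lactate, lactate/pyruvate ratio, cytosolic redox state); they are data,
    not code.
    """

    L_i_range: Tuple[float, float]
    lp_ratio_range: Tuple[float, float]
    redox_range: Tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("L_i_range", "lp_ratio_range", "redox_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: need min < max, got ({lo}, {hi})")


@dataclass(frozen=True)
class ConstraintReport:
    passed: bool
    violations: Tuple[Tuple[str, float, Tuple[float, float]], ...] = ()


def _pack(y: np.ndarray, n_tot: float) -> np.ndarray:
    """Physical state -> unconstrained solver variables."""
    eps = 1e-300
    frac = np.clip(y[2] / n_tot, 1e-12, 1 - 1e-12)
    return np.array([np.log(y[0] + eps), np.log(y[1] + eps), logit(frac)])


def _unpack(z: np.ndarray, n_tot: float) -> np.ndarray:
    return np.array([np.exp(z[0]), np.exp(z[1]), n_tot * expit(z[2])])


def _default_guess(params: KineticParameters) -> np.ndarray:
    # mid-range physiological state: ~1 mM lactate, L/P ~ 12, redox ~ 1%
    return np.array([0.9, 0.075, 0.01 * params.N_tot])


def _result_from_y(
    y: np.ndarray,
    params: KineticParameters,
    env: Environment,
    options: ModelOptions,
    n_iter: int,
) -> SteadyStateResult:
    state = CellState(L_i=max(float(y[0]), 0.0), P=max(float(y[1]), 0.0),
                      NADH=float(np.clip(y[2], 0.0, params.N_tot)))
    fluxes = compute_fluxes(state, params, env, options)
    residual = float(np.max(np.abs(rhs_array(state.as_array(), params, env, options))))
    nad = params.N_tot - state.NADH
    return SteadyStateResult(
        state=state,
        fluxes=fluxes,
        r=fluxes.J_MCT / fluxes.J_glyco if fluxes.J_glyco > 0 else np.nan,
        lp_ratio=state.L_i / state.P if state.P > 0 else np.inf,
        redox=state.NADH / nad if nad > 0 else np.inf,
        residual=residual,
        converged=residual < RESIDUAL_TOL,
        n_iterations=n_iter,
    )


def solve_steady_state(
    params: KineticParameters,
    env: Environment,
    options: ModelOptions = DEFAULT_OPTIONS,
    initial_guess: Optional[CellState] = None,
    multistart: bool = False,
) -> SteadyStateResult:
    """Solve for the steady state of the three balance equations.

    Parameters
    ----------
    initial_guess
        Starting state; defaults to a mid-range physiological state.
    multistart
        If true, also solve from a spread of initial guesses and flag the
        result as ``multistable`` when distinct steady states are found.

    Raises
    ------
    ConvergenceError
        If neither root finding nor relaxation by stiff integration reaches
        ``max |rhs| < 1e-10`` mM/s.  The best iterate is attached.
    """
    y0 = initial_guess.as_array() if initial_guess is not None else _default_guess(params)

    def fun(z: np.ndarray) -> np.ndarray:
        return rhs_array(_unpack(z, params.N_tot), params, env, options)

    sol = root(fun, _pack(y0, params.N_tot), method="hybr", tol=1e-14)
    n_iter = int(sol.nfev)
    y = _unpack(sol.x, params.N_tot)
    result = _result_from_y(y, params, env, options, n_iter)

    if not result.converged:
        # relax towards the attractor by stiff integration, then re-polish
        ivp = solve_ivp(
            lambda _t, yy: rhs_array(np.clip(yy, 0.0, None), params, env, options),
            (0.0, 1e5), y0, method="LSODA", rtol=1e-10, atol=1e-12,
        )
        if ivp.success:
            y_relaxed = np.clip(ivp.y[:, -1], 1e-12, None)
            y_relaxed[2] = min(y_relaxed[2], params.N_tot * (1 - 1e-12))
            sol2 = root(fun, _pack(y_relaxed, params.N_tot), method="hybr", tol=1e-14)
            n_iter += int(sol2.nfev)
            result = _result_from_y(
                _unpack(sol2.x, params.N_tot), params, env, options, n_iter
            )
            if not result.converged:
                relaxed = _result_from_y(y_relaxed, params, env, options, n_iter)
                if relaxed.residual < result.residual:
                    result = relaxed
        if not result.converged:
            raise ConvergenceError(
                f"no steady state found (best residual {result.residual:.3g} mM/s)",
                best=result,
            )

    if multistart:
        states = find_steady_states(params, env, options)
        if len(states) > 1:
            result = dataclasses.replace(result, multistable=True)
    return result


def find_steady_states(
    params: KineticParameters,
    env: Environment,
    options: ModelOptions = DEFAULT_OPTIONS,
    n_starts: int = 5,
) -> List[SteadyStateResult]:
    """Root-find from spread initial guesses; return distinct converged roots."""
    guesses = [
        np.array([li, p, f * params.N_tot])
        for li, p, f in (
            (0.9, 0.075, 0.01),
            (0.05, 0.005, 0.001),
            (3.0, 0.5, 0.2),
            (0.3, 0.2, 0.05),
            (1.5, 0.01, 0.005),
        )[:n_starts]
    ]
    found: List[SteadyStateResult] = []
    for g in guesses:
        try:
            res = solve_steady_state(
                params, env, options,
                initial_guess=CellState(*np.clip(g, 1e-9, None)),
            )
        except (ConvergenceError, InvalidStateError):
            continue
        if not any(
            np.allclose(res.state.as_array(), other.state.as_array(),
                        rtol=1e-6, atol=1e-9)
            for other in found
        ):
            found.append(res)
    return found


def check_constraints(
    result: SteadyStateResult, constraints: ConstraintSet
) -> ConstraintReport:
    """Check a converged steady state against the physiological windows."""
    if not result.converged:
        raise InvalidStateError("constraint check requires a converged steady state")
    violations = []
    for name, value, bounds in (
        ("L_i", result.state.L_i, constraints.L_i_range),
        ("lp_ratio", result.lp_ratio, constraints.lp_ratio_range),
        ("redox", result.redox, constraints.redox_range),
    ):
        lo, hi = bounds
        if not (lo <= value <= hi):
            violations.append((name, float(value), (lo, hi)))
    return ConstraintReport(passed=not violations, violations=tuple(violations))


def pyruvate_source_ratio(result: SteadyStateResult) -> float:
    """r = J_MCT / J_glyco: lactate- vs glycolysis-derived pyruvate supply.

    Negative for lactate exporters.  Undefined when glycolysis carries no
    flux.
    """
    if result.fluxes.J_glyco <= 0:
        raise ZeroDivisionError("r undefined: glycolytic flux is zero")
    return result.fluxes.J_MCT / result.fluxes.J_glyco
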