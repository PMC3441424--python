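"""Synthetic observations, parameter sampling, recovery, integration oracle.

This module makes the whole analysis testable without any external data:

* :func:`sample_parameters` draws kinetic parameter sets uniformly inside
  stated ranges and keeps only those whose steady state passes the
  physiological constraint windows (rejection sampling).
* :func:`simulate_observations` produces noisy pseudo-measurements of
  steady-state fluxes and concentrations under a list of stimulation
  scenarios, with multiplicative Gaussian noise (positive quantities carry
  scale-proportional error; draws are truncated so a positive truth stays
  positive).
* :func:`recover_parameters` fits free kinetic parameters back to such
  observations by bounded, inverse-variance-weighted least squares.
* :func:`integration_oracle` integrates the full ODE system to late time —
  an independent brute-force route to the steady state used to validate the
  Newton solver.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .model import (
    CellState,
    DEFAULT_OPTIONS,
    Environment,
    KineticParameters,
    ModelOptions,
    rhs_array,
)
from .scenarios import Scenario, apply_scenario, run_scenario
from .steady_state import (
    ConstraintSet,
    ConvergenceError,
    check_constraints,
    solve_steady_state,
)

__all__ = [
    "ParameterRanges",
    "RecoveryResult",
    "InfeasibleRangesError",
    "sample_parameters",
    "simulate_observations",
    "recover_parameters",
    "integration_oracle",
]

OBSERVABLES = ("J_MCT", "J_PDH", "L_i", "P")


class InfeasibleRangesError(RuntimeError):
    pass


@dataclass(frozen=True)
class ParameterRanges:
    """Per-parameter uniform sampling bounds around a reference set."""

    bounds: Mapping[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if name not in KineticParameters._FIELDS:
                raise ValueError(f"unknown parameter {name!r}")
            if not lo < hi:
                raise ValueError(f"{name}: need min < max, got ({lo}, {hi})")

    @staticmethod
    def around(params: KineticParameters, rel_width: float = 0.3,
               names: Optional[Sequence[str]] = None) -> "ParameterRanges":
        """Symmetric multiplicative bounds around a reference set."""
        names = names or KineticParameters._FIELDS
        return ParameterRanges({
            n: (getattr(params, n) * (1 - rel_width),
                getattr(params, n) * (1 + rel_width))
            for n in names
        })


@dataclass(frozen=True)
class RecoveryResult:
    estimates: Dict[str, float]
    truth: Optional[Dict[str, float]]
    relative_errors: Optional[Dict[str, float]]
    loss: float
    converged: bool
    identifiable: bool
    message: str = ""


def sample_parameters(
    ranges: ParameterRanges,
    constraints: ConstraintSet,
    n: int,
    seed: int,
    reference: KineticParameters,
    env: Environment,
    options: ModelOptions = DEFAULT_OPTIONS,
    max_draws: int = 100_000,
) -> List[KineticParameters]:
    """Rejection-sample parameter sets whose steady state is physiological.

    Fields without bounds stay at the reference value.  Reproducible under a
    fixed seed.  Raises :class:`InfeasibleRangesError` when the acceptance
    rate over ``max_draws`` draws falls below 0.1%.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(ranges.bounds)
    accepted: List[KineticParameters] = []
    draws = 0
    while len(accepted) < n:
        if draws >= max_draws:
            rate = len(accepted) / draws
            if rate < 1e-3:
                raise InfeasibleRangesError(
                    f"acceptance rate {rate:.2e} below 0.1% after {draws} draws"
                )
        draws += 1
        values = {
            name: float(rng.uniform(*ranges.bounds[name])) for name in names
        }
        candidate = dataclasses.replace(reference, **values)
        try:
            result = solve_steady_state(candidate, env, options)
        except ConvergenceError:
            continue
        if check_constraints(result, constraints).passed:
            accepted.append(candidate)
    return accepted


def simulate_observations(
    params: KineticParameters,
    env: Environment,
    options: ModelOptions = DEFAULT_OPTIONS,
    scenarios: Sequence[Scenario] = (),
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy pseudo-observations of stimulated steady states.

    One row per scenario with observed ``J_MCT, J_PDH, L_i, P``:
    ``observed = truth * (1 + N(0, noise_cv))``, redrawn (truncated) so that
    positive truths stay positive.  ``noise_cv = 0`` reproduces the truth
    exactly; a fixed seed gives identical noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for idx, scenario in enumerate(scenarios):
        res = run_scenario(params, env, options, scenario)
        truth = {
            "J_MCT": res.stimulated.fluxes.J_MCT,
            "J_PDH": res.stimulated.fluxes.J_PDH,
            "L_i": res.stimulated.state.L_i,
            "P": res.stimulated.state.P,
        }
        row = {"condition": idx, "scenario": scenario.name, "noise_cv": noise_cv}
        for name, value in truth.items():
            if noise_cv == 0:
                row[name] = value
            else:
                factor = 1.0 + noise_cv * rng.standard_normal()
                while value > 0 and factor <= 0:
                    factor = 1.0 + noise_cv * rng.standard_normal()
                row[name] = value * factor
        rows.append(row)
    return pd.DataFrame(rows)


def _predict(
    params: KineticParameters,
    env: Environment,
    options: ModelOptions,
    scenarios: Sequence[Scenario],
) -> np.ndarray:
    preds = []
    for scenario in scenarios:
        res = run_scenario(params, env, options, scenario)
        preds.extend([
            res.stimulated.fluxes.J_MCT,
            res.stimulated.fluxes.J_PDH,
            res.stimulated.state.L_i,
            res.stimulated.state.P,
        ])
    return np.array(preds)


def recover_parameters(
    observations: pd.DataFrame,
    scenarios: Sequence[Scenario],
    free: Sequence[str],
    reference: KineticParameters,
    env: Environment,
    options: ModelOptions = DEFAULT_OPTIONS,
    init: Optional[Mapping[str, float]] = None,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    truth: Optional[Mapping[str, float]] = None,
) -> RecoveryResult:
    """Weighted least-squares fit of free parameters to observations.

    Residuals are weighted by the inverse standard deviation of the
    multiplicative noise model (``sigma = noise_cv * |observed|``; for exact
    observations a uniform relative weighting is used).  Flags the design as
    non-identifiable when the observation count is insufficient or the
    Jacobian at the solution is rank-deficient.
    """
    free = list(free)
    obs_order = observations.sort_values("condition")
    y_obs = obs_order[list(OBSERVABLES)].to_numpy().ravel()
    noise_cv = float(obs_order["noise_cv"].iloc[0]) if "noise_cv" in obs_order else 0.0
    scale = np.maximum(np.abs(y_obs), 1e-12)
    sigma = (noise_cv if noise_cv > 0 else 1.0) * scale

    n_informative = y_obs.size
    if n_informative < len(free):
        return RecoveryResult(
            estimates={}, truth=dict(truth) if truth else None,
            relative_errors=None, loss=np.nan, converged=False,
            identifiable=False,
            message=f"{n_informative} observations for {len(free)} free parameters",
        )

    x0 = np.array([
        (init or {}).get(name, getattr(reference, name)) for name in free
    ])
    default_bounds = {name: (getattr(reference, name) * 0.1,
                             getattr(reference, name) * 10.0) for name in free}
    bmap = {**default_bounds, **(bounds or {})}
    lo = np.array([bmap[name][0] for name in free])
    hi = np.array([bmap[name][1] for name in free])

    def residuals(x: np.ndarray) -> np.ndarray:
        candidate = dataclasses.replace(
            reference, **{name: float(v) for name, v in zip(free, x)}
        )
        try:
            pred = _predict(candidate, env, options, scenarios)
        except ConvergenceError:
            return np.full_like(y_obs, 1e6)
        return (pred - y_obs) / sigma

    fit = least_squares(
        residuals, np.clip(x0, lo, hi), bounds=(lo, hi),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    estimates = {name: float(v) for name, v in zip(free, fit.x)}
    # identifiability: singular Jacobian => flat directions in the loss
    jac = np.atleast_2d(fit.jac)
    sv = np.linalg.svd(jac, compute_uv=False)
    identifiable = bool(sv.size and sv[-1] > 1e-8 * sv[0])

    rel_errors = None
    if truth:
        rel_errors = {
            name: abs(estimates[name] - truth[name]) / abs(truth[name])
            for name in free if name in truth
        }
    return RecoveryResult(
        estimates=estimates,
        truth=dict(truth) if truth else None,
        relative_errors=rel_errors,
        loss=float(2 * fit.cost),
        converged=bool(fit.success),
        identifiable=identifiable,
        message=fit.message,
    )


def integration_oracle(
    params: KineticParameters,
    env: Environment,
    options: ModelOptions = DEFAULT_OPTIONS,
    initial: Optional[CellState] = None,
    t_end: float = 1e5,
    return_trajectory: bool = False,
):
    """Stiff integration of the full ODE system to late time.

    An independent brute-force route to the steady state, used to validate
    the Newton solver.  Returns the final :class:`CellState`, or
    ``(final_state, t, y)`` when ``return_trajectory`` is set.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    y0 = (initial.as_array() if initial is not None
          else np.array([0.9, 0.075, 0.01 * params.N_tot]))
    sol = solve_ivp(
        lambda _t, y: rhs_array(np.clip(y, 0.0, None), params, env, options),
        (0.0, t_end), y0, method="LSODA", rtol=1e-12, atol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1]:g}: {sol.message}"
        )
    yf = np.clip(sol.y[:, -1], 0.0, None)
    final = CellState(L_i=float(yf[0]), P=float(yf[1]),
                      NADH=float(min(yf[2], params.N_tot)))
    if return_trajectory:
        return final, sol.t, sol.y
    return final
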