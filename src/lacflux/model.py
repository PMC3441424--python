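"""Core single-cell model: state, parameters, flux laws and ODE right-hand side.

The model tracks three cytosolic state variables — intracellular lactate
``L_i``, pyruvate ``P`` and reduced nicotinamide-adenine dinucleotide
``NADH`` — in a single brain cell bathed in a fixed environment (extracellular
lactate, glucose, intra-/extracellular protons).  Five fluxes connect them:

* ``J_MCT``     net inward lactate transport through monocarboxylate
                transporters (MCTs), modelled as a symmetric proton-coupled
                carrier; positive = uptake, negative = export.
* ``J_LDH``     net lactate dehydrogenase rate, mass-action in both
                directions and linear in the total LDH pool; positive =
                pyruvate + NADH -> lactate + NAD+.
* ``J_glyco``   pyruvate production by glycolysis (pyruvate-equivalents;
                the 2 pyruvate/glucose stoichiometry is absorbed into the
                maximal rate), Michaelis–Menten in glucose and in NAD+.
* ``J_PDH``     pyruvate consumption by pyruvate dehydrogenase,
                Michaelis–Menten in pyruvate; proxies oxidative metabolism.
* ``J_shuttle`` re-oxidation of cytosolic NADH by the mitochondrial shuttles
                (mainly malate–aspartate), first order in NADH.

Balance equations::

    dL_i/dt  = J_MCT   + J_LDH
    dP/dt    = J_glyco - J_LDH - J_PDH
    dNADH/dt = J_glyco - J_LDH - J_shuttle

NAD+ is never integrated: it is derived from the conserved pool
``NAD+ = N_tot - NADH``.  All concentrations are mM, all fluxes mM/s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Environment",
    "CellState",
    "KineticParameters",
    "MCTForm",
    "ModelOptions",
    "FluxVector",
    "flux_mct",
    "flux_ldh",
    "flux_glycolysis",
    "flux_pdh",
    "flux_shuttle",
    "compute_fluxes",
    "rhs",
]

# default validation window for intracellular protons, mM
# (pH_i between 7.8 and 6.6 — the physiologically scanned range)
H_I_MIN = 10.0 ** -4.8
H_I_MAX = 10.0 ** -3.6


class InvalidStateError(ValueError):
    """A concentration or pool constraint is violated."""


class ConfigurationError(ValueError):
    """Inconsistent model options."""


def _require_positive(obj, names) -> None:
    for name in names:
        value = getattr(obj, name)
        if not np.isfinite(value) or value <= 0:
            raise InvalidStateError(
                f"{type(obj).__name__}.{name} must be finite and > 0, got {value!r}"
            )


@dataclass(frozen=True)
class Environment:
    """Fixed boundary conditions around the cell.

    Parameters
    ----------
    L_e : extracellular lactate (mM)
    Glc : glucose (mM)
    H_i : intracellular proton concentration (mM); 1e-4.2 mM is pH_i 7.2
    H_e : extracellular proton concentration (mM); 1e-4.4 mM is pH_e 7.4
    """

    L_e: float = 1.0
    Glc: float = 1.0
    H_i: float = 10.0 ** -4.2
    H_e: float = 10.0 ** -4.4
    validate_ph: bool = True

    def __post_init__(self) -> None:
        _require_positive(self, ("L_e", "Glc", "H_i", "H_e"))
        if self.validate_ph and not (H_I_MIN <= self.H_i <= H_I_MAX):
            raise InvalidStateError(
                f"H_i={self.H_i:g} mM outside validated range "
                f"[{H_I_MIN:g}, {H_I_MAX:g}] mM (pH_i 7.8–6.6); "
                "pass validate_ph=False to override"
            )


@dataclass(frozen=True)
class CellState:
    """Dynamic variables: intracellular lactate, pyruvate, cytosolic NADH (mM)."""

    L_i: float
    P: float
    NADH: float

    def __post_init__(self) -> None:
        for name in ("L_i", "P", "NADH"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise InvalidStateError(
                    f"CellState.{name} must be finite and >= 0, got {value!r}"
                )

    def nad(self, params: "KineticParameters") -> float:
        """NAD+ by pool conservation (mM)."""
        nad = params.N_tot - self.NADH
        if nad < 0:
            raise InvalidStateError(
                f"NADH={self.NADH:g} exceeds total pool N_tot={params.N_tot:g}"
            )
        return nad

    def as_array(self) -> np.ndarray:
        return np.array([self.L_i, self.P, self.NADH], dtype=float)


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants, capacities and conserved pools of the five flux laws.

    Units: maximal rates mM/s, half-saturations mM, ``k_shuttle`` 1/s,
    LDH rate constants 1/(mM·s) (per mM of enzyme), pools mM.
    """

    v_max_MCT: float
    K_MCT_L: float
    K_MCT_H: float
    v_max_glyco: float
    K_glc: float
    K_NAD_g: float
    v_max_PDH: float
    K_PDH: float
    k_shuttle: float
    k_f_LDH: float
    k_r_LDH: float
    LDH_total: float = 3.2
    N_tot: float = 0.5

    _FIELDS = (
        "v_max_MCT", "K_MCT_L", "K_MCT_H", "v_max_glyco", "K_glc", "K_NAD_g",
        "v_max_PDH", "K_PDH", "k_shuttle", "k_f_LDH", "k_r_LDH",
        "LDH_total", "N_tot",
    )

    def __post_init__(self) -> None:
        for name in self._FIELDS:
            value = getattr(self, name)
            # capacities may be set to zero in degenerate/test configurations
            if not np.isfinite(value) or value < 0:
                raise InvalidStateError(
                    f"KineticParameters.{name} must be finite and >= 0, got {value!r}"
                )
        if self.N_tot <= 0:
            raise InvalidStateError("N_tot must be > 0")

    def replace(self, **changes) -> "KineticParameters":
        return dataclasses.replace(self, **changes)


class MCTForm(str, Enum):
    """Which carrier equation the lactate transporter uses."""

    PROTON_COUPLED = "proton_coupled"
    SIMPSON_ALTERNATIVE = "simpson_alternative"


@dataclass(frozen=True)
class ModelOptions:
    mct_form: MCTForm = MCTForm.PROTON_COUPLED
    frozen_glycolysis: bool = False
    J_glyco_fixed: Optional[float] = None

    def __post_init__(self) -> None:
        if self.frozen_glycolysis and self.J_glyco_fixed is None:
            raise ConfigurationError(
                "frozen_glycolysis=True requires J_glyco_fixed"
            )
        if not self.frozen_glycolysis and self.J_glyco_fixed is not None:
            raise ConfigurationError(
                "J_glyco_fixed given but frozen_glycolysis is False"
            )


DEFAULT_OPTIONS = ModelOptions()


@dataclass(frozen=True)
class FluxVector:
    """The five instantaneous fluxes (mM/s) evaluated at one state."""

    J_MCT: float
    J_LDH: float
    J_glyco: float
    J_PDH: float
    J_shuttle: float

    NAMES = ("J_MCT", "J_LDH", "J_glyco", "J_PDH", "J_shuttle")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.NAMES}


def _mct_saturation(L: float, H: float, params: KineticParameters) -> float:
    return (L * H) / ((L + params.K_MCT_L) * (H + params.K_MCT_H))


def flux_mct(
    state: CellState,
    params: KineticParameters,
    env: Environment,
    options: ModelOptions = DEFAULT_OPTIONS,
) -> float:
    """Net inward lactate flux through the MCT carrier (mM/s).

    Default form is a symmetric carrier co-transporting one proton with one
    lactate: ``v_max * [s(L_e, H_e) - s(L_i, H_i)]`` with
    ``s(L, H) = L·H / ((L + K_L)(H + K_H))``.  The alternative form drops the
    proton coupling (simple facilitated carrier in lactate alone).
    """
    if options.mct_form is MCTForm.SIMPSON_ALTERNATIVE:
        s_out = env.L_e / (env.L_e + params.K_MCT_L)
        s_in = state.L_i / (state.L_i + params.K_MCT_L)
    else:
        s_out = _mct_saturation(env.L_e, env.H_e, params)
        s_in = _mct_saturation(state.L_i, env.H_i, params)
    return params.v_max_MCT * (s_out - s_in)


def flux_ldh(state: CellState, params: KineticParameters) -> float:
    """Net LDH rate (mM/s); > 0 means pyruvate + NADH -> lactate + NAD+."""
    nad = state.nad(params)
    return params.LDH_total * (
        params.k_f_LDH * state.P * state.NADH
        - params.k_r_LDH * state.L_i * nad
    )


def flux_glycolysis(
    state: CellState,
    params: KineticParameters,
    env: Environment,
    options: ModelOptions = DEFAULT_OPTIONS,
) -> float:
    """Glycolytic pyruvate production (mM/s, pyruvate-equivalents).

    Michaelis–Menten in glucose and in cytosolic NAD+ (glycolysis stalls when
    the NAD+ pool is fully reduced).  In frozen mode the flux is clamped to
    ``options.J_glyco_fixed`` regardless of state.
    """
    if options.frozen_glycolysis:
        return float(options.J_glyco_fixed)
    nad = state.nad(params)
    return (
        params.v_max_glyco
        * env.Glc / (env.Glc + params.K_glc)
        * nad / (nad + params.K_NAD_g)
    )


def flux_pdh(state: CellState, params: KineticParameters) -> float:
    """Pyruvate consumption by PDH (mM/s), Michaelis–Menten in pyruvate."""
    return params.v_max_PDH * state.P / (state.P + params.K_PDH)


def flux_shuttle(state: CellState, params: KineticParameters) -> float:
    """Mitochondrial NADH re-oxidation (mM/s), first order in NADH."""
    return params.k_shuttle * state.NADH


def compute_fluxes(
    state: CellState,
    params: KineticParameters,
    env: Environment,
    options: ModelOptions = DEFAULT_OPTIONS,
) -> FluxVector:
    """Evaluate all five flux laws at one state (single code path with rhs)."""
    return FluxVector(
        J_MCT=flux_mct(state, params, env, options),
        J_LDH=flux_ldh(state, params),
        J_glyco=flux_glycolysis(state, params, env, options),
        J_PDH=flux_pdh(state, params),
        J_shuttle=flux_shuttle(state, params),
    )


def rhs(
    state: CellState,
    params: KineticParameters,
    env: Environment,
    options: ModelOptions = DEFAULT_OPTIONS,
) -> np.ndarray:
    """Time derivative (dL_i/dt, dP/dt, dNADH/dt) in mM/s."""
    f = compute_fluxes(state, params, env, options)
    return np.array(
        [
            f.J_MCT + f.J_LDH,
            f.J_glyco - f.J_LDH - f.J_PDH,
            f.J_glyco - f.J_LDH - f.J_shuttle,
        ]
    )


def rhs_array(
    y: np.ndarray,
    params: KineticParameters,
    env: Environment,
    options: ModelOptions = DEFAULT_OPTIONS,
) -> np.ndarray:
    """rhs on a raw (L_i, P, NADH) array — fast path for solvers.

    Unlike :func:`rhs` this does not validate the state; solver iterates are
    kept in bounds by the callers (variable transforms / clipping).
    """
    L_i, P, NADH = y
    nad = params.N_tot - NADH
    if options.mct_form is MCTForm.SIMPSON_ALTERNATIVE:
        s_out = env.L_e / (env.L_e + params.K_MCT_L)
        s_in = L_i / (L_i + params.K_MCT_L)
    else:
        s_out = _mct_saturation(env.L_e, env.H_e, params)
        s_in = (L_i * env.H_i) / ((L_i + params.K_MCT_L) * (env.H_i + params.K_MCT_H))
    j_mct = params.v_max_MCT * (s_out - s_in)
    j_ldh = params.LDH_total * (
        params.k_f_LDH * P * NADH - params.k_r_LDH * L_i * nad
    )
    if options.frozen_glycolysis:
        j_gly = options.J_glyco_fixed
    else:
        j_gly = (
            params.v_max_glyco
            * env.Glc / (env.Glc + params.K_glc)
            * nad / (nad + params.K_NAD_g)
        )
    j_pdh = params.v_max_PDH * P / (P + params.K_PDH)
    j_sh = params.k_shuttle * NADH
    return np.array(
        [j_mct + j_ldh, j_gly - j_ldh - j_pdh, j_gly - j_ldh - j_sh]
    )
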