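"""Named multiplicative stimulation scenarios and basal-vs-stimulated runs.

A :class:`Scenario` is a map from parameter/environment field names to
multiplicative factors (e.g. ``v_max_PDH -> 1.3`` for a +30% rise in PDH
capacity), optionally with

* ``f`` — a shorthand factor applied jointly to ``v_max_PDH`` and
  ``k_shuttle`` (the two oxidative-capacity knobs are often co-stimulated);
* ``frozen_glycolysis`` — clamp the glycolytic flux of the stimulated state
  to its basal value (cells that cannot upregulate glycolysis);
* ``baseline`` — another scenario applied first to obtain the basal cell
  (e.g. the glycolytic cell is the oxidative reference with PDH capacity
  x0.3 and shuttle constant x0.2).

``run_scenario`` solves the basal and stimulated steady states and reports
percent changes of every flux.  For lactate exporters (negative basal
``J_MCT``) the transport change is reported on the release magnitude
``|J_MCT|``, matching how lactate release is quoted experimentally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .model import (
    DEFAULT_OPTIONS,
    Environment,
    KineticParameters,
    ModelOptions,
)
from .steady_state import SteadyStateResult, solve_steady_state

__all__ = [
    "Scenario",
    "ScenarioResult",
    "apply_scenario",
    "run_scenario",
    "builtin_scenarios",
]

_PARAM_FIELDS = set(KineticParameters._FIELDS)
_ENV_FIELDS = {"L_e", "Glc", "H_i", "H_e"}

# Glycolytic-capacity factor of the cultured-cell calibration: chosen so the
# reference cell at 1.1 mM extracellular lactate settles at a supply ratio
# r = J_MCT/J_glyco of 3.2 (set by analysis/01_calibrate_reference.py).
INVITRO_GLYCO_FACTOR = 0.40119400442938424


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class Scenario:
    """A named set of multiplicative parameter/environment changes."""

    name: str
    multipliers: Mapping[str, float] = field(default_factory=dict)
    frozen_glycolysis: bool = False
    f: Optional[float] = None
    baseline: Optional["Scenario"] = None

    def __post_init__(self) -> None:
        for key, factor in self.multipliers.items():
            if key not in _PARAM_FIELDS | _ENV_FIELDS:
                raise ScenarioError(f"{self.name}: unknown field {key!r}")
            if not factor > 0:
                raise ScenarioError(
                    f"{self.name}: factor for {key} must be > 0, got {factor!r}"
                )
        if self.f is not None and not self.f > 0:
            raise ScenarioError(f"{self.name}: f must be > 0")

    def effective_multipliers(self) -> Dict[str, float]:
        """Explicit multipliers with the shorthand ``f`` expanded."""
        out = dict(self.multipliers)
        if self.f is not None:
            for key in ("v_max_PDH", "k_shuttle"):
                out[key] = out.get(key, 1.0) * self.f
        return out

    def inverse(self) -> "Scenario":
        return Scenario(
            name=f"{self.name}__inverse",
            multipliers={k: 1.0 / v for k, v in self.effective_multipliers().items()},
        )


@dataclass(frozen=True)
class ScenarioResult:
    scenario: Scenario
    basal: SteadyStateResult
    stimulated: SteadyStateResult
    pct_change: Dict[str, float]
    realized_gamma: float  # percent change of transport flux (release-signed)


def apply_scenario(
    params: KineticParameters, env: Environment, scenario: Scenario
) -> Tuple[KineticParameters, Environment]:
    """Return modified copies of params/env; the originals are untouched."""
    p_changes: Dict[str, float] = {}
    e_changes: Dict[str, float] = {}
    for key, factor in scenario.effective_multipliers().items():
        if key in _PARAM_FIELDS:
            p_changes[key] = getattr(params, key) * factor
        else:
            e_changes[key] = getattr(env, key) * factor
    new_params = dataclasses.replace(params, **p_changes) if p_changes else params
    new_env = dataclasses.replace(env, **e_changes) if e_changes else env
    return new_params, new_env


def _pct(basal: float, stimulated: float) -> float:
    if basal == 0:
        return float("nan")
    return 100.0 * (stimulated - basal) / abs(basal)


def run_scenario(
    params: KineticParameters,
    env: Environment,
    options: ModelOptions = DEFAULT_OPTIONS,
    scenario: Scenario = Scenario("identity"),
) -> ScenarioResult:
    """Solve basal and stimulated steady states and report percent changes.

    Percent change of a flux J is ``100 (J_stim - J_basal) / |J_basal|``;
    when the basal cell exports lactate the ``J_MCT`` entry is computed on
    the release magnitude ``|J_MCT|`` instead, so "+91" means 91% more
    lactate released.
    """
    if scenario.baseline is not None:
        basal_params, basal_env = apply_scenario(params, env, scenario.baseline)
    else:
        basal_params, basal_env = params, env
    basal = solve_steady_state(basal_params, basal_env, options)

    stim_params, stim_env = apply_scenario(basal_params, basal_env, scenario)
    stim_options = options
    if scenario.frozen_glycolysis:
        stim_options = dataclasses.replace(
            options, frozen_glycolysis=True, J_glyco_fixed=basal.fluxes.J_glyco
        )
    stimulated = solve_steady_state(
        stim_params, stim_env, stim_options, initial_guess=basal.state
    )

    pct = {
        name: _pct(getattr(basal.fluxes, name), getattr(stimulated.fluxes, name))
        for name in basal.fluxes.NAMES
    }
    if basal.fluxes.J_MCT < 0:
        pct["J_MCT"] = _pct(abs(basal.fluxes.J_MCT), abs(stimulated.fluxes.J_MCT))
    return ScenarioResult(
        scenario=scenario,
        basal=basal,
        stimulated=stimulated,
        pct_change=pct,
        realized_gamma=pct["J_MCT"],
    )


def builtin_scenarios() -> Dict[str, Scenario]:
    """The published stimulation library, keyed by figure-panel name.

    Factors are exactly the ones printed in the figure legends.  Conditions
    stated as absolute extracellular lactate levels (1.1 mM, 5.5 mM) are
    encoded as multipliers relative to the bundled reference environment
    (L_e = 1.0 mM).
    """
    lib: Dict[str, Scenario] = {}

    def add(name: str, **kwargs) -> Scenario:
        sc = Scenario(name=name, **kwargs)
        lib[name] = sc
        return sc

    # -- oxidative cell stimulations (Fig 2A conditions) ------------------
    ctrl = {"v_max_PDH": 1.3, "k_shuttle": 1.3, "v_max_glyco": 1.485}
    add("fig2A_ctrl", multipliers=ctrl)
    add("fig2A_mct", multipliers={**ctrl, "v_max_MCT": 1.8})
    add("fig2A_le", multipliers={**ctrl, "L_e": 1.8})
    add("fig2A_combined", multipliers={**ctrl, "v_max_MCT": 1.8, "L_e": 1.8})

    # -- glycolytic cell: PDH capacity x0.3, shuttle constant x0.2 --------
    gly = add("fig2B_basal",
              multipliers={"v_max_PDH": 0.3, "k_shuttle": 0.2})
    stim_b = {"v_max_PDH": 1.15, "v_max_glyco": 1.485}
    add("fig2B_ctrl", multipliers=ctrl, baseline=gly)
    add("fig2B_mct", multipliers={**stim_b, "v_max_MCT": 1.8}, baseline=gly)
    add("fig2B_le", multipliers={**stim_b, "L_e": 1.8}, baseline=gly)
    add("fig2B_combined",
        multipliers={**stim_b, "v_max_MCT": 1.8, "L_e": 1.8}, baseline=gly)

    # -- fixed-glycolysis transport stimulations (Fig 3 conditions) -------
    add("fig3_f13", f=1.3, frozen_glycolysis=True)
    add("fig3_f17", f=1.7, frozen_glycolysis=True)

    # -- literature calibrations (Fig 4A) ---------------------------------
    invivo = add("fig4A_invivo",
                 multipliers={"L_e": 1.1, "v_max_glyco": 0.51})
    add("fig4A_invitro",
        multipliers={"L_e": 1.1, "v_max_glyco": INVITRO_GLYCO_FACTOR})
    add("fig4A_invitro_high_le",
        multipliers={"L_e": 5.5, "v_max_glyco": INVITRO_GLYCO_FACTOR})
    add("fig4A_invitro_low_glyco",
        multipliers={"L_e": 5.5, "v_max_glyco": INVITRO_GLYCO_FACTOR * 0.4})

    # -- in-vivo stimulations on top of the calibrated basal (Fig 4B) -----
    stim4 = {"v_max_PDH": 1.7, "k_shuttle": 1.7}
    add("fig4B_ctrl", multipliers=ctrl, baseline=invivo)
    add("fig4B_mct", multipliers={**stim4, "v_max_MCT": 1.8}, baseline=invivo)
    add("fig4B_le", multipliers={**stim4, "L_e": 1.8}, baseline=invivo)
    add("fig4B_combined",
        multipliers={**stim4, "v_max_MCT": 1.8, "L_e": 1.8}, baseline=invivo)

    # -- exporter at rest that switches to import upon activation ---------
    # (basal factors chosen as a mild exporter; the stimulation factors are
    #  the published ones: +80% transport, +100% PDH, +70% shuttle)
    nals = add("figS2_basal",
               multipliers={"v_max_PDH": 0.4, "k_shuttle": 0.35})
    stim_s2 = {"v_max_PDH": 2.0, "k_shuttle": 1.7}
    add("figS2_mct", multipliers={**stim_s2, "v_max_MCT": 1.8}, baseline=nals)
    add("figS2_le", multipliers={**stim_s2, "L_e": 1.8}, baseline=nals)
    add("figS2_combined",
        multipliers={**stim_s2, "v_max_MCT": 1.8, "L_e": 1.8}, baseline=nals)
    add("figS2_combined_glyco",
        multipliers={**stim_s2, "v_max_MCT": 1.8, "L_e": 1.8,
                     "v_max_glyco": 1.485},
        baseline=nals)

    return lib
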