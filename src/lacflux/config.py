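"""Configuration I/O: parameter sets, environments, options, constraints.

Configs are YAML (JSON is accepted interchangeably — YAML is a superset).
The bundled ``oxidative_reference`` config holds the calibrated parameter
set of a typical oxidative cell together with the physiological constraint
windows; it is the basal condition for every published scenario and scan.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import yaml

from .model import Environment, KineticParameters, MCTForm, ModelOptions
from .scenarios import Scenario
from .steady_state import ConstraintSet

__all__ = ["ModelConfig", "load_config", "save_config", "oxidative_reference"]

_SECTIONS = {"parameters", "environment", "options", "constraints", "scenarios"}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    parameters: KineticParameters
    environment: Environment
    options: ModelOptions
    constraints: ConstraintSet
    scenarios: Dict[str, Scenario] = field(default_factory=dict)


def _check_keys(section: str, data: dict, allowed) -> None:
    unknown = set(data) - set(allowed)
    if unknown:
        raise ConfigError(f"{section}: unknown keys {sorted(unknown)}")


def _parse(data: dict, source: str) -> ModelConfig:
    if not isinstance(data, dict):
        raise ConfigError(f"{source}: top level must be a mapping")
    _check_keys("config", data, _SECTIONS)
    try:
        raw_params = dict(data["parameters"])
    except KeyError:
        raise ConfigError(f"{source}: missing required section 'parameters'")
    _check_keys("parameters", raw_params, KineticParameters._FIELDS)
    missing = [f.name for f in dataclasses.fields(KineticParameters)
               if f.default is dataclasses.MISSING and f.name not in raw_params]
    if missing:
        raise ConfigError(f"{source}: parameters missing {missing}")
    for key, value in raw_params.items():
        if not float(value) > 0:
            raise ConfigError(
                f"{source}: parameter {key} must be > 0, got {value!r}"
            )
    try:
        params = KineticParameters(**{k: float(v) for k, v in raw_params.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{source}: invalid parameters: {exc}") from exc

    raw_env = dict(data.get("environment", {}))
    _check_keys("environment", raw_env, ("L_e", "Glc", "H_i", "H_e"))
    env = Environment(**{k: float(v) for k, v in raw_env.items()})

    raw_opt = dict(data.get("options", {}))
    _check_keys("options", raw_opt,
                ("mct_form", "frozen_glycolysis", "J_glyco_fixed"))
    if "mct_form" in raw_opt:
        raw_opt["mct_form"] = MCTForm(raw_opt["mct_form"])
    options = ModelOptions(**raw_opt)

    raw_con = dict(data.get("constraints", {}))
    _check_keys("constraints", raw_con,
                ("L_i_range", "lp_ratio_range", "redox_range"))
    if raw_con:
        constraints = ConstraintSet(
            **{k: tuple(float(x) for x in v) for k, v in raw_con.items()}
        )
    else:
        raise ConfigError(f"{source}: missing required section 'constraints'")

    scenario_lib: Dict[str, Scenario] = {}
    for name, spec in dict(data.get("scenarios", {})).items():
        _check_keys(f"scenario {name}", spec,
                    ("multipliers", "frozen_glycolysis", "f", "baseline"))
        baseline = spec.get("baseline")
        scenario_lib[name] = Scenario(
            name=name,
            multipliers={k: float(v)
                         for k, v in dict(spec.get("multipliers", {})).items()},
            frozen_glycolysis=bool(spec.get("frozen_glycolysis", False)),
            f=float(spec["f"]) if spec.get("f") is not None else None,
            baseline=scenario_lib[baseline] if baseline else None,
        )
    return ModelConfig(parameters=params, environment=env, options=options,
                       constraints=constraints, scenarios=scenario_lib)


def load_config(path: Union[str, Path]) -> ModelConfig:
    """Load and validate a YAML/JSON config; unknown keys are rejected."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _parse(data, str(path))


def _to_dict(config: ModelConfig) -> dict:
    return {
        "parameters": {name: float(getattr(config.parameters, name))
                       for name in KineticParameters._FIELDS},
        "environment": {name: float(getattr(config.environment, name))
                        for name in ("L_e", "Glc", "H_i", "H_e")},
        "options": {
            "mct_form": config.options.mct_form.value,
            "frozen_glycolysis": config.options.frozen_glycolysis,
            **({"J_glyco_fixed": config.options.J_glyco_fixed}
               if config.options.J_glyco_fixed is not None else {}),
        },
        "constraints": {
            "L_i_range": list(config.constraints.L_i_range),
            "lp_ratio_range": list(config.constraints.lp_ratio_range),
            "redox_range": list(config.constraints.redox_range),
        },
        "scenarios": {
            name: {
                "multipliers": {k: float(v) for k, v in sc.multipliers.items()},
                "frozen_glycolysis": sc.frozen_glycolysis,
                **({"f": float(sc.f)} if sc.f is not None else {}),
                **({"baseline": sc.baseline.name} if sc.baseline else {}),
            }
            for name, sc in config.scenarios.items()
        },
    }


def save_config(config: ModelConfig, path: Union[str, Path]) -> None:
    """Write a config; floats keep full precision (round-trip exact)."""
    path = Path(path)
    data = _to_dict(config)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def oxidative_reference() -> ModelConfig:
    """The bundled calibrated reference config of a typical oxidative cell."""
    resource = importlib.resources.files("lacflux") / "configs" / "oxidative_reference.yaml"
    data = yaml.safe_load(resource.read_text())
    return _parse(data, "oxidative_reference")
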