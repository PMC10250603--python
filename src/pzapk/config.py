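"""YAML run configuration.

A run config collects the cohort design, model settings, estimation /
VPC / bootstrap settings and the master seed.  Every stochastic step draws
its seed from here, so re-running a command with the same config and seed
reproduces its outputs exactly.  CLI flags override config entries.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Mapping

import yaml

from .cohort import CohortDesign
from .modelspec import ModelSpec, base_model_spec, final_model_spec
from .pk import PopulationParameters, omega_from_cv_percent

__all__ = ["load_config", "design_from_config", "spec_from_config", "params_from_config"]

_DEFAULTS: dict[str, Any] = {
    "seed": 1,
    "design": {},
    "model": {"spec": "final", "omega_scale": "cv_percent", "values": {}},
    "estimation": {"maxiter": 300, "compute_se": True},
    "vpc": {"n_sim": 1000, "bins": 8},
    "bootstrap": {"n_resamples": 1000},
}


class ConfigError(ValueError):
    pass


def load_config(path: str | None) -> dict:
    """Load and validate a YAML config, filling defaults; ``None`` gives the
    pure defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in _DEFAULTS.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ConfigError("config root must be a mapping")
        for key, value in user.items():
            if key not in cfg:
                raise ConfigError(f"unknown config section {key!r}")
            if isinstance(cfg[key], dict):
                if not isinstance(value, Mapping):
                    raise ConfigError(f"section {key!r} must be a mapping")
                cfg[key].update(value)
            else:
                cfg[key] = value
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    return cfg


def design_from_config(cfg: Mapping) -> CohortDesign:
    fields = {f.name for f in dataclasses.fields(CohortDesign)}
    kwargs = dict(cfg.get("design", {}))
    unknown = set(kwargs) - fields
    if unknown:
        raise ConfigError(f"unknown design option(s): {sorted(unknown)}")
    for key in ("fixed_times", "tablets", "age_beta", "lbw_beta",
                "lbw_male_range", "lbw_female_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return CohortDesign(**kwargs)


def params_from_config(cfg: Mapping) -> PopulationParameters:
    """Population parameters from the ``model.values`` section; IIV entries
    are read on the scale named by ``model.omega_scale`` (``cv_percent`` or
    ``sd``)."""
    model = cfg.get("model", {})
    values = dict(model.get("values", {}))
    scale = model.get("omega_scale", "cv_percent")
    if scale not in ("cv_percent", "sd"):
        raise ConfigError("omega_scale must be 'cv_percent' or 'sd'")
    if scale == "cv_percent":
        for key in ("omega_cl", "omega_v", "omega_ka"):
            if key in values:
                values[key] = omega_from_cv_percent(values[key])
        base = PopulationParameters.from_cv_percent()
    else:
        base = PopulationParameters()
    return base.replace(**values)


def spec_from_config(cfg: Mapping) -> ModelSpec:
    model = cfg.get("model", {})
    name = model.get("spec", "final")
    pp = params_from_config(cfg)
    if name == "final":
        return final_model_spec(pp)
    if name == "base":
        return base_model_spec(pp)
    if name == "base-no-allometry":
        return base_model_spec(pp, allometry=None)
    raise ConfigError(f"unknown model spec {name!r} (final | base | base-no-allometry)")
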