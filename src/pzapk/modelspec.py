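"""Model specification: which fixed effects, covariate terms, random effects
and residual-error parameters a population fit estimates.

A :class:`ModelSpec` pins down the free-parameter vector used by the FOCE
engine and the optimizer: typical values ``(CL, V, Ka)`` and each estimated
covariate effect enter as fixed effects; diagonal log-normal interindividual
variability terms (some possibly fixed) and a single additive residual SD
complete the vector.  Positive parameters are optimised on the log scale;
covariate-effect thetas are optimised untransformed with bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .pk import PopulationParameters

__all__ = ["CovariateEffect", "ModelSpec", "ParamSet", "final_model_spec", "base_model_spec"]

ETA_NAMES = ("cl", "v", "ka")


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate term on a structural parameter.

    kind:
      * ``"allometric"`` - fixed-exponent power term ``(x/reference)**exponent``
      * ``"power"``      - estimated-exponent power term ``(x/reference)**theta``
      * ``"categorical"``- ``1 + theta * x`` for a 0/1 covariate
    """

    name: str
    parameter: str  # "cl" | "v" | "ka"
    kind: str
    column: str
    reference: float = 1.0
    exponent: float | None = None  # fixed exponent (allometric only)
    init: float = 0.1

    def __post_init__(self) -> None:
        if self.parameter not in ETA_NAMES:
            raise ValueError(f"parameter must be one of {ETA_NAMES}, got {self.parameter!r}")
        if self.kind not in ("allometric", "power", "categorical"):
            raise ValueError(f"unknown covariate-effect kind {self.kind!r}")
        if self.kind == "allometric" and self.exponent is None:
            raise ValueError("allometric effects need a fixed exponent")

    @property
    def estimated(self) -> bool:
        return self.kind != "allometric"


@dataclass(frozen=True)
class ParamSet:
    """A concrete parameter value assignment for a :class:`ModelSpec`."""

    theta: Mapping[str, float]  # {"cl","v","ka"} typical values
    effects: Mapping[str, float]  # estimated covariate thetas by effect name
    omega: np.ndarray  # SDs of (eta_cl, eta_v, eta_ka)
    sigma: float  # additive residual SD (ug/mL)

    def as_series(self) -> pd.Series:
        vals = {
            "theta_cl": self.theta["cl"],
            "theta_v": self.theta["v"],
            "theta_ka": self.theta["ka"],
        }
        vals.update({f"theta_{k}": v for k, v in self.effects.items()})
        vals.update({f"omega_{n}": self.omega[i] for i, n in enumerate(ETA_NAMES)})
        vals["sigma"] = self.sigma
        return pd.Series(vals)


@dataclass(frozen=True)
class ModelSpec:
    """Estimation specification for the one-compartment steady-state model."""

    effects: tuple[CovariateEffect, ...] = ()
    theta_init: Mapping[str, float] = field(
        default_factory=lambda: {"cl": 4.0, "v": 40.0, "ka": 1.5}
    )
    omega_init: Mapping[str, float] = field(
        default_factory=lambda: {"cl": 0.1, "v": 0.03, "ka": 0.5}
    )
    omega_fixed: frozenset = frozenset({"v"})
    sigma_init: float = 3.0
    tau: float = 24.0

    def __post_init__(self) -> None:
        names = [e.name for e in self.effects]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate covariate-effect names: {names}")

    # -- free-parameter layout ------------------------------------------------

    @property
    def estimated_effects(self) -> tuple[CovariateEffect, ...]:
        return tuple(e for e in self.effects if e.estimated)

    @property
    def estimated_omegas(self) -> tuple[str, ...]:
        return tuple(n for n in ETA_NAMES if n not in self.omega_fixed)

    def param_names(self) -> list[str]:
        names = ["theta_cl", "theta_v", "theta_ka"]
        names += [f"theta_{e.name}" for e in self.estimated_effects]
        names += [f"omega_{n}" for n in self.estimated_omegas]
        names.append("sigma")
        return names

    def n_params(self) -> int:
        return len(self.param_names())

    def initial_paramset(self, inits: Mapping[str, float] | None = None) -> ParamSet:
        """Initial values, optionally overridden by entries of ``inits``
        keyed like :meth:`param_names` (e.g. ``theta_cl``, ``omega_ka``)."""
        inits = dict(inits or {})
        theta = {k: inits.pop(f"theta_{k}", self.theta_init[k]) for k in ("cl", "v", "ka")}
        effects = {e.name: inits.pop(f"theta_{e.name}", e.init) for e in self.estimated_effects}
        omega = np.array(
            [inits.pop(f"omega_{n}", self.omega_init[n]) for n in ETA_NAMES]
        )
        sigma = inits.pop("sigma", self.sigma_init)
        if inits:
            raise ValueError(f"unknown initial-value keys: {sorted(inits)}")
        return ParamSet(theta=theta, effects=effects, omega=omega, sigma=float(sigma))

    # -- packing for the optimizer -------------------------------------------

    def pack(self, ps: ParamSet) -> np.ndarray:
        x = [np.log(ps.theta["cl"]), np.log(ps.theta["v"]), np.log(ps.theta["ka"])]
        for e in self.estimated_effects:
            x.append(ps.effects[e.name])
        for n in self.estimated_omegas:
            x.append(np.log(max(ps.omega[ETA_NAMES.index(n)], 1e-8)))
        x.append(np.log(ps.sigma))
        return np.array(x, dtype=float)

    def unpack(self, x: np.ndarray) -> ParamSet:
        x = np.asarray(x, dtype=float)
        theta = {"cl": np.exp(x[0]), "v": np.exp(x[1]), "ka": np.exp(x[2])}
        i = 3
        effects = {}
        for e in self.estimated_effects:
            effects[e.name] = float(x[i])
            i += 1
        omega = np.array([self.omega_init[n] for n in ETA_NAMES], dtype=float)
        for n in self.estimated_omegas:
            omega[ETA_NAMES.index(n)] = np.exp(x[i])
            i += 1
        sigma = float(np.exp(x[i]))
        return ParamSet(theta=theta, effects=effects, omega=omega, sigma=sigma)

    def bounds(self) -> list[tuple[float, float]]:
        b: list[tuple[float, float]] = [(np.log(1e-3), np.log(1e4))] * 3
        for e in self.estimated_effects:
            b.append((-0.95, 20.0) if e.kind == "categorical" else (-5.0, 5.0))
        b += [(np.log(1e-4), np.log(6.0))] * len(self.estimated_omegas)
        b.append((np.log(1e-3), np.log(1e3)))
        return b

    # -- editing ---------------------------------------------------------------

    def with_effect(self, effect: CovariateEffect) -> "ModelSpec":
        return replace(self, effects=self.effects + (effect,))

    def without_effect(self, name: str) -> "ModelSpec":
        kept = tuple(e for e in self.effects if e.name != name)
        if len(kept) == len(self.effects):
            raise KeyError(f"no covariate effect named {name!r}")
        return replace(self, effects=kept)

    # -- bridges to the convenience container ---------------------------------

    def paramset_from_population(self, pp: PopulationParameters) -> ParamSet:
        """Translate a final-model :class:`PopulationParameters` into a
        :class:`ParamSet` for this spec (the spec must use the final-model
        effect name ``gdm_cl`` if it carries the geriatric-DM term)."""
        effects = {}
        for e in self.estimated_effects:
            if e.name == "gdm_cl":
                effects[e.name] = pp.theta_gdm_cl
            else:
                effects[e.name] = e.init
        return ParamSet(
            theta={"cl": pp.theta_cl, "v": pp.theta_v, "ka": pp.theta_ka},
            effects=effects,
            omega=pp.omega.copy(),
            sigma=pp.sigma_add,
        )

    def population_from_paramset(self, ps: ParamSet) -> PopulationParameters:
        return PopulationParameters(
            theta_cl=ps.theta["cl"],
            theta_gdm_cl=ps.effects.get("gdm_cl", 0.0),
            theta_v=ps.theta["v"],
            theta_ka=ps.theta["ka"],
            omega_cl=float(ps.omega[0]),
            omega_v=float(ps.omega[1]),
            omega_ka=float(ps.omega[2]),
            omega_fixed=tuple(sorted(self.omega_fixed)),
            sigma_add=ps.sigma,
        )


def final_model_spec(
    pp: PopulationParameters | None = None,
    allometry: str = "LBW",
    gdm_column: str = "gdm70",
) -> ModelSpec:
    """The final covariate model: fixed allometric scaling of CL (0.75) and V
    (1.0) by lean body weight (reference 48 kg) plus an estimated categorical
    geriatric-DM effect on CL.  ``pp`` seeds the initial values."""
    pp = pp or PopulationParameters.from_cv_percent()
    size_col = "lean_body_weight" if allometry.upper() == "LBW" else "body_weight"
    effects = (
        CovariateEffect(
            name="allo_cl", parameter="cl", kind="allometric", column=size_col,
            reference=pp.allometric_ref, exponent=pp.allometric_exp_cl,
        ),
        CovariateEffect(
            name="allo_v", parameter="v", kind="allometric", column=size_col,
            reference=pp.allometric_ref, exponent=pp.allometric_exp_v,
        ),
        CovariateEffect(
            name="gdm_cl", parameter="cl", kind="categorical", column=gdm_column,
            init=pp.theta_gdm_cl,
        ),
    )
    return ModelSpec(
        effects=effects,
        theta_init={"cl": pp.theta_cl, "v": pp.theta_v, "ka": pp.theta_ka},
        omega_init={"cl": pp.omega_cl, "v": pp.omega_v, "ka": pp.omega_ka},
        omega_fixed=frozenset(pp.omega_fixed),
        sigma_init=pp.sigma_add,
    )


def base_model_spec(pp: PopulationParameters | None = None, allometry: str | None = "LBW") -> ModelSpec:
    """Base (pre-covariate-search) model: structural parameters with optional
    allometric size scaling and no other covariates."""
    spec = final_model_spec(pp, allometry=allometry or "LBW").without_effect("gdm_cl")
    if allometry is None:
        spec = spec.without_effect("allo_cl").without_effect("allo_v")
    return spec
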