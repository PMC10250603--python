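"""One-compartment oral steady-state kinetics and covariate machinery.

The structural model is a one-compartment disposition model with first-order
absorption and first-order elimination, dosed orally once daily to steady
state.  Because bioavailability ``F`` is not separately identifiable after
oral dosing, all parameters are apparent quantities: clearance ``CL/F``
(L/h), central volume ``Vd/F`` (L) and the absorption rate constant ``Ka``
(1/h).

At steady state under a repeated dose ``D`` every ``tau`` hours the plasma
concentration ``t`` hours after the last dose is the superposition limit

    ke   = CL / V
    C(t) = D*Ka / (V*(Ka - ke)) * ( exp(-ke*t)/(1 - exp(-ke*tau))
                                  - exp(-Ka*t)/(1 - exp(-Ka*tau)) )

with the usual flip-flop limit form when ``Ka`` approaches ``ke``.

Covariates act multiplicatively on the typical parameter values:

* allometric body-size scaling on ``CL/F`` (exponent 0.75) and ``Vd/F``
  (exponent 1.0) using lean body weight relative to a 48 kg reference,
* a fractional shift on ``CL/F`` for geriatric (age >= 70 y) patients with
  diabetes mellitus,
* generic power / categorical covariate factors used by the covariate
  search machinery.

Individual parameters combine these factors with log-normal random effects:
``CL_i = TVCL * (LBW/48)**0.75 * (1 + theta_gdm*GDM) * exp(eta_CL)`` etc.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "DosingRegimen",
    "CovariateSet",
    "IndividualPK",
    "PopulationParameters",
    "concentration_ss",
    "concentration_single_dose",
    "conc_ss",
    "auc_0_24_ss",
    "cmax_ss",
    "power_covariate_factor",
    "categorical_covariate_factor",
    "allometric_factor",
    "is_geriatric_dm",
    "individual_parameters",
    "lean_body_weight",
    "omega_from_cv_percent",
    "cv_percent_from_omega",
    "reference_estimates",
]

# Relative half-life separation below which the flip-flop limit form is used.
_KA_KE_RTOL = 1e-6


class ParameterDomainError(ValueError):
    """Raised when a PK parameter violates its positivity/domain constraint."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)) or np.any(np.asarray(value) <= 0):
            raise ParameterDomainError(f"{name} must be strictly positive and finite, got {value!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DosingRegimen:
    """Oral once-daily dosing at steady state.

    Parameters
    ----------
    dose : float
        Amount per administration (mg).
    tau : float
        Dosing interval (h), 24 for once-daily dosing.
    steady_state : bool
        Whether the subject is assumed to be at steady state.  Non-steady-
        state subjects are excluded from all fitting and simulation here.
    """

    dose: float
    tau: float = 24.0
    steady_state: bool = True

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ParameterDomainError(f"dose must be non-negative, got {self.dose}")
        _require_positive(tau=self.tau)


@dataclass(frozen=True)
class CovariateSet:
    """Baseline covariates for one subject.

    Continuous covariates carry their clinical units (years, kg, g/dL,
    mg/dL, U/L).  ``feeding`` is ``"fasted"`` or ``"fed"``.
    """

    age: float
    sex: str  # "M" / "F"
    body_weight: float
    lean_body_weight: float
    dm: bool = False
    feeding: str = "fasted"
    renal_disease: bool = False
    liver_disease: bool = False
    albumin: float = 4.2
    total_bilirubin: float = 0.6
    ast: float = 27.0
    alt: float = 19.0

    def __post_init__(self) -> None:
        _require_positive(lean_body_weight=self.lean_body_weight, body_weight=self.body_weight)
        if self.age < 18:
            raise ParameterDomainError(f"age must be >= 18 y (adult study population), got {self.age}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.feeding not in ("fasted", "fed"):
            raise ValueError(f"feeding must be 'fasted' or 'fed', got {self.feeding!r}")


@dataclass(frozen=True)
class IndividualPK:
    """Individual apparent PK parameters with their random-effect vector."""

    cl: float
    v: float
    ka: float
    eta: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        _require_positive(cl=self.cl, v=self.v, ka=self.ka)


@dataclass(frozen=True)
class PopulationParameters:
    """Population (typical) parameters of the final covariate model.

    ``omega_*`` are the standard deviations of the log-normal interindividual
    random effects; entries named in ``omega_fixed`` are held constant during
    estimation.  ``sigma_add`` is the additive residual SD on the
    concentration scale (ug/mL).
    """

    theta_cl: float = 4.49
    theta_gdm_cl: float = 0.32
    theta_v: float = 44.2
    theta_ka: float = 1.49
    omega_cl: float = 0.0100
    omega_v: float = 0.0300
    omega_ka: float = 0.8326
    omega_fixed: tuple[str, ...] = ("v",)
    sigma_add: float = 3.41
    allometric_ref: float = 48.0
    allometric_exp_cl: float = 0.75
    allometric_exp_v: float = 1.0
    geriatric_age_cutoff: float = 70.0

    def __post_init__(self) -> None:
        _require_positive(
            theta_cl=self.theta_cl,
            theta_v=self.theta_v,
            theta_ka=self.theta_ka,
            sigma_add=self.sigma_add,
            allometric_ref=self.allometric_ref,
        )
        for name in ("omega_cl", "omega_v", "omega_ka"):
            if getattr(self, name) < 0:
                raise ParameterDomainError(f"{name} must be non-negative")
        if self.theta_gdm_cl <= -1:
            raise ParameterDomainError("theta_gdm_cl must exceed -1 (CL must stay positive)")
        for name in self.omega_fixed:
            if name not in ("cl", "v", "ka"):
                raise ValueError(f"unknown random effect {name!r} in omega_fixed")

    @property
    def omega(self) -> np.ndarray:
        """Random-effect SDs as an array ordered (CL, V, Ka)."""
        return np.array([self.omega_cl, self.omega_v, self.omega_ka])

    @classmethod
    def from_cv_percent(cls, iiv_cv: Sequence[float] = (1.0, 3.0, 100.0), **kwargs) -> "PopulationParameters":
        """Build parameters with IIV given as %CV of the log-normal effects."""
        cv_cl, cv_v, cv_ka = iiv_cv
        return cls(
            omega_cl=omega_from_cv_percent(cv_cl),
            omega_v=omega_from_cv_percent(cv_v),
            omega_ka=omega_from_cv_percent(cv_ka),
            **kwargs,
        )

    def replace(self, **kwargs) -> "PopulationParameters":
        return replace(self, **kwargs)


def omega_from_cv_percent(cv: float) -> float:
    """SD of a log-normal random effect whose coefficient of variation is ``cv`` %."""
    if cv < 0:
        raise ParameterDomainError("CV must be non-negative")
    return float(np.sqrt(np.log1p((cv / 100.0) ** 2)))


def cv_percent_from_omega(omega: float) -> float:
    """%CV of a log-normal random effect with log-scale SD ``omega``."""
    return float(np.sqrt(np.expm1(omega**2)) * 100.0)


def reference_estimates() -> PopulationParameters:
    """Published final-model population estimates for adult TB patients.

    Typical values: CL/F 4.49 L/h, Vd/F 44.2 L, Ka 1.49 1/h; geriatric-DM
    fractional CL shift 0.32; IIV %CV 1 / 3 (fixed) / 100 on CL, V, Ka;
    additive residual SD 3.41 ug/mL.  Allometric reference lean body weight
    48 kg with fixed exponents 0.75 (CL) and 1 (V).
    """
    return PopulationParameters.from_cv_percent()


# ---------------------------------------------------------------------------
# Structural model
# ---------------------------------------------------------------------------


def _conc_ss_flat(cl, v, ka, dose, tau, t):
    """Steady-state concentration for pre-aligned equal-length arrays.

    Internal fast path for the estimation engine: no broadcasting, no domain
    checks; identical arithmetic to :func:`concentration_ss`.
    """
    ke = cl / v
    diff = ka - ke
    near = np.abs(diff) < _KA_KE_RTOL * ka
    any_near = bool(near.any())
    if any_near:
        diff = np.where(near, 1.0, diff)
    e_ke_t = np.exp(-ke * t)
    acc_ke = -np.expm1(-ke * tau)
    out = dose * ka / (v * diff) * (e_ke_t / acc_ke - np.exp(-ka * t) / -np.expm1(-ka * tau))
    if any_near:
        i = np.flatnonzero(near)
        km = 0.5 * (ka[i] + ke[i])
        e_tau = np.exp(-km * tau[i])
        out[i] = (
            dose[i] * ka[i] / v[i] * np.exp(-km * t[i])
            * (t[i] * (1.0 - e_tau) + tau[i] * e_tau) / (1.0 - e_tau) ** 2
        )
    return np.maximum(out, 0.0)


def concentration_ss(cl, v, ka, dose, tau, t):
    """Steady-state concentration, vectorised over all arguments.

    Parameters may be scalars or broadcastable arrays; all must be strictly
    positive except ``dose`` (non-negative) and ``t`` in ``[0, tau]``.
    ``t = 0`` equals the trough value at ``t = tau`` (periodicity).
    """
    cl, v, ka, dose, tau, t = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (cl, v, ka, dose, tau, t))
    )
    ke = cl / v
    near = np.abs(ka - ke) < _KA_KE_RTOL * ka

    # General branch with a safe denominator where degenerate.
    denom = np.where(near, 1.0, ka - ke)
    e_ke_t = np.exp(-ke * t)
    e_ka_t = np.exp(-ka * t)
    acc_ke = 1.0 - np.exp(-ke * tau)
    acc_ka = 1.0 - np.exp(-ka * tau)
    general = dose * ka / (v * denom) * (e_ke_t / acc_ke - e_ka_t / acc_ka)

    # Flip-flop limit Ka -> ke:  C = D*Ka/V * e^{-kt} * [t(1-e^{-k tau}) + tau e^{-k tau}] / (1-e^{-k tau})^2
    # evaluated at the midpoint rate k = (Ka+ke)/2, which makes the switch
    # second-order accurate in (Ka - ke)
    km = 0.5 * (ka + ke)
    e_m_t = np.exp(-km * t)
    e_tau = np.exp(-km * tau)
    limit = dose * ka / v * e_m_t * (t * (1.0 - e_tau) + tau * e_tau) / (1.0 - e_tau) ** 2

    out = np.where(near, limit, general)
    return np.maximum(out, 0.0) if out.ndim else float(max(out, 0.0))


def concentration_single_dose(cl, v, ka, dose, t):
    """Concentration after a single oral dose at ``t >= 0`` hours."""
    cl, v, ka, dose, t = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (cl, v, ka, dose, t))
    )
    ke = cl / v
    near = np.abs(ka - ke) < _KA_KE_RTOL * ka
    denom = np.where(near, 1.0, ka - ke)
    general = dose * ka / (v * denom) * (np.exp(-ke * t) - np.exp(-ka * t))
    limit = dose * ka / v * t * np.exp(-0.5 * (ka + ke) * t)
    out = np.where(near, limit, general)
    return np.maximum(out, 0.0) if out.ndim else float(max(out, 0.0))


def conc_ss(pk: IndividualPK, reg: DosingRegimen, t) -> float | np.ndarray:
    """Steady-state concentration (ug/mL) ``t`` hours after the last dose."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > reg.tau):
        raise ValueError(f"t must lie in [0, tau={reg.tau}]")
    out = concentration_ss(pk.cl, pk.v, pk.ka, reg.dose, reg.tau, t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def auc_0_24_ss(pk: IndividualPK, reg: DosingRegimen) -> float:
    """Steady-state AUC over one dosing interval: ``AUC_ss = D / (CL/F)``."""
    if not reg.steady_state:
        raise ValueError("AUC over one interval equals D/CL only at steady state")
    return reg.dose / pk.cl


def cmax_ss(pk: IndividualPK, reg: DosingRegimen) -> tuple[float, float]:
    """Peak steady-state concentration and its time within one interval.

    The peak has no closed form at steady state; a dense grid is refined by
    bounded scalar maximisation.
    """
    grid = np.linspace(0.0, reg.tau, 513)
    conc = concentration_ss(pk.cl, pk.v, pk.ka, reg.dose, reg.tau, grid)
    i = int(np.argmax(conc))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda x: -concentration_ss(pk.cl, pk.v, pk.ka, reg.dose, reg.tau, x),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    tmax = float(res.x)
    cmax = float(-res.fun)
    if conc[i] > cmax:  # guard: refinement can never fall below the grid
        cmax, tmax = float(conc[i]), float(grid[i])
    return cmax, tmax


# ---------------------------------------------------------------------------
# Covariate machinery
# ---------------------------------------------------------------------------


def power_covariate_factor(value: float, median: float, exponent: float) -> float:
    """Continuous-covariate factor ``(value / median) ** exponent``."""
    _require_positive(value=value, median=median)
    return float((value / median) ** exponent)


def categorical_covariate_factor(effect: float, flag) -> float:
    """Categorical-covariate factor ``1 + effect * flag``."""
    flag = float(bool(flag))
    out = 1.0 + effect * flag
    if out <= 0:
        raise ParameterDomainError(f"categorical effect {effect} drives the parameter non-positive")
    return out


def allometric_factor(lbw: float, ref: float = 48.0, exponent: float = 0.75) -> float:
    """Allometric body-size factor ``(lbw / ref) ** exponent``."""
    return power_covariate_factor(lbw, ref, exponent)


def is_geriatric_dm(age: float, dm_flag: bool, cutoff: float = 70.0) -> bool:
    """Geriatric-diabetes indicator: age at or above the cutoff AND diabetic."""
    if age < 18:
        raise ValueError("adult study population: age must be >= 18 y")
    return bool(age >= cutoff and dm_flag)


def individual_parameters(
    model: PopulationParameters,
    cov: CovariateSet,
    eta: Sequence[float] = (0.0, 0.0, 0.0),
) -> IndividualPK:
    """Map population parameters + covariates + random effects to one subject.

    ``CL = theta_cl * (LBW/48)^0.75 * (1 + theta_gdm*GDM) * e^eta_CL``;
    ``V  = theta_v  * (LBW/48)^1    * e^eta_V``; ``Ka = theta_ka * e^eta_Ka``.
    """
    eta = tuple(float(e) for e in eta)
    gdm = is_geriatric_dm(cov.age, cov.dm, model.geriatric_age_cutoff)
    cl = (
        model.theta_cl
        * allometric_factor(cov.lean_body_weight, model.allometric_ref, model.allometric_exp_cl)
        * categorical_covariate_factor(model.theta_gdm_cl, gdm)
        * np.exp(eta[0])
    )
    v = (
        model.theta_v
        * allometric_factor(cov.lean_body_weight, model.allometric_ref, model.allometric_exp_v)
        * np.exp(eta[1])
    )
    ka = model.theta_ka * np.exp(eta[2])
    return IndividualPK(cl=float(cl), v=float(v), ka=float(ka), eta=eta)


def lean_body_weight(weight: float, height_cm: float, sex: str) -> float:
    """Janmahasatian lean body weight (kg) from total weight, height and sex."""
    _require_positive(weight=weight, height_cm=height_cm)
    bmi = weight / (height_cm / 100.0) ** 2
    if sex == "M":
        return 9270.0 * weight / (6680.0 + 216.0 * bmi)
    if sex == "F":
        return 9270.0 * weight / (8780.0 + 244.0 * bmi)
    raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
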