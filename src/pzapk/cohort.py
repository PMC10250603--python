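"""Synthetic cohort generator emulating the study population.

Generates adult TB patients with the demographic structure of the modelling
cohort (two-thirds male; median age ~54.5 y on 19-96; median lean body
weight ~48.1 kg; diabetes prevalence ~11%, enriched above age 70 so that
the four age-by-DM subgroups are proportioned like the study), guideline
once-daily dosing (nominal 25 mg/kg rounded to the nearest marketed tablet
strength, capped at 2000 mg), the sparse outpatient/inpatient sampling
scheme, and LLOQ censoring at 2.0 ug/mL.

Ages and lean body weights are drawn from scaled Beta distributions matched
to the published medians and ranges; diabetes uses piecewise age-specific
prevalences.  The generator returns both the dataset and the simulation
truth (parameters, eta and epsilon draws, pre-censoring concentrations) so
that estimation can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import LLOQ, Observation, SubjectRecord
from .modelspec import ModelSpec, ParamSet, final_model_spec
from .pk import CovariateSet, DosingRegimen, PopulationParameters, concentration_ss

__all__ = [
    "CohortDesign",
    "SimulationTruth",
    "sample_demographics",
    "assign_dose",
    "sample_times",
    "simulate_dataset",
    "study_design",
    "recovery_design",
]

TABLET_SIZES = (500.0, 1000.0, 1200.0, 1250.0, 1500.0, 1600.0, 2000.0)


@dataclass(frozen=True)
class CohortDesign:
    """Demographics, dosing rule, sampling scheme and censoring rule."""

    n_subjects: int = 488
    male_fraction: float = 0.666
    # age: scaled Beta on [age_min, age_max], matched to median 54.5 y and
    # ~22.5% of subjects aged >= 70
    age_min: float = 19.0
    age_max: float = 96.0
    age_beta: tuple[float, float] = (1.3, 1.5)
    # lean body weight: sex-specific scaled Betas, overall median ~48.1 kg
    lbw_male_range: tuple[float, float] = (28.0, 63.79)
    lbw_female_range: tuple[float, float] = (23.1, 55.0)
    lbw_beta: tuple[float, float] = (3.0, 2.0)
    weight_ratio_mu: float = 0.24  # log of TBW/LBW ratio
    weight_ratio_sd: float = 0.08
    dm_prevalence_young: float = 0.085
    dm_prevalence_old: float = 0.209
    dm_age_cutoff: float = 70.0
    gdm_fraction: float | None = None  # overrides DM/age joint draw when set
    fed_fraction: float = 0.244
    renal_fraction: float = 0.039
    liver_fraction: float = 0.03
    inpatient_fraction: float = 0.3
    sampling: str = "study"  # "study" | "fixed"
    fixed_times: tuple[float, ...] = (1.0, 2.0, 5.0)
    mg_per_kg: float = 25.0
    tablets: tuple[float, ...] = TABLET_SIZES
    max_dose: float = 2000.0
    lloq: float = LLOQ
    tau: float = 24.0

    def __post_init__(self) -> None:
        for name in ("male_fraction", "fed_fraction", "inpatient_fraction",
                     "dm_prevalence_young", "dm_prevalence_old"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.tablets:
            raise ValueError("tablet set must be non-empty")
        if self.lloq <= 0:
            raise ValueError("lloq must be positive")
        if self.sampling not in ("study", "fixed"):
            raise ValueError("sampling must be 'study' or 'fixed'")


def study_design(n_subjects: int = 488, **kwargs) -> CohortDesign:
    """The training-cohort design: sparse random outpatient / 0-1-2-5 h
    inpatient sampling with study demographics."""
    return CohortDesign(n_subjects=n_subjects, sampling="study", **kwargs)


def recovery_design(n_subjects: int = 500, gdm_fraction: float = 0.12, **kwargs) -> CohortDesign:
    """Parameter-recovery design: every subject sampled at 1, 2 and 5 h at
    steady state, with an elevated geriatric-DM fraction so the covariate
    effect is well informed."""
    return CohortDesign(
        n_subjects=n_subjects, sampling="fixed", gdm_fraction=gdm_fraction, **kwargs
    )


@dataclass(frozen=True)
class SimulationTruth:
    """Everything needed to score recovery: generating parameters, random
    draws and pre-censoring concentrations."""

    params: ParamSet
    eta: pd.DataFrame
    epsilon: np.ndarray
    concentrations: np.ndarray  # pre-censoring, per observation row
    seed: int


def _scaled_beta(rng: np.random.Generator, n: int, a: float, b: float,
                 lo: float, hi: float) -> np.ndarray:
    return lo + (hi - lo) * rng.beta(a, b, size=n)


def sample_demographics(design: CohortDesign, seed: int | np.random.Generator) -> list[CovariateSet]:
    """Draw per-subject covariates; reproducible under the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = design.n_subjects
    if n == 0:
        return []
    male = rng.random(n) < design.male_fraction
    a, b = design.age_beta
    age = _scaled_beta(rng, n, a, b, design.age_min, design.age_max)

    if design.gdm_fraction is not None:
        # recovery-style draw: a fixed fraction is geriatric-diabetic
        gdm = rng.random(n) < design.gdm_fraction
        dm = gdm.copy()
        age = np.where(gdm, rng.uniform(design.dm_age_cutoff, 90.0, n),
                       np.minimum(age, design.dm_age_cutoff - 1e-6))
    else:
        old = age >= design.dm_age_cutoff
        p = np.where(old, design.dm_prevalence_old, design.dm_prevalence_young)
        dm = rng.random(n) < p

    la, lb = design.lbw_beta
    lbw_m = _scaled_beta(rng, n, la, lb, *design.lbw_male_range)
    lbw_f = _scaled_beta(rng, n, la, lb, *design.lbw_female_range)
    lbw = np.where(male, lbw_m, lbw_f)
    ratio = np.exp(rng.normal(design.weight_ratio_mu, design.weight_ratio_sd, n))
    weight = lbw * np.clip(ratio, 1.05, 1.8)

    fed = rng.random(n) < design.fed_fraction
    renal = rng.random(n) < design.renal_fraction
    liver = rng.random(n) < design.liver_fraction
    albumin = np.clip(rng.normal(4.2, 0.5, n), 2.0, 7.0)
    tbil = np.clip(rng.lognormal(np.log(0.6), 0.4, n), 0.1, 5.0)
    ast = np.clip(rng.lognormal(np.log(27.0), 0.5, n), 5.0, 400.0)
    alt = np.clip(rng.lognormal(np.log(19.0), 0.6, n), 3.0, 400.0)

    return [
        CovariateSet(
            age=float(age[i]),
            sex="M" if male[i] else "F",
            body_weight=float(weight[i]),
            lean_body_weight=float(lbw[i]),
            dm=bool(dm[i]),
            feeding="fed" if fed[i] else "fasted",
            renal_disease=bool(renal[i]),
            liver_disease=bool(liver[i]),
            albumin=float(albumin[i]),
            total_bilirubin=float(tbil[i]),
            ast=float(ast[i]),
            alt=float(alt[i]),
        )
        for i in range(n)
    ]


def assign_dose(body_weight: float, mg_per_kg: float = 25.0,
                tablets: Sequence[float] = TABLET_SIZES, max_dose: float = 2000.0) -> float:
    """Guideline dose: nominal mg/kg amount rounded to the nearest marketed
    tablet strength, capped at the maximum daily dose."""
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    nominal = min(mg_per_kg * body_weight, max_dose)
    tablets = np.asarray(tablets, dtype=float)
    dose = float(tablets[np.argmin(np.abs(tablets - nominal))])
    return min(dose, max_dose)


def sample_times(patient_type: str, seed: int | np.random.Generator,
                 tau: float = 24.0) -> np.ndarray:
    """Observation times for one subject under the study sampling scheme.

    Outpatients contribute one random post-dose sample on (0, tau];
    inpatients contribute at least two of the pre-dose / 1 / 2 / 5 h points
    (pre-dose is the trough, represented as t = 0 of the steady-state
    interval).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if patient_type == "outpatient":
        u = rng.uniform(0.0, tau)
        return np.array([tau if u == 0.0 else u])
    if patient_type == "inpatient":
        k = int(rng.choice([2, 3], p=[0.7, 0.3]))
        return np.sort(rng.choice([0.0, 1.0, 2.0, 5.0], size=k, replace=False))
    raise ValueError("patient_type must be 'outpatient' or 'inpatient'")


def simulate_dataset(
    design: CohortDesign,
    params: PopulationParameters | ParamSet | None = None,
    seed: int = 0,
    spec: ModelSpec | None = None,
) -> tuple[list[SubjectRecord], SimulationTruth]:
    """Simulate a cohort under the final covariate model.

    eta ~ N(0, diag(omega^2)) on the log scale; observations are the
    steady-state concentration plus additive N(0, sigma^2) noise truncated
    at zero; values below the LLOQ keep their raw value but carry the BLQ
    flag (imputation is a separate explicit step).
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params = PopulationParameters.from_cv_percent()
    spec = spec or final_model_spec(params if isinstance(params, PopulationParameters) else None)
    ps = spec.paramset_from_population(params) if isinstance(params, PopulationParameters) else params

    covs = sample_demographics(design, rng)
    n = len(covs)
    eta = rng.normal(0.0, 1.0, size=(n, 3)) * ps.omega

    # per-subject structural parameters under the final covariate model
    from .foce import covariate_frame  # local import to avoid a cycle

    stubs = [
        SubjectRecord(
            id=f"S{i + 1:04d}",
            covariates=covs[i],
            regimen=DosingRegimen(dose=assign_dose(covs[i].body_weight, design.mg_per_kg,
                                                   design.tablets, design.max_dose),
                                  tau=design.tau),
        )
        for i in range(n)
    ]
    cov_tab = covariate_frame(stubs)
    fac_cl = np.ones(n)
    fac_v = np.ones(n)
    fac_ka = np.ones(n)
    for e in spec.effects:
        x = cov_tab[e.column].to_numpy(dtype=float)
        if e.kind == "allometric":
            f = (x / e.reference) ** e.exponent
        elif e.kind == "power":
            f = (x / e.reference) ** ps.effects[e.name]
        else:
            f = 1.0 + ps.effects[e.name] * x
        if e.parameter == "cl":
            fac_cl *= f
        elif e.parameter == "v":
            fac_v *= f
        else:
            fac_ka *= f
    cl = ps.theta["cl"] * fac_cl * np.exp(eta[:, 0])
    v = ps.theta["v"] * fac_v * np.exp(eta[:, 1])
    ka = ps.theta["ka"] * fac_ka * np.exp(eta[:, 2])

    inpatient = rng.random(n) < design.inpatient_fraction
    subjects = []
    all_eps = []
    all_true = []
    for i, stub in enumerate(stubs):
        if design.sampling == "fixed":
            times = np.asarray(design.fixed_times, dtype=float)
        else:
            times = sample_times("inpatient" if inpatient[i] else "outpatient", rng, design.tau)
        true_conc = concentration_ss(cl[i], v[i], ka[i], stub.regimen.dose, design.tau, times)
        true_conc = np.atleast_1d(true_conc)
        eps = rng.normal(0.0, ps.sigma, size=times.size)
        obs_conc = np.maximum(true_conc + eps, 0.0)
        obs = [
            Observation(time=float(t), conc=float(c), blq=bool(c < design.lloq))
            for t, c in zip(times, obs_conc)
        ]
        subjects.append(stub.with_observations(obs))
        all_eps.append(eps)
        all_true.append(true_conc)

    truth = SimulationTruth(
        params=ps,
        eta=pd.DataFrame(eta, columns=["eta_cl", "eta_v", "eta_ka"],
                         index=[s.id for s in subjects]),
        epsilon=np.concatenate(all_eps) if all_eps else np.array([]),
        concentrations=np.concatenate(all_true) if all_true else np.array([]),
        seed=seed,
    )
    return subjects, truth
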