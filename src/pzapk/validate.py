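"""External validation, comparator-model registry, Bayesian forecasting and
PK/PD target attainment.

Prediction errors compare predicted with observed concentrations on a test
set disjoint from model development:

    MPE = sum(C_pred - C_obs) / N        (bias, ug/mL)
    APE = sum(|C_pred - C_obs|) / N      (imprecision, ug/mL)

``mode="population"`` predicts with eta = 0; ``mode="individual"`` first
estimates each subject's empirical-Bayes eta from their own observations
(MAP Bayesian step) and predicts at that eta.  Note the individual mode
reuses the same sparse observations for both the MAP step and the error
computation; both modes are therefore always reported side by side.

Bayesian forecasting converts the MAP individual clearance into steady-state
exposure at a normalisation dose (AUC_0-24 = D/CL_i; Cmax by numerical peak
search), and target attainment scores the exposures against the commonly
used pyrazinamide efficacy thresholds AUC_0-24 >= 363 ug*h/mL and
Cmax >= 30 ug/mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data import SubjectRecord
from .foce import FoceEngine
from .modelspec import ModelSpec, ParamSet, final_model_spec
from .pk import DosingRegimen, IndividualPK, PopulationParameters, auc_0_24_ss, cmax_ss

__all__ = [
    "ValidationSummary",
    "ExposureEstimate",
    "ModelRegistry",
    "mpe",
    "ape",
    "prediction_records",
    "external_validate",
    "forecast_individual",
    "forecast_cohort",
    "target_attainment",
    "subgroup_summary",
    "subgroup_label",
]

AUC_TARGET = 363.0  # ug*h/mL
CMAX_TARGET = 30.0  # ug/mL


def _errors(records) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        return (records["pred"] - records["obs"]).to_numpy(dtype=float)
    arr = np.asarray(records, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:  # (pred, obs) pairs
        return arr[:, 0] - arr[:, 1]
    raise TypeError("records must be a DataFrame with pred/obs or an (N,2) array")


def mpe(records) -> float:
    """Mean prediction error sum(C_pred - C_obs)/N (signed bias, ug/mL)."""
    e = _errors(records)
    if e.size == 0:
        raise ValueError("MPE needs at least one record")
    return float(e.mean())


def ape(records) -> float:
    """Absolute prediction error sum(|C_pred - C_obs|)/N; always >= |MPE|."""
    e = _errors(records)
    if e.size == 0:
        raise ValueError("APE needs at least one record")
    return float(np.abs(e).mean())


@dataclass(frozen=True)
class ValidationSummary:
    """MPE/APE with nonparametric intervals for one model and mode."""

    label: str
    mode: str
    mpe: float
    mpe_ci: tuple[float, float]  # 2.5-97.5 percentile of per-observation errors
    mpe_range: tuple[float, float]  # min-max of per-observation errors
    ape: float
    ape_ci: tuple[float, float]
    ape_range: tuple[float, float]
    n: int

    def as_row(self) -> dict:
        return {
            "model": self.label,
            "mode": self.mode,
            "MPE": self.mpe,
            "MPE_ci_low": self.mpe_ci[0],
            "MPE_ci_high": self.mpe_ci[1],
            "APE": self.ape,
            "APE_ci_low": self.ape_ci[0],
            "APE_ci_high": self.ape_ci[1],
            "N": self.n,
        }


def prediction_records(
    subjects: Sequence[SubjectRecord],
    spec: ModelSpec,
    params: ParamSet,
    mode: str = "population",
) -> pd.DataFrame:
    """Paired predicted/observed concentrations for every observation."""
    eng = FoceEngine(list(subjects), spec)
    if mode == "population":
        pred = eng.predict(params, None)
    elif mode == "individual":
        eta, _ = eng.eta_modes(params, eta0=np.zeros((eng.n_sub, 3)))
        pred = eng.predict(params, eta)
    else:
        raise ValueError("mode must be 'population' or 'individual'")
    ids = np.array([s.id for s in subjects])
    return pd.DataFrame(
        {"id": ids[eng.isub], "time": eng.t, "obs": eng.y, "pred": pred, "mode": mode}
    )


def external_validate(
    test_subjects: Sequence[SubjectRecord],
    params: ParamSet | PopulationParameters,
    spec: ModelSpec | None = None,
    mode: str = "population",
    label: str = "final",
) -> ValidationSummary:
    """MPE/APE of a model on an external test set under one prediction mode."""
    if isinstance(params, PopulationParameters):
        spec = spec or final_model_spec(params)
        params = spec.paramset_from_population(params)
    elif spec is None:
        raise ValueError("spec is required when params is a ParamSet")
    rec = prediction_records(test_subjects, spec, params, mode=mode)
    e = (rec["pred"] - rec["obs"]).to_numpy()
    a = np.abs(e)
    return ValidationSummary(
        label=label,
        mode=mode,
        mpe=float(e.mean()),
        mpe_ci=(float(np.percentile(e, 2.5)), float(np.percentile(e, 97.5))),
        mpe_range=(float(e.min()), float(e.max())),
        ape=float(a.mean()),
        ape_ci=(float(np.percentile(a, 2.5)), float(np.percentile(a, 97.5))),
        ape_range=(float(a.min()), float(a.max())),
        n=int(e.size),
    )


class ModelRegistry:
    """Named comparator population models for side-by-side validation.

    Comparator parameter sets are user-supplied (e.g. from the literature);
    none are hard-coded.  The registry round-trips through YAML.
    """

    def __init__(self) -> None:
        self._models: dict[str, PopulationParameters] = {}

    def register(self, label: str, params: PopulationParameters) -> None:
        if label in self._models:
            raise KeyError(f"duplicate model label {label!r}")
        self._models[label] = params

    def __getitem__(self, label: str) -> PopulationParameters:
        return self._models[label]

    def __contains__(self, label: str) -> bool:
        return label in self._models

    def labels(self) -> list[str]:
        return list(self._models)

    def validate_all(
        self, test_subjects: Sequence[SubjectRecord], modes: Sequence[str] = ("population", "individual")
    ) -> pd.DataFrame:
        """Table of MPE/APE per registered model and prediction mode."""
        rows = []
        for label, pp in self._models.items():
            for mode in modes:
                rows.append(external_validate(test_subjects, pp, mode=mode, label=label).as_row())
        return pd.DataFrame(rows)

    def to_yaml(self, path) -> None:
        payload = {
            label: {
                "theta_cl": pp.theta_cl,
                "theta_gdm_cl": pp.theta_gdm_cl,
                "theta_v": pp.theta_v,
                "theta_ka": pp.theta_ka,
                "omega_cl": pp.omega_cl,
                "omega_v": pp.omega_v,
                "omega_ka": pp.omega_ka,
                "sigma_add": pp.sigma_add,
                "allometric_ref": pp.allometric_ref,
            }
            for label, pp in self._models.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelRegistry":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        reg = cls()
        for label, kw in payload.items():
            reg.register(label, PopulationParameters(**kw))
        return reg


# ---------------------------------------------------------------------------
# Bayesian forecasting and target attainment
# ---------------------------------------------------------------------------


def subgroup_label(age: float, dm: bool, cutoff: float = 70.0) -> str:
    return f"{'>=70' if age >= cutoff else '<70'}/{'DM' if dm else 'noDM'}"


@dataclass(frozen=True)
class ExposureEstimate:
    """MAP-forecast steady-state exposure for one subject."""

    subject_id: str
    auc_0_24: float  # ug*h/mL at the normalisation dose
    cmax: float  # ug/mL at the normalisation dose
    cl: float  # individual apparent clearance (L/h)
    normalization_dose: float
    subgroup: str


def forecast_individual(
    subject: SubjectRecord,
    params: ParamSet | PopulationParameters,
    spec: ModelSpec | None = None,
    normalization_dose: float = 1200.0,
) -> ExposureEstimate:
    """MAP Bayesian forecast of AUC_0-24 and Cmax at a normalisation dose.

    The subject's empirical-Bayes eta is estimated from their own
    observations; ``AUC_0-24 = dose / CL_i`` and Cmax comes from the peak of
    the individual steady-state profile at the normalisation dose.
    """
    if len(subject.observations) < 1:
        raise ValueError("forecasting needs at least one observation")
    if isinstance(params, PopulationParameters):
        spec = spec or final_model_spec(params)
        params = spec.paramset_from_population(params)
    elif spec is None:
        raise ValueError("spec is required when params is a ParamSet")
    eng = FoceEngine([subject], spec)
    eta, _ = eng.eta_modes(params, eta0=np.zeros((1, 3)))
    cl, v, ka = eng.individual_params(params, eta)
    pk = IndividualPK(cl=float(cl[0]), v=float(v[0]), ka=float(ka[0]),
                      eta=tuple(float(e) for e in eta[0]))
    reg = DosingRegimen(dose=normalization_dose, tau=subject.regimen.tau)
    cmax, _tmax = cmax_ss(pk, reg)
    return ExposureEstimate(
        subject_id=subject.id,
        auc_0_24=auc_0_24_ss(pk, reg),
        cmax=cmax,
        cl=pk.cl,
        normalization_dose=normalization_dose,
        subgroup=subgroup_label(subject.covariates.age, subject.covariates.dm),
    )


def forecast_cohort(
    subjects: Sequence[SubjectRecord],
    params: ParamSet | PopulationParameters,
    spec: ModelSpec | None = None,
    normalization_dose: float = 1200.0,
) -> pd.DataFrame:
    """Vectorised MAP forecast for a cohort; one row per subject."""
    if isinstance(params, PopulationParameters):
        spec = spec or final_model_spec(params)
        ps = spec.paramset_from_population(params)
    else:
        if spec is None:
            raise ValueError("spec is required when params is a ParamSet")
        ps = params
    subjects = list(subjects)
    eng = FoceEngine(subjects, spec)
    eta, _ = eng.eta_modes(ps, eta0=np.zeros((eng.n_sub, 3)))
    cl, v, ka = eng.individual_params(ps, eta)
    rows = []
    for i, s in enumerate(subjects):
        pk = IndividualPK(cl=float(cl[i]), v=float(v[i]), ka=float(ka[i]))
        reg = DosingRegimen(dose=normalization_dose, tau=s.regimen.tau)
        cmax, _ = cmax_ss(pk, reg)
        rows.append(
            {
                "id": s.id,
                "auc_0_24": auc_0_24_ss(pk, reg),
                "cmax": cmax,
                "cl": pk.cl,
                "normalization_dose": normalization_dose,
                "subgroup": subgroup_label(s.covariates.age, s.covariates.dm),
            }
        )
    return pd.DataFrame(rows)


def target_attainment(
    estimates: pd.DataFrame,
    auc_target: float = AUC_TARGET,
    cmax_target: float = CMAX_TARGET,
) -> pd.Series:
    """Fractions of subjects meeting the AUC, Cmax and joint efficacy targets
    (inclusive thresholds)."""
    if len(estimates) == 0:
        raise ValueError("target attainment needs at least one exposure estimate")
    auc_ok = estimates["auc_0_24"] >= auc_target
    cmax_ok = estimates["cmax"] >= cmax_target
    return pd.Series(
        {
            "auc": float(auc_ok.mean()),
            "cmax": float(cmax_ok.mean()),
            "both": float((auc_ok & cmax_ok).mean()),
        }
    )


def subgroup_summary(estimates: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of AUC/Cmax/CL by the four age-by-DM subgroups."""
    if "subgroup" not in estimates.columns:
        raise ValueError("estimates must carry a 'subgroup' column")
    rows = []
    for label, grp in estimates.groupby("subgroup"):
        row = {"subgroup": label, "n": len(grp)}
        for col in ("auc_0_24", "cmax", "cl"):
            q1, med, q3 = grp[col].quantile([0.25, 0.5, 0.75])
            row[f"{col}_median"] = med
            row[f"{col}_q1"] = q1
            row[f"{col}_q3"] = q3
        rows.append(row)
    return pd.DataFrame(rows).set_index("subgroup")
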