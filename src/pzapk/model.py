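"""Model and Results objects for population PK estimation.

:class:`PopPKModel` binds a dataset of :class:`~pzapk.data.SubjectRecord`
to a :class:`~pzapk.modelspec.ModelSpec` and exposes ``fit()``;
:class:`PopPKResults` carries the estimates, their uncertainties, the
empirical-Bayes etas, shrinkage and a ``summary()`` table, in the style of
statsmodels results objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import SubjectRecord, frame_to_subjects
from .foce import FoceEngine, eta_shrinkage
from .modelspec import ETA_NAMES, ModelSpec, ParamSet, final_model_spec
from .pk import cv_percent_from_omega

__all__ = ["PopPKModel", "PopPKResults", "fit_population"]


class PopPKModel:
    """One-compartment oral steady-state population PK model (FOCE-I).

    Parameters
    ----------
    subjects : sequence of SubjectRecord
        Modelling dataset; every subject needs at least one observation.
        BLQ imputation (:func:`pzapk.data.impute_blq`) is the caller's
        explicit preprocessing step.
    spec : ModelSpec, optional
        Estimation specification; defaults to the final covariate model
        (allometric lean-body-weight scaling + geriatric-DM effect on CL).
    """

    def __init__(self, subjects: Sequence[SubjectRecord], spec: ModelSpec | None = None):
        self.spec = spec if spec is not None else final_model_spec()
        self.subjects = list(subjects)
        self.engine = FoceEngine(self.subjects, self.spec)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec | None = None) -> "PopPKModel":
        """Build the model from a long-format dataset frame."""
        return cls(frame_to_subjects(df), spec=spec)

    @property
    def n_subjects(self) -> int:
        return self.engine.n_sub

    @property
    def n_observations(self) -> int:
        return self.engine.n_obs

    def ofv(self, params: ParamSet) -> float:
        """FOCE-I objective function value at the given parameters."""
        return self.engine.ofv(params)

    def fit(
        self,
        start: Mapping[str, float] | ParamSet | None = None,
        compute_se: bool = True,
        maxiter: int = 300,
        prefit: bool = True,
    ) -> "PopPKResults":
        """Estimate the population parameters by FOCE-I.

        ``start`` overrides the spec's initial values (keys like
        ``theta_cl``, ``omega_ka``, ``sigma``) or supplies a full ParamSet;
        ``prefit`` runs the pooled least-squares stage first.
        """
        res, ps, eta, ofv, n_fail = self.engine.minimize(inits=start, maxiter=maxiter,
                                                         prefit=prefit)
        # L-BFGS-B reports an abnormal line search when it reaches the
        # numerical noise floor of the FOCE objective at the optimum; the
        # returned point is still the best found, so only iteration-limit
        # terminations count as failures.
        optimizer_ok = bool(res.success) or str(res.message).startswith("ABNORMAL")
        converged = optimizer_ok and np.isfinite(ofv) and n_fail <= max(1, 0.01 * self.n_subjects)
        se = self.engine.standard_errors(ps) if compute_se else None
        estimates = self.engine.paramset_as_free_series(ps)
        rse = None
        if se is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                rse = 100.0 * se / estimates.abs()
        shrink = pd.Series(
            eta_shrinkage(eta, ps.omega),
            index=[f"eta_{n}" for n in ETA_NAMES],
        )
        eta_df = pd.DataFrame(eta, columns=[f"eta_{n}" for n in ETA_NAMES],
                              index=[s.id for s in self.subjects])
        return PopPKResults(
            model=self,
            params=ps,
            estimates=estimates,
            ofv=float(ofv),
            se=se,
            rse=rse,
            ebes=eta_df,
            eta_shrinkage=shrink,
            converged=converged,
            n_inner_failures=n_fail,
            optimizer_message=str(res.message),
        )


@dataclass
class PopPKResults:
    """Estimation results: point estimates, uncertainty, EBEs, diagnostics."""

    model: PopPKModel
    params: ParamSet
    estimates: pd.Series
    ofv: float
    se: pd.Series | None
    rse: pd.Series | None
    ebes: pd.DataFrame
    eta_shrinkage: pd.Series
    converged: bool
    n_inner_failures: int
    optimizer_message: str = ""

    @property
    def n_subjects(self) -> int:
        return self.model.n_subjects

    @property
    def n_observations(self) -> int:
        return self.model.n_observations

    # -- predictions -----------------------------------------------------------

    def predict(self, mode: str = "population") -> pd.DataFrame:
        """Per-observation predictions.

        ``mode="population"`` uses eta = 0 (PRED); ``mode="individual"`` uses
        each subject's empirical-Bayes eta (IPRED).
        """
        eng = self.model.engine
        if mode == "population":
            pred = eng.predict(self.params, None)
        elif mode == "individual":
            pred = eng.predict(self.params, self.ebes.to_numpy())
        else:
            raise ValueError("mode must be 'population' or 'individual'")
        ids = np.array([s.id for s in self.model.subjects])
        return pd.DataFrame(
            {
                "id": ids[eng.isub],
                "time": eng.t,
                "obs": eng.y,
                "pred": pred,
                "mode": mode,
            }
        )

    def individual_parameters(self) -> pd.DataFrame:
        """Empirical-Bayes individual (CL/F, Vd/F, Ka) per subject."""
        cl, v, ka = self.model.engine.individual_params(self.params, self.ebes.to_numpy())
        return pd.DataFrame(
            {"cl": cl, "v": v, "ka": ka}, index=self.ebes.index
        )

    # -- reporting ---------------------------------------------------------------

    def summary(self) -> str:
        """Human-readable estimation report (typical values, %RSE, IIV %CV
        with shrinkage, residual SD, OFV)."""
        lines = []
        w = 74
        lines.append("=" * w)
        lines.append("Population PK estimation (one-compartment oral, steady state, FOCE-I)")
        lines.append("=" * w)
        lines.append(
            f"Subjects: {self.n_subjects}    Observations: {self.n_observations}    "
            f"Converged: {self.converged}"
        )
        lines.append(f"OFV: {self.ofv:.3f}")
        lines.append("-" * w)
        lines.append(f"{'Parameter':<28}{'Estimate':>12}{'SE':>12}{'%RSE':>10}")
        for name in self.estimates.index:
            est = self.estimates[name]
            se = self.se[name] if self.se is not None else np.nan
            rse = self.rse[name] if self.rse is not None else np.nan
            lines.append(
                f"{name:<28}{est:>12.4g}{se:>12.3g}{rse:>10.1f}"
            )
        lines.append("-" * w)
        lines.append("Interindividual variability (log-normal, diagonal)")
        for i, n in enumerate(ETA_NAMES):
            om = self.params.omega[i]
            fixed = " (FIX)" if n in self.model.spec.omega_fixed else ""
            lines.append(
                f"  omega_{n:<4} sd={om:.4g}{fixed}  CV%={cv_percent_from_omega(om):.3g}  "
                f"shrinkage%={self.eta_shrinkage[f'eta_{n}']:.1f}"
            )
        lines.append(f"Additive residual SD (ug/mL): {self.params.sigma:.4g}")
        lines.append("=" * w)
        return "\n".join(lines)

    def to_payload(self) -> dict:
        """JSON-serialisable record sufficient to reproduce predictions."""
        return {
            "estimates": self.estimates.to_dict(),
            "omega": {n: float(self.params.omega[i]) for i, n in enumerate(ETA_NAMES)},
            "sigma": float(self.params.sigma),
            "ofv": self.ofv,
            "se": None if self.se is None else {k: _f(v) for k, v in self.se.items()},
            "rse": None if self.rse is None else {k: _f(v) for k, v in self.rse.items()},
            "eta_shrinkage": {k: _f(v) for k, v in self.eta_shrinkage.items()},
            "converged": self.converged,
            "n_subjects": self.n_subjects,
            "n_observations": self.n_observations,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_payload(), fh, indent=2)


def _f(v):
    return None if v is None or (isinstance(v, float) and not np.isfinite(v)) else float(v)


def fit_population(
    subjects: Sequence[SubjectRecord],
    spec: ModelSpec | None = None,
    inits: Mapping[str, float] | None = None,
    **fit_kwargs,
) -> PopPKResults:
    """Functional wrapper: build a :class:`PopPKModel` and fit it."""
    return PopPKModel(subjects, spec=spec).fit(start=inits, **fit_kwargs)


def paramset_from_payload(spec: ModelSpec, payload: Mapping) -> ParamSet:
    """Rebuild a :class:`ParamSet` from a saved results payload."""
    est = payload["estimates"]
    inits = {k: v for k, v in est.items()}
    return spec.initial_paramset(inits)
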