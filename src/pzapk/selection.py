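"""Likelihood-ratio covariate model selection.

Forward selection followed by backward elimination over candidate
covariate-parameter pairs, each tested one at a time (one covariate on one
PK parameter per step).  A forward step is accepted when the OFV drops by
at least the threshold (3.84 for the first entry, chi2(1) at p<0.05;
6.63 thereafter, p<0.01); a retained covariate survives backward
elimination only if removing it raises the OFV by at least 6.63.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .data import SubjectRecord
from .model import fit_population
from .modelspec import CovariateEffect, ModelSpec

__all__ = [
    "CovariateCandidate",
    "SelectionStep",
    "SelectionTrace",
    "lrt_decision",
    "stepwise_search",
    "compare_body_size_predictors",
]


@dataclass(frozen=True)
class CovariateCandidate:
    """A covariate-parameter pair to be tested (power or categorical form)."""

    name: str
    parameter: str  # "cl" | "v" | "ka"
    kind: str  # "power" | "categorical"
    column: str  # covariate column, incl. derived ones like "gdm70"
    reference: float = 1.0
    init: float = 0.1

    def as_effect(self) -> CovariateEffect:
        return CovariateEffect(
            name=self.name, parameter=self.parameter, kind=self.kind,
            column=self.column, reference=self.reference, init=self.init,
        )


@dataclass(frozen=True)
class SelectionStep:
    candidate: str
    delta_ofv: float
    decision: str  # "accepted" | "rejected" | "removed" | "retained" | "failed"
    phase: str  # "forward" | "backward"


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    final_spec: ModelSpec | None = None
    base_ofv: float = float("nan")
    final_ofv: float = float("nan")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])


def lrt_decision(ofv_reduced: float, ofv_full: float, threshold: float = 3.84) -> bool:
    """Accept the fuller (1 extra df) model iff the OFV drop meets the
    threshold (inclusive)."""
    return (ofv_reduced - ofv_full) >= threshold


def stepwise_search(
    subjects: Sequence[SubjectRecord],
    base_spec: ModelSpec,
    candidates: Sequence[CovariateCandidate],
    forward_first: float = 3.84,
    forward_later: float = 6.63,
    backward: float = 6.63,
    fit_kwargs: dict | None = None,
) -> SelectionTrace:
    """Forward-selection / backward-elimination covariate search.

    Deterministic given the data and candidate ordering (ties broken by
    listed order).  Candidates whose fit raises are skipped with a warning.
    """
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("compute_se", False)
    trace = SelectionTrace()

    base_fit = fit_population(list(subjects), base_spec, **fit_kwargs)
    trace.base_ofv = base_fit.ofv
    current_spec = base_spec
    current_ofv = base_fit.ofv
    remaining = list(candidates)
    included: list[CovariateCandidate] = []

    # forward pass
    while remaining:
        threshold = forward_first if not included else forward_later
        drops = []
        for cand in remaining:
            try:
                fit = fit_population(list(subjects), current_spec.with_effect(cand.as_effect()),
                                     **fit_kwargs)
                drops.append((cand, current_ofv - fit.ofv, fit.ofv))
            except Exception as exc:  # noqa: BLE001 - candidate failure is survivable
                warnings.warn(f"candidate {cand.name} failed to fit: {exc}", RuntimeWarning)
                trace.steps.append(SelectionStep(cand.name, float("nan"), "failed", "forward"))
        if not drops:
            break
        best, best_drop, best_ofv = max(drops, key=lambda d: d[1])
        for cand, drop, _ in drops:
            if cand is not best:
                trace.steps.append(SelectionStep(cand.name, drop, "rejected", "forward"))
        if lrt_decision(current_ofv, best_ofv, threshold):
            trace.steps.append(SelectionStep(best.name, best_drop, "accepted", "forward"))
            current_spec = current_spec.with_effect(best.as_effect())
            current_ofv = best_ofv
            included.append(best)
            remaining = [c for c in remaining if c is not best]
        else:
            trace.steps.append(SelectionStep(best.name, best_drop, "rejected", "forward"))
            break

    # backward pass: drop the weakest covariate while its removal costs < threshold
    changed = True
    while changed and included:
        changed = False
        rises = []
        for cand in included:
            try:
                fit = fit_population(list(subjects), current_spec.without_effect(cand.name),
                                     **fit_kwargs)
                rises.append((cand, fit.ofv - current_ofv, fit.ofv))
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"backward refit without {cand.name} failed: {exc}", RuntimeWarning)
        if not rises:
            break
        weakest, rise, ofv_without = min(rises, key=lambda d: d[1])
        if rise < backward:
            trace.steps.append(SelectionStep(weakest.name, rise, "removed", "backward"))
            current_spec = current_spec.without_effect(weakest.name)
            current_ofv = ofv_without
            included = [c for c in included if c is not weakest]
            changed = True
        else:
            for cand, r, _ in rises:
                trace.steps.append(SelectionStep(cand.name, r, "retained", "backward"))

    trace.selected = [c.name for c in included]
    trace.final_spec = current_spec
    trace.final_ofv = current_ofv
    return trace


def compare_body_size_predictors(
    subjects: Sequence[SubjectRecord],
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """OFV drop from adding fixed-exponent allometric scaling (0.75 on CL,
    1.0 on V) by lean body weight versus total body weight, each against the
    covariate-free base model.  The larger drop marks the preferred body-size
    predictor."""
    from .modelspec import base_model_spec

    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("compute_se", False)
    no_size = base_model_spec(allometry=None)
    base_fit = fit_population(list(subjects), no_size, **fit_kwargs)
    rows = {}
    for label, col in (("lean_body_weight", "LBW"), ("body_weight", "WT")):
        spec = base_model_spec(allometry=col)
        fit = fit_population(list(subjects), spec, **fit_kwargs)
        rows[label] = {"ofv": fit.ofv, "delta_ofv": base_fit.ofv - fit.ofv}
    table = pd.DataFrame(rows).T
    table["selected"] = table["delta_ofv"] == table["delta_ofv"].max()
    table.attrs["base_ofv"] = base_fit.ofv
    return table
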