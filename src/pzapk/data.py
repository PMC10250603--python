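"""Subject records and the long-format concentration-time dataset.

The on-disk dialect follows NONMEM conventions: comma-separated, one row per
dose event (``EVID=1``) or observation (``EVID=0``), missing values written
as ``"."``.  Covariates are repeated on every row of a subject.

Below-quantification-limit (BLQ) handling is a separate, explicit step:
``read_dataset`` keeps raw sub-LLOQ values with their BLQ flag, and
``impute_blq`` applies Beal's M5 rule (replace by LLOQ/2 and treat as an
ordinary observation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .pk import CovariateSet, DosingRegimen

__all__ = [
    "LLOQ",
    "Observation",
    "SubjectRecord",
    "impute_blq",
    "read_dataset",
    "write_dataset",
    "subjects_to_frame",
    "frame_to_subjects",
]

#: Lower limit of quantification of the plasma assay (ug/mL).
LLOQ = 2.0

MANDATORY_COLUMNS = ["ID", "TIME", "DV", "AMT", "EVID", "BLQ"]
COVARIATE_COLUMNS = {
    "AGE": "age",
    "SEX": "sex",
    "WT": "body_weight",
    "LBW": "lean_body_weight",
    "DM": "dm",
    "FED": "feeding",
    "RENAL": "renal_disease",
    "LIVER": "liver_disease",
    "ALB": "albumin",
    "TBIL": "total_bilirubin",
    "AST": "ast",
    "ALT": "alt",
}


class DataError(ValueError):
    """Raised for malformed or inconsistent datasets."""


class Observation(NamedTuple):
    time: float
    conc: float
    blq: bool = False
    imputed: bool = False


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: covariates, dosing regimen and observation rows."""

    id: str
    covariates: CovariateSet
    regimen: DosingRegimen
    observations: tuple[Observation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for obs in self.observations:
            if obs.time < 0 or obs.time > self.regimen.tau:
                raise DataError(
                    f"subject {self.id}: observation time {obs.time} outside [0, tau={self.regimen.tau}]"
                )
            if obs.conc < 0:
                raise DataError(f"subject {self.id}: negative concentration {obs.conc}")

    def with_observations(self, observations: Iterable[Observation]) -> "SubjectRecord":
        return replace(self, observations=tuple(observations))


def impute_blq(subjects_or_obs, lloq: float = LLOQ):
    """Apply Beal's M5 imputation: concentrations below ``lloq`` become ``lloq/2``.

    Accepts a list of :class:`SubjectRecord`, a list of :class:`Observation`
    or a long-format :class:`pandas.DataFrame`; returns the same kind of
    object with sub-LLOQ rows replaced by ``lloq/2`` and flagged as imputed.
    Rows at or above the LLOQ are untouched.
    """
    if lloq <= 0:
        raise ValueError("lloq must be positive")

    if isinstance(subjects_or_obs, pd.DataFrame):
        df = subjects_or_obs.copy()
        obs_mask = df["EVID"] == 0
        if (df.loc[obs_mask, "DV"] < 0).any():
            raise DataError("negative concentrations in dataset")
        below = obs_mask & (df["DV"] < lloq)
        df.loc[below, "DV"] = lloq / 2.0
        df.loc[below, "BLQ"] = 1
        if "IMPUTED" not in df.columns:
            df["IMPUTED"] = 0
        df.loc[below, "IMPUTED"] = 1
        return df

    items = list(subjects_or_obs)
    if items and isinstance(items[0], SubjectRecord):
        return [s.with_observations(impute_blq(list(s.observations), lloq)) for s in items]

    out = []
    for obs in items:
        if obs.conc < 0:
            raise DataError(f"negative concentration {obs.conc}")
        if obs.conc < lloq:
            out.append(Observation(obs.time, lloq / 2.0, blq=True, imputed=True))
        else:
            out.append(obs)
    return out


# ---------------------------------------------------------------------------
# Long-format frame <-> subjects
# ---------------------------------------------------------------------------


def subjects_to_frame(subjects: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Serialise subjects into the long-format dataset (one dose row + obs rows)."""
    rows = []
    for s in subjects:
        cov = s.covariates
        base = {
            "ID": s.id,
            "AGE": cov.age,
            "SEX": cov.sex,
            "WT": cov.body_weight,
            "LBW": cov.lean_body_weight,
            "DM": int(cov.dm),
            "FED": int(cov.feeding == "fed"),
            "RENAL": int(cov.renal_disease),
            "LIVER": int(cov.liver_disease),
            "ALB": cov.albumin,
            "TBIL": cov.total_bilirubin,
            "AST": cov.ast,
            "ALT": cov.alt,
            "TAU": s.regimen.tau,
        }
        rows.append(
            dict(base, TIME=0.0, DV=np.nan, AMT=s.regimen.dose, EVID=1, BLQ=0, IMPUTED=0)
        )
        for obs in s.observations:
            rows.append(
                dict(
                    base,
                    TIME=obs.time,
                    DV=obs.conc,
                    AMT=np.nan,
                    EVID=0,
                    BLQ=int(obs.blq),
                    IMPUTED=int(obs.imputed),
                )
            )
    columns = MANDATORY_COLUMNS + ["IMPUTED", "TAU"] + list(COVARIATE_COLUMNS)
    return pd.DataFrame(rows, columns=columns)


def frame_to_subjects(df: pd.DataFrame) -> list[SubjectRecord]:
    """Reconstruct :class:`SubjectRecord` objects from a long-format frame."""
    _validate_frame(df)
    subjects = []
    for sid, grp in df.groupby("ID", sort=False):
        dose_rows = grp[grp["EVID"] == 1]
        if len(dose_rows) != 1:
            raise DataError(f"subject {sid}: expected exactly one dose row, found {len(dose_rows)}")
        dose_row = dose_rows.iloc[0]
        first = grp.iloc[0]
        cov = CovariateSet(
            age=float(first["AGE"]),
            sex=str(first["SEX"]),
            body_weight=float(first["WT"]),
            lean_body_weight=float(first["LBW"]),
            dm=bool(first["DM"]),
            feeding="fed" if int(first["FED"]) else "fasted",
            renal_disease=bool(first.get("RENAL", 0)),
            liver_disease=bool(first.get("LIVER", 0)),
            albumin=float(first.get("ALB", 4.2)),
            total_bilirubin=float(first.get("TBIL", 0.6)),
            ast=float(first.get("AST", 27.0)),
            alt=float(first.get("ALT", 19.0)),
        )
        tau = float(first["TAU"]) if "TAU" in grp.columns and np.isfinite(first["TAU"]) else 24.0
        regimen = DosingRegimen(dose=float(dose_row["AMT"]), tau=tau)
        obs = [
            Observation(
                time=float(r["TIME"]),
                conc=float(r["DV"]),
                blq=bool(r["BLQ"]),
                imputed=bool(r.get("IMPUTED", 0)),
            )
            for _, r in grp[grp["EVID"] == 0].iterrows()
        ]
        subjects.append(SubjectRecord(id=str(sid), covariates=cov, regimen=regimen, observations=tuple(obs)))
    return subjects


def _validate_frame(df: pd.DataFrame) -> None:
    if df.empty:
        raise DataError("empty dataset")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"missing mandatory column(s): {missing}")
    obs = df[df["EVID"] == 0]
    bad = obs[obs["DV"].isna()]
    if not bad.empty:
        raise DataError(f"observation row without DV at index {bad.index[0]}")
    neg = obs[obs["DV"] < 0]
    if not neg.empty:
        raise DataError(f"negative concentration at index {neg.index[0]}")


def read_dataset(path) -> pd.DataFrame:
    """Read a long-format dataset (CSV, ``"."`` for missing) and validate it."""
    df = pd.read_csv(path, na_values=["."], keep_default_na=True)
    _validate_frame(df)
    return df


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a long-format dataset as CSV with ``"."`` for missing values."""
    df.to_csv(path, index=False, na_rep=".")
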