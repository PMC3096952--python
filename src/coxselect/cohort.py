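"""Survival cohort container and endpoint preparation.

A :class:`SurvivalCohort` bundles a per-patient covariate table with
follow-up time (years), a cause-specific event indicator (1 = death from
disease, 0 = censored) and optional side-columns (strata fields such as raw
tumor size or receptor status) that travel with the patients but are not
modeling variables.

Endpoint preparation follows the administrative-censoring convention for a
fixed-horizon endpoint: follow-up beyond the horizon is truncated to the
horizon and the event indicator cleared; events occurring exactly at the
horizon are kept as events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["SurvivalCohort", "prepare_endpoint", "binarize_age"]


@dataclass
class SurvivalCohort:
    """Patient x variable covariate matrix plus survival outcome.

    Parameters
    ----------
    data
        Covariate table, one row per patient, one column per modeling
        variable.  Values must be numeric with no missing entries (apply a
        complete-case filter before constructing; see :func:`coxselect.io.read_cohort`).
    time
        Follow-up in years, strictly positive.
    event
        1 for an observed disease-specific death, 0 for censoring.
    strata
        Optional extra columns aligned with ``data`` (e.g. NPI components),
        never used as modeling variables.
    """

    data: pd.DataFrame
    time: np.ndarray
    event: np.ndarray
    strata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.data.shape[0] != self.time.shape[0] or self.time.shape[0] != self.event.shape[0]:
            raise ValidationError("data, time and event must have equal length")
        if len(set(self.data.columns)) != self.data.shape[1]:
            raise ValidationError("variable_names must be unique")
        if self.data.isna().any().any():
            raise ValidationError("covariate table contains missing values; apply complete-case filtering first")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValidationError("time must be finite and strictly positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event must be 0 or 1")
        self.event = self.event.astype(np.int64)
        if self.strata is not None:
            self.strata = self.strata.reset_index(drop=True)
            if self.strata.shape[0] != self.n_patients:
                raise ValidationError("strata table must align with data rows")

    # -- basic views ------------------------------------------------------

    @property
    def n_patients(self) -> int:
        return self.data.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def variable_names(self) -> list[str]:
        return list(self.data.columns)

    def matrix(self, variables: list[str] | None = None) -> np.ndarray:
        """Covariate values as a float array, optionally for a subset."""
        df = self.data if variables is None else self.data[list(variables)]
        return df.to_numpy(dtype=float)

    # -- subsetting -------------------------------------------------------

    def take(self, idx) -> "SurvivalCohort":
        """Row subset by positional index; preserves alignment of strata."""
        idx = np.asarray(idx)
        return SurvivalCohort(
            data=self.data.iloc[idx],
            time=self.time[idx],
            event=self.event[idx],
            strata=None if self.strata is None else self.strata.iloc[idx],
        )

    def select_variables(self, variables: list[str]) -> "SurvivalCohort":
        missing = [v for v in variables if v not in self.data.columns]
        if missing:
            raise ValidationError(f"variables not in cohort: {missing}")
        return SurvivalCohort(
            data=self.data[list(variables)],
            time=self.time,
            event=self.event,
            strata=self.strata,
        )

    def to_frame(self) -> pd.DataFrame:
        """Single table: covariates (+ strata) + time_years + event."""
        out = self.data.copy()
        if self.strata is not None:
            for c in self.strata.columns:
                if c not in out.columns:
                    out[c] = self.strata[c].to_numpy()
        out["time_years"] = self.time
        out["event"] = self.event
        return out


def prepare_endpoint(cohort: SurvivalCohort, horizon_years: float) -> SurvivalCohort:
    """Administratively censor follow-up at a fixed horizon.

    Patients followed beyond ``horizon_years`` get time set to the horizon
    and event set to 0.  Events at exactly the horizon are kept.  Returns a
    new cohort; the input is not mutated.  Idempotent.
    """
    if not np.isfinite(horizon_years) or horizon_years <= 0:
        raise ValidationError("horizon_years must be positive")
    beyond = cohort.time > horizon_years
    time = np.where(beyond, horizon_years, cohort.time)
    event = np.where(beyond, 0, cohort.event)
    return SurvivalCohort(cohort.data.copy(), time, event,
                          None if cohort.strata is None else cohort.strata.copy())


def binarize_age(cohort: SurvivalCohort, cutoff: float = 50.0,
                 column: str = "age") -> SurvivalCohort:
    """Replace age in years by the indicator ``age < cutoff``.

    Young age at diagnosis is the adverse category in breast cancer, hence
    the "<" orientation (variable reads "age < 50 years").
    """
    if column not in cohort.data.columns:
        raise ValidationError(f"column {column!r} not present in cohort")
    data = cohort.data.copy()
    data[column] = (data[column] < cutoff).astype(float)
    return SurvivalCohort(data, cohort.time.copy(), cohort.event.copy(),
                          None if cohort.strata is None else cohort.strata.copy())
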