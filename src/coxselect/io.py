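"""Cohort file I/O, run configuration and report writing.

Cohorts travel as plain CSV (comma-separated, UTF-8, header row, ``.``
decimal): one row per patient, covariate columns plus ``time_years`` and
``event``.  A :class:`RunConfig` names the column roles and the variable
set; configs are YAML (JSON being a YAML subset, both parse).

Reports are deterministic CSV/JSON twins of the usual figure panels:
score distributions, reduced-model size distribution, stability tables
(frequency-based and ATD-weighted) and the final model, plus a manifest
capturing config, seed and package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import SurvivalCohort
from .errors import ValidationError
from .nested_cv import CVSummary

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_cohort", "write_cohort", "write_reports",
           "load_config", "VARIABLE_SETS"]

# the three model families: all 18 variables, the 14 protein markers alone,
# or the 7 clinico-pathological variables alone
VARIABLE_SETS = {
    "combined": ["AURKA", "BAG1", "BCL2", "BIRC5", "CCNB1", "CD68", "GRB7",
                 "GSTM1", "KI67", "MMP11", "MYBL2", "ER", "PR", "HER2",
                 "nodal_status", "tumor_size", "nuclear_grade", "age"],
    "proteins_only": ["AURKA", "BAG1", "BCL2", "BIRC5", "CCNB1", "CD68", "GRB7",
                      "GSTM1", "KI67", "MMP11", "MYBL2", "ER", "PR", "HER2"],
    "clinical_only": ["nodal_status", "tumor_size", "nuclear_grade", "age",
                      "ER", "PR", "HER2"],
}


@dataclass
class RunConfig:
    """Column roles and analysis settings for a pipeline run."""

    time_column: str = "time_years"
    event_column: str = "event"
    variable_set: str | list[str] = "combined"
    strata_columns: list[str] = field(default_factory=list)
    horizon_years: float = 15.0
    age_column: str | None = "age"
    age_cutoff: float = 50.0
    n_repeats: int = 100
    ties: str = "strict"
    seed: int = 0

    def variables(self) -> list[str]:
        if isinstance(self.variable_set, str):
            if self.variable_set not in VARIABLE_SETS:
                raise ValidationError(
                    f"unknown variable set {self.variable_set!r}; "
                    f"expected one of {sorted(VARIABLE_SETS)} or an explicit list")
            return list(VARIABLE_SETS[self.variable_set])
        if not self.variable_set:
            raise ValidationError("variable set must be non-empty")
        return list(self.variable_set)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def read_cohort(path, config: RunConfig | None = None) -> SurvivalCohort:
    """Read a cohort CSV, applying a complete-case filter over the used
    columns (the count of dropped rows is logged)."""
    config = config or RunConfig()
    df = pd.read_csv(path)
    variables = config.variables()
    needed = [config.time_column, config.event_column] + variables + list(config.strata_columns)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns in {path}: {missing}")
    before = len(df)
    df = df.dropna(subset=[config.time_column, config.event_column] + variables
                   + list(config.strata_columns))
    dropped = before - len(df)
    if dropped:
        logger.warning("complete-case filter dropped %d of %d rows", dropped, before)
    if not len(df):
        raise ValidationError(f"no usable rows in {path} after complete-case filtering")
    try:
        data = df[variables].astype(float)
        time = df[config.time_column].to_numpy(dtype=float)
        event = df[config.event_column].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"unparseable numeric values in {path}: {exc}") from exc
    strata = df[list(config.strata_columns)] if config.strata_columns else None
    return SurvivalCohort(data=data, time=time, event=event.astype(int), strata=strata)


def write_cohort(cohort: SurvivalCohort, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def _stability_frame(summary: CVSummary) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": summary.variables,
            "frequency_stability": [summary.frequency_stability[v] for v in summary.variables],
            "weighted_stability": [summary.weighted_stability[v] for v in summary.variables],
            "in_final_model": [v in summary.final_model for v in summary.variables],
        }
    )


def write_reports(summary: CVSummary, out_dir, comparisons: dict | None = None,
                  config: RunConfig | None = None) -> dict[str, Path]:
    """Write the tabular report set for one nested-CV run.

    Returns a name -> path map of the files written; output is
    byte-identical across reruns with the same inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    scores = pd.DataFrame(
        {
            "repeat_id": [r.repeat_id for r in summary.outer_records] * 2,
            "fold_id": [r.fold_id for r in summary.outer_records] * 2,
            "model": ["reduced"] * len(summary.outer_records)
            + ["full"] * len(summary.outer_records),
            "test_score": np.concatenate([summary.reduced_scores, summary.full_scores]),
            "train_score": np.concatenate(
                [summary.reduced_train_scores, summary.full_train_scores]),
        }
    )
    paths["scores"] = out / "score_distributions.csv"
    scores.to_csv(paths["scores"], index=False)

    sizes = pd.DataFrame(
        {
            "repeat_id": [r.repeat_id for r in summary.outer_records],
            "fold_id": [r.fold_id for r in summary.outer_records],
            "expected_size": [r.expected_size for r in summary.outer_records],
            "reduced_size": summary.outer_sizes,
        }
    )
    paths["sizes"] = out / "model_size_distribution.csv"
    sizes.to_csv(paths["sizes"], index=False)

    paths["stability"] = out / "stability.csv"
    _stability_frame(summary).to_csv(paths["stability"], index=False)

    final = {
        "final_model": summary.final_model,
        "final_size": summary.final_size,
        "mean_reduced_score": float(summary.reduced_scores.mean()),
        "mean_full_score": float(summary.full_scores.mean()),
        "n_outer_records": len(summary.outer_records),
        "n_skipped_outer": summary.n_skipped_outer,
        "n_repeats": summary.n_repeats,
        "seed": summary.seed,
    }
    paths["final_model"] = out / "final_model.json"
    paths["final_model"].write_text(json.dumps(final, indent=2, sort_keys=True) + "\n")

    if comparisons:
        rows = []
        for name, c in comparisons.items():
            rows.append({"comparison": name, "u_statistic": c.u_statistic,
                         "p_value": c.p_value, "n_a": c.n_a, "n_b": c.n_b,
                         "direction": c.direction})
        paths["comparisons"] = out / "comparisons.csv"
        pd.DataFrame(rows).to_csv(paths["comparisons"], index=False)

    manifest = {
        "coxselect_version": __version__,
        "seed": summary.seed,
        "n_repeats": summary.n_repeats,
        "variables": summary.variables,
        "config": None if config is None else {
            k: getattr(config, k) for k in RunConfig.__dataclass_fields__},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
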