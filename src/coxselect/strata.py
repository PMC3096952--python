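"""Cohort stratification and model-score comparison.

Provides the Nottingham Prognostic Index (NPI, Galea formula
0.2 * size_cm + grade + nodal stage), a midpoint split of the cohort at
NPI 4.4 (patients at exactly 4.4 go to the lower-risk group), selection of
the node-negative / hormone-receptor-positive subpopulation, and the
two-sided Mann-Whitney U comparison of cross-validated score
distributions.

The NPI formula itself is the standard published index; the binary nodal
status of the modeled cohorts is mapped to an NPI nodal stage
(negative -> 1, positive -> 2 by default) because the index expects a
three-level stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import SurvivalCohort
from .errors import ValidationError

__all__ = ["NPIRecord", "ComparisonResult", "compute_npi", "split_by_npi",
           "select_node_negative_hr_positive", "compare_score_distributions"]

NPI_THRESHOLD = 4.4


@dataclass
class NPIRecord:
    npi_value: float
    group: str  # "lower" (<= threshold) or "higher"


@dataclass
class ComparisonResult:
    """Two-sided Mann-Whitney U comparison of two score samples."""

    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    direction: str  # which sample has the larger mean: "a", "b" or "tie"


def compute_npi(size_cm, grade, node_stage):
    """Nottingham Prognostic Index: 0.2 * tumor size (cm) + grade + nodal stage.

    Accepts scalars or aligned arrays; grade and stage must be in 1..3.
    """
    size_cm = np.asarray(size_cm, dtype=float)
    grade = np.asarray(grade)
    node_stage = np.asarray(node_stage)
    if np.any(size_cm < 0):
        raise ValidationError("tumor size must be non-negative")
    if not np.isin(grade, (1, 2, 3)).all():
        raise ValidationError("grade must be 1, 2 or 3")
    if not np.isin(node_stage, (1, 2, 3)).all():
        raise ValidationError("node stage must be 1, 2 or 3")
    out = 0.2 * size_cm + grade.astype(float) + node_stage.astype(float)
    return float(out) if out.ndim == 0 else out


def npi_group(npi_value: float, threshold: float = NPI_THRESHOLD) -> NPIRecord:
    v = float(npi_value)
    return NPIRecord(v, "lower" if v <= threshold else "higher")


def _cohort_column(cohort: SurvivalCohort, name: str) -> np.ndarray:
    if name in cohort.data.columns:
        return cohort.data[name].to_numpy(dtype=float)
    if cohort.strata is not None and name in cohort.strata.columns:
        return cohort.strata[name].to_numpy(dtype=float)
    raise ValidationError(f"column {name!r} not present in cohort")


def split_by_npi(cohort: SurvivalCohort, threshold: float = NPI_THRESHOLD,
                 size_column: str = "tumor_size", grade_column: str = "nuclear_grade",
                 node_column: str = "nodal_status",
                 node_stage_map: dict[int, int] | None = None
                 ) -> tuple[SurvivalCohort, SurvivalCohort]:
    """Partition the cohort at an NPI threshold (boundary goes to lower).

    ``node_column`` may be a binary status (mapped to stage via
    ``node_stage_map``, default {0: 1, 1: 2}) or already a 1-3 stage.
    """
    size = _cohort_column(cohort, size_column)
    grade = _cohort_column(cohort, grade_column)
    node = _cohort_column(cohort, node_column)
    if node_stage_map is None:
        node_stage_map = {0: 1, 1: 2}
    if np.isin(node, (0, 1)).all():
        stage = np.vectorize(lambda v: node_stage_map[int(v)])(node)
    else:
        stage = node.astype(int)
    npi = compute_npi(size, grade.astype(int), stage)
    lower_mask = npi <= threshold
    lower = cohort.take(np.flatnonzero(lower_mask))
    higher = cohort.take(np.flatnonzero(~lower_mask))
    return lower, higher


def select_node_negative_hr_positive(cohort: SurvivalCohort,
                                     node_column: str = "nodal_status",
                                     er_column: str = "ER", pr_column: str = "PR"
                                     ) -> SurvivalCohort:
    """Keep node-negative patients with ER and/or PR positive (score > 0),
    and drop nodal status from the modeling variables (it is constant in
    the selected subpopulation)."""
    node = _cohort_column(cohort, node_column)
    er = _cohort_column(cohort, er_column)
    pr = _cohort_column(cohort, pr_column)
    keep = (node == 0) & ((er > 0) | (pr > 0))
    sub = cohort.take(np.flatnonzero(keep))
    if node_column in sub.data.columns:
        data = sub.data.drop(columns=[node_column])
        strata = sub.strata.copy() if sub.strata is not None else None
        # keep nodal status available as a stratum column for audit
        if strata is None:
            import pandas as pd

            strata = pd.DataFrame({node_column: sub.data[node_column].to_numpy()})
        elif node_column not in strata.columns:
            strata[node_column] = sub.data[node_column].to_numpy()
        sub = SurvivalCohort(data, sub.time, sub.event, strata)
    return sub


def compare_score_distributions(a, b) -> ComparisonResult:
    """Two-sided Mann-Whitney U test between two score distributions.

    Exact null distribution when both samples have at most 20 values,
    tie-corrected normal approximation (with continuity correction)
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both score samples must be non-empty")
    method = "exact" if (a.size <= 20 and b.size <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    ma, mb = a.mean(), b.mean()
    direction = "a" if ma > mb else ("b" if mb > ma else "tie")
    return ComparisonResult(u_statistic=float(res.statistic),
                            p_value=float(min(res.pvalue, 1.0)),
                            n_a=int(a.size), n_b=int(b.size), direction=direction)
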