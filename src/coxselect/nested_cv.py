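"""Nested cross-validation orchestration.

The full procedure: an outer 10-fold cross-validation (repeated, by
default, 100 times) estimates model performance; inside each outer
iteration an inner 10-fold cross-validation performs backward elimination
and model-size selection without ever touching the outer test fold.  From
the 10 inner reduced models we compute

* the expected model size  <n> = sum_X(h_X n_X) / sum_X(h_X)   and
* per-variable stability   <v> = sum_X(h_X U_X(v)) / sum_X(h_X),

where h_X is reduced model X's inner ATD-AUCROC, n_X its size and U_X(v)
the indicator that X contains v.  The outer iteration then trains the
round(<n>) most stable variables on the outer training set and scores both
this reduced model and the all-variable full model on the outer test fold.

Fold assignment is stratified by the event indicator ("balanced"), so
every fold carries its share of deaths; one master seed drives the whole
run through per-repeat derived seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .atd import _atd_score_fast
from .cohort import SurvivalCohort
from .cox import CoxWorkspace
from .errors import UnevaluableDataError, ValidationError
from .selection import (
    NestedModelPath,
    ReducedModelRecord,
    _eliminate_and_evaluate,
    select_reduced_model,
)

logger = logging.getLogger(__name__)

__all__ = ["FoldPlan", "InnerSummary", "OuterRecord", "CVSummary",
           "make_fold_plan", "inner_loop", "outer_iteration", "run_nested_cv",
           "expected_model_size", "stability_scores"]

N_FOLDS = 10


# ---------------------------------------------------------------------------
# fold plans


@dataclass
class FoldPlan:
    """Outer fold assignment for one repeat, plus the inner assignment of
    each outer-training set."""

    repeat_id: int
    outer_assignment: np.ndarray                    # (n,) values 0..9
    inner_assignments: dict[int, np.ndarray]        # outer fold -> (n_outer_train,)
    seed: int


def _stratified_assignment(event: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Deal patients round-robin into folds separately within events and
    censored, after shuffling, so per-fold event counts differ by at most 1."""
    assign = np.empty(len(event), dtype=np.int64)
    for value in (1, 0):
        idx = np.flatnonzero(event == value)
        idx = rng.permutation(idx)
        fold_order = rng.permutation(n_folds)
        assign[idx] = fold_order[np.arange(len(idx)) % n_folds]
    return assign


def make_fold_plan(cohort: SurvivalCohort, n_repeats: int, seed: int,
                   n_folds: int = N_FOLDS) -> list[FoldPlan]:
    """Event-stratified outer/inner fold plans, deterministic given seed."""
    if cohort.n_events < n_folds:
        raise ValidationError(
            f"cohort has {cohort.n_events} events; need at least one per fold "
            f"({n_folds} folds) — use a larger cohort or fewer folds")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_repeats)
    plans = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        outer = _stratified_assignment(cohort.event, n_folds, rng)
        inner: dict[int, np.ndarray] = {}
        for f in range(n_folds):
            train_idx = np.flatnonzero(outer != f)
            inner[f] = _stratified_assignment(cohort.event[train_idx], n_folds, rng)
        plans.append(FoldPlan(
            repeat_id=r, outer_assignment=outer, inner_assignments=inner,
            seed=int(child.generate_state(1)[0] % 2**31)))
    return plans


# ---------------------------------------------------------------------------
# Table-style weighted summaries of the inner loop


def expected_model_size(records: list[ReducedModelRecord]) -> float:
    """Performance-weighted mean reduced-model size, <n>."""
    if not records:
        raise UnevaluableDataError("no reduced-model records")
    h = np.array([r.score for r in records])
    n = np.array([r.size for r in records])
    if h.sum() <= 0:
        return float(n.mean())
    return float((h * n).sum() / h.sum())


def stability_scores(records: list[ReducedModelRecord], variables: list[str]) -> dict[str, float]:
    """Performance-weighted membership fraction per variable, <v>."""
    if not records:
        raise UnevaluableDataError("no reduced-model records")
    h = np.array([r.score for r in records])
    denom = h.sum()
    out = {}
    for v in variables:
        u = np.array([r.usage(v) for r in records])
        out[v] = float((h * u).sum() / denom) if denom > 0 else float(u.mean())
    return out


@dataclass
class InnerSummary:
    """Result of one inner 10-fold loop: the reduced-model records, the
    expected size <n> (real-valued) and per-variable stability <v>."""

    reduced_records: list[ReducedModelRecord]
    expected_size: float
    stability: dict[str, float]
    n_skipped: int = 0


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def inner_loop(outer_train: SurvivalCohort, inner_assignment: np.ndarray,
               variables: list[str], ties: str = "strict",
               repeat_id: int = -1, n_folds: int = N_FOLDS) -> InnerSummary:
    """Run backward elimination + nested-model evaluation + reduced-model
    selection on each inner fold, then summarize."""
    records: list[ReducedModelRecord] = []
    skipped = 0
    for f in range(n_folds):
        tr_idx = np.flatnonzero(inner_assignment != f)
        te_idx = np.flatnonzero(inner_assignment == f)
        train = outer_train.take(tr_idx)
        test = outer_train.take(te_idx)
        try:
            ws = CoxWorkspace(train.select_variables(variables))
            path, evals = _eliminate_and_evaluate(
                ws, variables, test.matrix(variables), test.time, test.event,
                ties=ties)
            rec = select_reduced_model(evals, NestedModelPath(path),
                                       fold_id=f, repeat_id=repeat_id)
        except (UnevaluableDataError, ValidationError) as exc:
            logger.warning("inner fold %d skipped: %s", f, exc)
            skipped += 1
            continue
        records.append(rec)
    if not records:
        raise UnevaluableDataError("all inner folds unevaluable")
    return InnerSummary(
        reduced_records=records,
        expected_size=expected_model_size(records),
        stability=stability_scores(records, variables),
        n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# outer level


@dataclass
class OuterRecord:
    """Reduced and full model results for one outer iteration."""

    repeat_id: int
    fold_id: int
    reduced: ReducedModelRecord
    full: ReducedModelRecord
    reduced_train_score: float
    full_train_score: float
    expected_size: float


def _rank_variables(stability: dict[str, float], declared: list[str]) -> list[str]:
    """Order variables by stability (descending), ties by declared order."""
    pos = {v: i for i, v in enumerate(declared)}
    return sorted(declared, key=lambda v: (-stability[v], pos[v]))


def outer_iteration(outer_train: SurvivalCohort, outer_test: SurvivalCohort,
                    inner_summary: InnerSummary, variables: list[str],
                    ties: str = "strict", repeat_id: int = -1,
                    fold_id: int = -1) -> OuterRecord:
    """Train the round(<n>) most stable variables and the full model on the
    outer training set; score both on the outer test fold (and on the
    training side, for the overfitting diagnostic)."""
    r = max(1, min(len(variables), _round_half_away(inner_summary.expected_size)))
    ranked = _rank_variables(inner_summary.stability, variables)
    reduced_vars = ranked[:r]

    ws = CoxWorkspace(outer_train.select_variables(variables))
    scores = {}
    for label, subset in (("reduced", reduced_vars), ("full", list(variables))):
        fit = ws.fit(subset)
        if not fit.converged:
            raise UnevaluableDataError(
                f"{label} model fit failed on outer training set: {fit.message}")
        lp_test = outer_test.matrix(subset) @ fit.beta
        lp_train = outer_train.matrix(subset) @ fit.beta
        scores[label] = (
            _atd_score_fast(lp_test, outer_test.time, outer_test.event, ties=ties).value,
            _atd_score_fast(lp_train, outer_train.time, outer_train.event, ties=ties).value,
        )
    reduced_rec = ReducedModelRecord(variables=reduced_vars, size=r,
                                     score=scores["reduced"][0],
                                     fold_id=fold_id, repeat_id=repeat_id)
    full_rec = ReducedModelRecord(variables=list(variables), size=len(variables),
                                  score=scores["full"][0],
                                  fold_id=fold_id, repeat_id=repeat_id)
    return OuterRecord(repeat_id=repeat_id, fold_id=fold_id,
                       reduced=reduced_rec, full=full_rec,
                       reduced_train_score=scores["reduced"][1],
                       full_train_score=scores["full"][1],
                       expected_size=inner_summary.expected_size)


@dataclass
class CVSummary:
    """Aggregated output of the full nested cross-validation."""

    variables: list[str]
    outer_records: list[OuterRecord]
    reduced_scores: np.ndarray
    full_scores: np.ndarray
    reduced_train_scores: np.ndarray
    full_train_scores: np.ndarray
    outer_sizes: np.ndarray
    frequency_stability: dict[str, float]
    weighted_stability: dict[str, float]
    final_model: list[str]
    final_size: int
    n_skipped_outer: int
    n_repeats: int
    seed: int
    inner_summaries: list[InnerSummary] = field(default_factory=list, repr=False)


def run_nested_cv(cohort: SurvivalCohort, variables: list[str] | None = None,
                  n_repeats: int = 100, seed: int = 0, ties: str = "strict",
                  n_folds: int = N_FOLDS, keep_inner: bool = False) -> CVSummary:
    """Full nested cross-validation: repeated outer 10-fold CV with an inner
    10-fold selection loop per outer iteration.

    The final model's size is the rounded mean of the outer reduced-model
    sizes; its membership is that many top variables ranked by frequency
    stability (fraction of outer reduced models containing the variable),
    ties broken by the ATD-weighted variant, then declared order.
    """
    if variables is None:
        variables = cohort.variable_names
    variables = list(variables)
    if not variables:
        raise ValidationError("variable set must be non-empty")
    cohort = cohort.select_variables(variables) if cohort.variable_names != variables else cohort

    plans = make_fold_plan(cohort, n_repeats, seed, n_folds=n_folds)
    outer_records: list[OuterRecord] = []
    inner_summaries: list[InnerSummary] = []
    skipped = 0
    total = n_repeats * n_folds
    for plan in plans:
        for f in range(n_folds):
            tr_idx = np.flatnonzero(plan.outer_assignment != f)
            te_idx = np.flatnonzero(plan.outer_assignment == f)
            outer_train = cohort.take(tr_idx)
            outer_test = cohort.take(te_idx)
            try:
                summary = inner_loop(outer_train, plan.inner_assignments[f],
                                     variables, ties=ties, repeat_id=plan.repeat_id,
                                     n_folds=n_folds)
                rec = outer_iteration(outer_train, outer_test, summary, variables,
                                      ties=ties, repeat_id=plan.repeat_id, fold_id=f)
            except UnevaluableDataError as exc:
                logger.warning("outer fold (repeat %d, fold %d) skipped: %s",
                               plan.repeat_id, f, exc)
                skipped += 1
                continue
            outer_records.append(rec)
            if keep_inner:
                inner_summaries.append(summary)
    if skipped > 0.2 * total:
        raise UnevaluableDataError(
            f"{skipped}/{total} outer folds unevaluable; aborting")
    if not outer_records:
        raise UnevaluableDataError("no evaluable outer fold")

    reduced_scores = np.array([r.reduced.score for r in outer_records])
    full_scores = np.array([r.full.score for r in outer_records])
    sizes = np.array([r.reduced.size for r in outer_records])
    n_rec = len(outer_records)
    freq = {v: sum(r.reduced.usage(v) for r in outer_records) / n_rec for v in variables}
    ksum = reduced_scores.sum()
    weighted = {
        v: float(sum(r.reduced.score * r.reduced.usage(v) for r in outer_records) / ksum)
        if ksum > 0 else freq[v]
        for v in variables
    }
    final_size = max(1, min(len(variables), _round_half_away(float(sizes.mean()))))
    pos = {v: i for i, v in enumerate(variables)}
    ranked = sorted(variables, key=lambda v: (-freq[v], -weighted[v], pos[v]))
    final_model = ranked[:final_size]

    return CVSummary(
        variables=variables,
        outer_records=outer_records,
        reduced_scores=reduced_scores,
        full_scores=full_scores,
        reduced_train_scores=np.array([r.reduced_train_score for r in outer_records]),
        full_train_scores=np.array([r.full_train_score for r in outer_records]),
        outer_sizes=sizes,
        frequency_stability=freq,
        weighted_stability=weighted,
        final_model=final_model,
        final_size=final_size,
        n_skipped_outer=skipped,
        n_repeats=n_repeats,
        seed=seed,
        inner_summaries=inner_summaries,
    )
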