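"""Likelihood-driven backward elimination and reduced-model selection.

At each elimination step every remaining variable is dropped in turn, the
leave-one-out Cox model is refit, and the variable whose removal costs the
least log partial likelihood is eliminated ("contributes the least to the
model likelihood").  Eliminated variables are pushed onto the front of a
nested-variable list, so the size-m model is exactly the first m entries —
the variables that survived longest.

The module is deterministic: likelihood ties are broken by removing the
variable that appears latest in the cohort's declared variable order, and
score ties in reduced-model selection are broken toward the smaller model.
Non-convergent candidate fits are treated as likelihood minus infinity and
are never kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atd import ATDScore, _atd_score_fast
from .cohort import SurvivalCohort
from .cox import CoxWorkspace
from .errors import EliminationError, UnevaluableDataError, ValidationError

__all__ = [
    "NestedModelPath",
    "ReducedModelRecord",
    "SizeEvaluation",
    "backward_eliminate",
    "evaluate_nested_models",
    "select_reduced_model",
]


@dataclass
class NestedModelPath:
    """Elimination-ordered variable list; the size-m model is the first m
    entries (position encodes reverse elimination order)."""

    ordered_variables: list[str]

    def model_of_size(self, m: int) -> list[str]:
        if not 1 <= m <= len(self.ordered_variables):
            raise ValidationError(f"model size {m} outside 1..{len(self.ordered_variables)}")
        return self.ordered_variables[:m]


@dataclass
class SizeEvaluation:
    """ATD score of the size-m nested model on a held-out fold (score is
    None when the fit did not converge)."""

    size: int
    score: ATDScore | None
    converged: bool


@dataclass
class ReducedModelRecord:
    """A selected reduced model: its variables, size and held-out ATD score,
    with fold provenance.  Variable usage indicators are membership tests
    on ``variables``."""

    variables: list[str]
    size: int
    score: float
    fold_id: int = -1
    repeat_id: int = -1

    def usage(self, variable: str) -> int:
        return 1 if variable in self.variables else 0


def _eliminate_on_workspace(ws: CoxWorkspace, variables: list[str]) -> list[str]:
    """Core elimination loop over a prepared workspace.  Returns the nested
    list (most important variable first)."""
    n_test = 0
    empty = np.zeros((0, len(variables)))
    nested, _ = _eliminate_and_evaluate(ws, variables, empty,
                                        np.zeros(n_test), np.zeros(n_test, dtype=int),
                                        ties="strict", evaluate=False)
    return nested


def _eliminate_and_evaluate(ws: CoxWorkspace, variables: list[str],
                            Xtest_full: np.ndarray, test_time: np.ndarray,
                            test_event: np.ndarray, ties: str = "strict",
                            evaluate: bool = True
                            ) -> tuple[list[str], list[SizeEvaluation]]:
    """Fused elimination + nested-model evaluation for the inner loop.

    The active variable set when elimination has reduced to size m is the
    size-m nested model, and the kept leave-one-out fit at that step is its
    maximum-partial-likelihood fit on the training data — so each nested
    model's coefficients fall out of the elimination pass and only the
    full-size model needs a dedicated fit.  ``Xtest_full`` is the test
    covariate matrix in workspace variable order.
    """
    declared = {v: i for i, v in enumerate(variables)}
    available = list(variables)
    cols = ws.columns_of(available)
    p = len(available)
    fits: dict[int, tuple[np.ndarray, np.ndarray] | None] = {}
    full_beta, _, _, full_ok, _ = ws.fit_columns(cols)
    fits[p] = (cols.copy(), full_beta) if full_ok else None
    cur_beta = full_beta if full_ok else np.zeros(p)
    nested: list[str] = []
    step = 0
    while len(available) > 1:
        step += 1
        best_ll = -np.inf
        best_j = -1
        best_beta = None
        for j in range(len(available)):
            keep = [i for i in range(len(available)) if i != j]
            beta, ll, _, ok, _ = ws.fit_columns(cols[keep], beta0=cur_beta[keep])
            if not ok:
                continue
            if ll > best_ll or (
                ll == best_ll and best_j >= 0
                and declared[available[j]] > declared[available[best_j]]
            ):
                best_ll = ll
                best_j = j
                best_beta = beta
        if best_j < 0:
            raise EliminationError(
                f"all leave-one-out fits failed at elimination step {step} "
                f"(remaining variables: {available})")
        nested.insert(0, available.pop(best_j))
        cols = cols[np.arange(len(cols)) != best_j]
        cur_beta = best_beta
        fits[len(available)] = (cols.copy(), best_beta)
    nested.insert(0, available.pop())
    if not evaluate:
        return nested, []
    if 1 not in fits:  # single-variable input: the loop never ran
        c1 = ws.columns_of(nested[:1])
        beta1, _, _, ok1, _ = ws.fit_columns(c1)
        fits[1] = (c1, beta1) if ok1 else None

    evals: list[SizeEvaluation] = []
    for m in range(1, p + 1):
        entry = fits.get(m)
        if entry is None:
            evals.append(SizeEvaluation(m, None, False))
            continue
        cols_m, beta_m = entry
        lp = Xtest_full[:, cols_m] @ beta_m
        evals.append(SizeEvaluation(
            m, _atd_score_fast(lp, test_time, test_event, ties=ties), True))
    return nested, evals


def backward_eliminate(train: SurvivalCohort, variables: list[str] | None = None) -> NestedModelPath:
    """Backward-eliminate from the full variable set down to one variable.

    Purely deterministic given the cohort and its declared variable order.
    """
    if variables is None:
        variables = train.variable_names
    if len(variables) < 1:
        raise ValidationError("need at least one variable")
    ws = CoxWorkspace(train.select_variables(list(variables)))
    return NestedModelPath(_eliminate_on_workspace(ws, list(variables)))


def _evaluate_path_on_workspace(ws: CoxWorkspace, path: list[str],
                                test_scores_input: np.ndarray,
                                test_time: np.ndarray, test_event: np.ndarray,
                                ties: str = "strict") -> list[SizeEvaluation]:
    """Train each prefix model on the workspace cohort and score its
    prognostic index on the test arrays.  ``test_scores_input`` is the test
    covariate matrix in path order (n_test, |path|)."""
    out: list[SizeEvaluation] = []
    cols = ws.columns_of(path)
    prev_beta = np.zeros(0)
    for m in range(1, len(path) + 1):
        b0 = np.append(prev_beta, 0.0)
        beta, ll, _, ok, _ = ws.fit_columns(cols[:m], beta0=b0)
        if not ok:
            out.append(SizeEvaluation(m, None, False))
            prev_beta = np.append(prev_beta, 0.0)
            continue
        prev_beta = beta
        lp = test_scores_input[:, :m] @ beta
        score = _atd_score_fast(lp, test_time, test_event, ties=ties)
        out.append(SizeEvaluation(m, score, True))
    return out


def evaluate_nested_models(path: NestedModelPath, train: SurvivalCohort,
                           test: SurvivalCohort, ties: str = "strict") -> list[SizeEvaluation]:
    """Score every nested model size on a held-out test cohort.

    Trains the size-m model (first m path entries) on ``train`` and
    evaluates its prognostic index on ``test`` with the ATD-AUCROC.
    Raises :class:`UnevaluableDataError` if the test fold has no usable
    event time (caller logs and skips the fold).
    """
    ws = CoxWorkspace(train.select_variables(path.ordered_variables))
    Xtest = test.matrix(path.ordered_variables)
    return _evaluate_path_on_workspace(ws, path.ordered_variables, Xtest,
                                       test.time, test.event, ties=ties)


def select_reduced_model(evaluations: list[SizeEvaluation],
                         path: NestedModelPath | None = None,
                         fold_id: int = -1, repeat_id: int = -1) -> ReducedModelRecord:
    """Pick the nested size with the highest held-out ATD score.

    Ties go to the smaller model (parsimony).  Non-converged sizes are
    ignored; an input with no scored entry raises.
    """
    best: SizeEvaluation | None = None
    for ev in sorted(evaluations, key=lambda e: e.size):
        if ev.score is None:
            continue
        if best is None or ev.score.value > best.score.value:
            best = ev
    if best is None:
        raise UnevaluableDataError("no scored nested model to select from")
    variables = path.model_of_size(best.size) if path is not None else []
    return ReducedModelRecord(variables=variables, size=best.size,
                              score=best.score.value, fold_id=fold_id,
                              repeat_id=repeat_id)
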