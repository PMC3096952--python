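"""Average time-dependent AUCROC (ATD-AUCROC).

The discrimination statistic used throughout the pipeline: at the time of
each death in a test set, form a staircase ROC curve from the model's
prognostic index with *cumulative* cases (patients already dead of disease
by that time) and *dynamic* controls (patients still under observation
beyond that time), and average the resulting AUCs over all deaths.

The staircase (empirical step-function) AUC credits only strict
case-over-control orderings; a half credit for ties is exactly the
trapezoidal correction the staircase convention avoids, so ties score 0
by default.  ``ties="half"`` is available as a sensitivity switch.

Patients censored at or before the evaluation time are neither cases nor
controls at that time and are excluded from its ROC.  Deaths sharing a
time each contribute one term to the average (multiplicity preserved).
The latest event time typically has no controls left; such time points are
recorded as not included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import UnevaluableDataError, ValidationError

__all__ = ["EventTimeROCPoint", "ATDScore", "staircase_auc", "atd_aucroc"]


@dataclass
class EventTimeROCPoint:
    """One death-event time point of the time-dependent ROC assessment."""

    event_time: float
    n_cases: int
    n_controls: int
    auc_at_time: float | None
    included: bool


@dataclass
class ATDScore:
    """Mean staircase AUC over all included death-event time points."""

    value: float
    n_events_averaged: int
    points: list[EventTimeROCPoint] = field(default_factory=list, repr=False)


def staircase_auc(case_scores, control_scores, ties: str = "strict") -> float:
    """Area under the staircase ROC: fraction of case-control pairs ordered
    correctly (strictly, by default) by the risk score.

    Parameters
    ----------
    case_scores, control_scores
        Risk scores of cases (events by time t) and controls (still at risk
        after t).  Both must be non-empty.
    ties
        ``"strict"``: tied pairs score 0 (staircase convention).
        ``"half"``: tied pairs score 1/2 (trapezoidal correction).
    """
    case = np.asarray(case_scores, dtype=float)
    ctrl = np.asarray(control_scores, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValidationError("staircase_auc requires non-empty case and control sets")
    if ties not in ("strict", "half"):
        raise ValidationError(f"ties must be 'strict' or 'half', got {ties!r}")
    ctrl_sorted = np.sort(ctrl)
    # for each case: #controls strictly below, and #tied
    n_below = np.searchsorted(ctrl_sorted, case, side="left")
    wins = float(n_below.sum())
    if ties == "half":
        n_le = np.searchsorted(ctrl_sorted, case, side="right")
        wins += 0.5 * float((n_le - n_below).sum())
    return wins / (case.size * ctrl.size)


@njit(cache=True)
def _atd_points(scores, time, event, half_credit):  # pragma: no cover - compiled
    """Per-death-event staircase AUC; NaN where cases or controls are empty.

    Returns (auc_per_event, n_cases, n_controls) aligned with the event
    records in input order.
    """
    n = scores.shape[0]
    n_ev = 0
    for i in range(n):
        if event[i] == 1:
            n_ev += 1
    aucs = np.empty(n_ev)
    ncase = np.zeros(n_ev, dtype=np.int64)
    nctrl = np.zeros(n_ev, dtype=np.int64)
    etimes = np.empty(n_ev)
    e = 0
    for i in range(n):
        if event[i] == 1:
            etimes[e] = time[i]
            e += 1
    case_buf = np.empty(n)
    ctrl_buf = np.empty(n)
    for e in range(n_ev):
        t = etimes[e]
        nc = 0
        nk = 0
        for j in range(n):
            if time[j] <= t and event[j] == 1:
                case_buf[nc] = scores[j]
                nc += 1
            elif time[j] > t:
                ctrl_buf[nk] = scores[j]
                nk += 1
        ncase[e] = nc
        nctrl[e] = nk
        if nc == 0 or nk == 0:
            aucs[e] = np.nan
            continue
        wins = 0.0
        for a in range(nc):
            sa = case_buf[a]
            for b in range(nk):
                if sa > ctrl_buf[b]:
                    wins += 1.0
                elif half_credit == 1 and sa == ctrl_buf[b]:
                    wins += 0.5
        aucs[e] = wins / (nc * nk)
    return aucs, ncase, nctrl, etimes


def _atd_score_fast(scores, time, event, ties: str = "strict") -> ATDScore:
    """Selection-loop fast path: the ATD score without per-time points."""
    aucs, _, _, _ = _atd_points(
        np.ascontiguousarray(scores, dtype=np.float64),
        np.ascontiguousarray(time, dtype=np.float64),
        np.ascontiguousarray(event, dtype=np.int64),
        1 if ties == "half" else 0)
    if aucs.size == 0:
        raise UnevaluableDataError("no events in test set; fold unevaluable")
    ok = ~np.isnan(aucs)
    if not ok.any():
        raise UnevaluableDataError(
            "no event time with both cases and controls; fold unevaluable")
    return ATDScore(value=float(aucs[ok].mean()), n_events_averaged=int(ok.sum()))


def atd_aucroc(scores, time, event, ties: str = "strict") -> ATDScore:
    """Average the staircase AUC over every death event in a test set.

    For each record with ``event == 1`` at time t (deaths sharing a time are
    counted with multiplicity): cases are patients with ``time <= t`` and
    ``event == 1``; controls are patients with ``time > t``; patients
    censored at or before t are excluded.  Event times where either set is
    empty are skipped (recorded with ``included=False``).
    """
    scores = np.ascontiguousarray(scores, dtype=np.float64)
    time = np.ascontiguousarray(time, dtype=np.float64)
    event = np.ascontiguousarray(event, dtype=np.int64)
    if not (scores.shape == time.shape == event.shape) or scores.ndim != 1:
        raise ValidationError("scores, time and event must be aligned 1-d arrays")
    if ties not in ("strict", "half"):
        raise ValidationError(f"ties must be 'strict' or 'half', got {ties!r}")
    if not (event == 1).any():
        raise UnevaluableDataError("no events in test set; fold unevaluable")

    aucs, ncase, nctrl, etimes = _atd_points(scores, time, event,
                                             1 if ties == "half" else 0)
    points = [
        EventTimeROCPoint(float(etimes[e]), int(ncase[e]), int(nctrl[e]),
                          None if np.isnan(aucs[e]) else float(aucs[e]),
                          not np.isnan(aucs[e]))
        for e in range(aucs.size)
    ]
    ok = ~np.isnan(aucs)
    if not ok.any():
        raise UnevaluableDataError(
            "no event time with both cases and controls; fold unevaluable")
    return ATDScore(value=float(aucs[ok].mean()), n_events_averaged=int(ok.sum()),
                    points=points)
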