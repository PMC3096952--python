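import numpy as np
import pytest

from coxselect import (ReducedModelRecord, UnevaluableDataError,
                       ValidationError, expected_model_size, inner_loop,
                       make_fold_plan, outer_iteration, run_nested_cv,
                       stability_scores)
from coxselect.nested_cv import _round_half_away


def _records(hs, ns, varsets):
    return [ReducedModelRecord(variables=v, size=n, score=h)
            for h, n, v in zip(hs, ns, varsets)]


class TestWeightedSummaries:
    def test_expected_size_hand_computed(self):
        # h = (0.6, 0.4), n = (4, 9): (0.6*4 + 0.4*9) / 1.0 = 6.0
        recs = _records([0.6, 0.4], [4, 9], [["a"] * 4, ["a"] * 9])
        assert expected_model_size(recs) == pytest.approx(6.0, abs=0)

    def test_equal_weights_give_arithmetic_mean(self):
        recs = _records([0.5, 0.5, 0.5], [2, 4, 9], [["a"]] * 3)
        assert expected_model_size(recs) == pytest.approx(5.0)

    def test_stability_bounds(self):
        recs = _records([0.6, 0.4], [2, 2], [["a", "b"], ["a", "c"]])
        st = stability_scores(recs, ["a", "b", "c"])
        assert st["a"] == pytest.approx(1.0)            # present everywhere
        assert st["b"] == pytest.approx(0.6 / 1.0)
        assert st["c"] == pytest.approx(0.4 / 1.0)

    @pytest.mark.parametrize("x,r", [(6.0, 6), (6.5, 7), (6.49, 6), (0.4, 0), (1.5, 2)])
    def test_rounding_half_away_from_zero(self, x, r):
        assert _round_half_away(x) == r


class TestFoldPlan:
    def test_equal_fold_sizes_when_divisible(self, signal_cohort):
        c = signal_cohort.take(np.arange(100))
        plan = make_fold_plan(c, n_repeats=1, seed=0)[0]
        sizes = np.bincount(plan.outer_assignment, minlength=10)
        assert (sizes == 10).all()

    def test_event_stratification(self, signal_cohort):
        plan = make_fold_plan(signal_cohort, n_repeats=1, seed=1)[0]
        ev = signal_cohort.event
        counts = [ev[plan.outer_assignment == f].sum() for f in range(10)]
        assert max(counts) - min(counts) <= 1

    def test_same_seed_same_plan(self, signal_cohort):
        a = make_fold_plan(signal_cohort, n_repeats=2, seed=3)
        b = make_fold_plan(signal_cohort, n_repeats=2, seed=3)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.outer_assignment, pb.outer_assignment)
            for f in range(10):
                np.testing.assert_array_equal(pa.inner_assignments[f],
                                              pb.inner_assignments[f])

    def test_folds_partition_cohort(self, signal_cohort):
        plan = make_fold_plan(signal_cohort, n_repeats=1, seed=2)[0]
        assert plan.outer_assignment.shape[0] == signal_cohort.n_patients
        assert set(np.unique(plan.outer_assignment)) == set(range(10))

    def test_too_few_events_rejected(self, toy_cohort):
        with pytest.raises(ValidationError, match="event"):
            make_fold_plan(toy_cohort, n_repeats=1, seed=0)


class TestInnerLoop:
    def test_summary_consistent_with_records(self, signal_cohort):
        outer_train = signal_cohort.take(np.arange(540))
        plan = make_fold_plan(signal_cohort, n_repeats=1, seed=4)[0]
        variables = signal_cohort.variable_names[:8]
        inner = plan.inner_assignments[0]
        # the inner assignment indexes outer-training patients; build one
        # for this 540-patient subset directly
        summary = inner_loop(outer_train, inner[:540], variables, repeat_id=0)
        assert summary.expected_size == pytest.approx(
            expected_model_size(summary.reduced_records))
        st = stability_scores(summary.reduced_records, variables)
        for v in variables:
            assert summary.stability[v] == pytest.approx(st[v])
        assert 1.0 <= summary.expected_size <= len(variables)


@pytest.fixture(scope="module")
def cv_summary(signal_cohort):
    c = signal_cohort.take(np.arange(200))
    return run_nested_cv(c, n_repeats=2, seed=11, keep_inner=True)


class TestRunNestedCV:

    def test_bookkeeping_counts(self, cv_summary):
        expected = 2 * 10 - cv_summary.n_skipped_outer
        assert len(cv_summary.reduced_scores) == expected
        assert len(cv_summary.full_scores) == expected

    def test_counting_identity(self, cv_summary):
        """Sum over variables of frequency-stability * #records equals the
        sum of reduced-model sizes."""
        n_rec = len(cv_summary.outer_records)
        lhs = sum(cv_summary.frequency_stability[v] * n_rec
                  for v in cv_summary.variables)
        rhs = cv_summary.outer_sizes.sum()
        assert lhs == pytest.approx(rhs)

    def test_reduced_nested_in_full(self, cv_summary):
        full = set(cv_summary.variables)
        for rec in cv_summary.outer_records:
            assert set(rec.reduced.variables) <= full
            assert rec.reduced.size == len(rec.reduced.variables)

    def test_audit_identity(self, cv_summary):
        """<n> and <v> recomputed from stored inner records match the
        values used at run time."""
        for rec, summary in zip(cv_summary.outer_records,
                                cv_summary.inner_summaries):
            n = expected_model_size(summary.reduced_records)
            assert n == pytest.approx(summary.expected_size, abs=0)
            assert rec.reduced.size == max(1, min(len(cv_summary.variables),
                                                  _round_half_away(n)))
            st = stability_scores(summary.reduced_records, cv_summary.variables)
            for v in cv_summary.variables:
                assert st[v] == pytest.approx(summary.stability[v], abs=0)

    def test_reduced_model_ranks_by_stability(self, cv_summary):
        for rec, summary in zip(cv_summary.outer_records,
                                cv_summary.inner_summaries):
            chosen = set(rec.reduced.variables)
            worst_in = min(summary.stability[v] for v in chosen)
            best_out = max((summary.stability[v] for v in cv_summary.variables
                            if v not in chosen), default=-1.0)
            assert worst_in >= best_out - 1e-12

    def test_determinism(self, signal_cohort):
        c = signal_cohort.take(np.arange(200))
        a = run_nested_cv(c, n_repeats=1, seed=5)
        b = run_nested_cv(c, n_repeats=1, seed=5)
        np.testing.assert_array_equal(a.reduced_scores, b.reduced_scores)
        assert a.final_model == b.final_model

    def test_final_model_size(self, cv_summary):
        assert cv_summary.final_size == max(1, min(
            len(cv_summary.variables),
            _round_half_away(float(cv_summary.outer_sizes.mean()))))
        assert len(cv_summary.final_model) == cv_summary.final_size

    def test_training_scores_reflect_overfitting(self, cv_summary):
        """Training-side scores exceed test-side scores on average — the
        plus-signs-above-circles diagnostic."""
        assert cv_summary.full_train_scores.mean() > cv_summary.full_scores.mean()
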