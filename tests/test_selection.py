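import numpy as np
import pandas as pd
import pytest

from coxselect import (SurvivalCohort, UnevaluableDataError, backward_eliminate,
                       evaluate_nested_models, select_reduced_model)
from coxselect.atd import ATDScore
from coxselect.cox import CoxWorkspace
from coxselect.selection import (NestedModelPath, SizeEvaluation,
                                 _eliminate_and_evaluate)
from coxselect.simulate import CohortSpec, CovariateSpec, generate_cohort


def _signal_plus_null_spec(seed, n=600, beta_a=np.log(2.5)):
    covs = [
        CovariateSpec("A", "clinical_binary", {"p": 0.5}, true_beta=beta_a),
        CovariateSpec("B", "clinical_binary", {"p": 0.5}, true_beta=0.0),
    ]
    return CohortSpec(n_patients=n, covariates=covs, baseline=("exponential", 0.08),
                      censoring=("uniform", 30.0), horizon_years=15.0, seed=seed)


class TestBackwardEliminate:
    def test_single_variable_path(self):
        c = generate_cohort(_signal_plus_null_spec(0))
        path = backward_eliminate(c, ["A"])
        assert path.ordered_variables == ["A"]

    def test_null_variable_eliminated_first(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            c = generate_cohort(_signal_plus_null_spec(seed))
            path = backward_eliminate(c)
            if path.ordered_variables == ["A", "B"]:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_kept_model_maximizes_likelihood_at_each_step(self, signal_cohort):
        """Argmax property: removing the chosen variable leaves a higher
        log partial likelihood than any alternative single removal."""
        train = signal_cohort.take(np.arange(250))
        variables = signal_cohort.variable_names[:8]
        path = backward_eliminate(train, variables)
        ws = CoxWorkspace(train.select_variables(variables))
        remaining = list(variables)
        order = path.ordered_variables
        while len(remaining) > 1:
            removed = order[len(remaining) - 1]  # eliminated at this step
            kept = [v for v in remaining if v != removed]
            ll_kept = ws.fit(kept).log_partial_likelihood
            for alt in remaining:
                if alt == removed:
                    continue
                ll_alt = ws.fit([v for v in remaining if v != alt]).log_partial_likelihood
                assert ll_kept >= ll_alt - 1e-6
            remaining = kept

    def test_deterministic(self, signal_cohort):
        train = signal_cohort.take(np.arange(300))
        p1 = backward_eliminate(train, signal_cohort.variable_names[:6])
        p2 = backward_eliminate(train, signal_cohort.variable_names[:6])
        assert p1.ordered_variables == p2.ordered_variables

    def test_training_loglik_monotone_along_path(self, signal_cohort):
        train = signal_cohort.take(np.arange(300))
        variables = signal_cohort.variable_names[:7]
        path = backward_eliminate(train, variables)
        ws = CoxWorkspace(train.select_variables(variables))
        lls = [ws.fit(path.model_of_size(m)).log_partial_likelihood
               for m in range(1, len(variables) + 1)]
        assert all(a <= b + 1e-9 for a, b in zip(lls, lls[1:]))


class TestEvaluateNestedModels:
    def test_one_entry_per_size(self, signal_cohort):
        train = signal_cohort.take(np.arange(400))
        test = signal_cohort.take(np.arange(400, 600))
        variables = signal_cohort.variable_names[:5]
        path = backward_eliminate(train, variables)
        evals = evaluate_nested_models(path, train, test)
        assert [e.size for e in evals] == [1, 2, 3, 4, 5]

    def test_train_equals_test_consistency(self, signal_cohort):
        """Deliberate leak: scoring the training set must match a direct
        training-side evaluation."""
        from coxselect import atd_aucroc, prognostic_index
        train = signal_cohort.take(np.arange(300))
        variables = signal_cohort.variable_names[:4]
        path = backward_eliminate(train, variables)
        evals = evaluate_nested_models(path, train, train)
        ws = CoxWorkspace(train.select_variables(variables))
        for e in evals:
            fit = ws.fit(path.model_of_size(e.size))
            direct = atd_aucroc(prognostic_index(fit, train), train.time,
                                train.event).value
            assert e.score.value == pytest.approx(direct, abs=1e-12)

    def test_fused_inner_loop_matches_public_contract(self, signal_cohort):
        train = signal_cohort.take(np.arange(400))
        test = signal_cohort.take(np.arange(400, 600))
        variables = signal_cohort.variable_names[:9]
        path = backward_eliminate(train, variables)
        evals = evaluate_nested_models(path, train, test)
        ws = CoxWorkspace(train.select_variables(variables))
        path2, evals2 = _eliminate_and_evaluate(
            ws, variables, test.matrix(variables), test.time, test.event)
        assert path.ordered_variables == path2
        for a, b in zip(evals, evals2):
            assert a.size == b.size
            assert a.score.value == pytest.approx(b.score.value, abs=1e-12)


class TestSelectReducedModel:
    @staticmethod
    def _evals(scores, sizes):
        return [SizeEvaluation(s, ATDScore(v, 1), True)
                for v, s in zip(scores, sizes)]

    def test_argmax(self):
        rec = select_reduced_model(self._evals([0.6, 0.7, 0.65], [1, 2, 3]),
                                   NestedModelPath(["a", "b", "c"]))
        assert rec.size == 2 and rec.variables == ["a", "b"]

    def test_tie_broken_toward_parsimony(self):
        rec = select_reduced_model(self._evals([0.7, 0.7], [2, 5]))
        assert rec.size == 2

    def test_single_entry(self):
        rec = select_reduced_model(self._evals([0.55], [3]))
        assert rec.size == 3 and rec.score == 0.55

    def test_unscored_input_rejected(self):
        with pytest.raises(UnevaluableDataError):
            select_reduced_model([SizeEvaluation(1, None, False)])
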