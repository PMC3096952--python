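import numpy as np
import pandas as pd
import pytest

from coxselect import (SurvivalCohort, ValidationError, fit_cox,
                       prognostic_index)
from coxselect.cox import CoxWorkspace


def _lifelines_fit(cohort, variables):
    from lifelines import CoxPHFitter

    df = cohort.data[list(variables)].copy()
    df["T"] = cohort.time
    df["E"] = cohort.event
    cph = CoxPHFitter()
    # lifelines also uses the Breslow tie approximation; tighten its stop
    # so the comparison probes our solver, not lifelines' default slack
    cph.fit(df, "T", "E", fit_options={"precision": 1e-10})
    return cph


@pytest.fixture(scope="module")
def tied_cohort():
    """Integer-valued times force many ties; exercises Breslow handling."""
    rng = np.random.default_rng(7)
    n = 80
    data = pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": (rng.uniform(size=n) < 0.4).astype(float),
    })
    time = np.ceil(rng.exponential(5, size=n))
    event = (rng.uniform(size=n) < 0.6).astype(int)
    return SurvivalCohort(data, time, event)


class TestFitCox:
    def test_agrees_with_independent_implementation_on_ties(self, tied_cohort):
        # scikit-survival implements the same Breslow tie approximation;
        # lifelines uses Efron and is compared on tie-free data below
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        fit = fit_cox(tied_cohort, ["x1", "x2"])
        y = np.array(list(zip(tied_cohort.event.astype(bool), tied_cohort.time)),
                     dtype=[("e", bool), ("t", float)])
        oracle = CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12)
        oracle.fit(tied_cohort.data[["x1", "x2"]].to_numpy(), y)
        assert fit.converged
        np.testing.assert_allclose(fit.beta, oracle.coef_, atol=1e-8)

    def test_agrees_with_lifelines_without_ties(self, signal_cohort):
        # continuous event times: Breslow and Efron coincide, so lifelines
        # is a second independent oracle here
        sub = ["AURKA", "nodal_status", "tumor_size"]
        fit = fit_cox(signal_cohort, sub)
        cph = _lifelines_fit(signal_cohort, sub)
        np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-7)
        assert fit.log_partial_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-7)

    def test_recovers_known_hazard_ratio(self):
        # one binary covariate with true HR 2, large n
        rng = np.random.default_rng(3)
        n = 5000
        x = (rng.uniform(size=n) < 0.5).astype(float)
        t_event = rng.exponential(1.0 / (0.1 * np.exp(np.log(2) * x)))
        t_cens = rng.uniform(0, 20, n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        c = SurvivalCohort(pd.DataFrame({"x": x}), np.maximum(time, 1e-9), event)
        fit = fit_cox(c, ["x"])
        assert abs(fit.beta[0] - np.log(2)) < 3 * fit.se[0]

    def test_constant_column_flagged_not_crashed(self, tied_cohort):
        data = tied_cohort.data.copy()
        data["flat"] = 1.0
        c = SurvivalCohort(data, tied_cohort.time, tied_cohort.event)
        fit = fit_cox(c, ["flat"])
        assert not fit.converged
        assert "constant" in fit.message

    def test_empty_subset_rejected(self, tied_cohort):
        with pytest.raises(ValidationError):
            fit_cox(tied_cohort, [])

    def test_loglik_nondecreasing_in_nested_subsets(self, tied_cohort):
        """The optimum over a superset of variables can never be worse."""
        rng = np.random.default_rng(5)
        data = tied_cohort.data.copy()
        data["x3"] = rng.normal(size=len(data))
        c = SurvivalCohort(data, tied_cohort.time, tied_cohort.event)
        ws = CoxWorkspace(c)
        lls = [ws.fit(["x1"]).log_partial_likelihood,
               ws.fit(["x1", "x2"]).log_partial_likelihood,
               ws.fit(["x1", "x2", "x3"]).log_partial_likelihood]
        assert lls[0] <= lls[1] + 1e-9 and lls[1] <= lls[2] + 1e-9

    def test_loglik_recomputable_from_beta(self, tied_cohort):
        from coxselect.cox import _breslow_loglik

        fit = fit_cox(tied_cohort, ["x1", "x2"])
        ws = CoxWorkspace(tied_cohort.select_variables(["x1", "x2"]))
        cols = ws.columns_of(["x1", "x2"])
        XT = ws._XT_full[cols]
        X = np.ascontiguousarray(XT.T)
        ll = _breslow_loglik(X, XT, XT @ ws._evf, ws._ends, ws._d, fit.beta)
        assert ll == pytest.approx(fit.log_partial_likelihood, abs=1e-9)


class TestPrognosticIndex:
    def test_zero_beta_gives_zero_scores(self, tied_cohort):
        fit = fit_cox(tied_cohort, ["x1", "x2"])
        fit.beta = np.zeros(2)
        assert (prognostic_index(fit, tied_cohort) == 0).all()

    def test_single_unit_beta_is_identity(self, tied_cohort):
        fit = fit_cox(tied_cohort, ["x1"])
        fit.beta = np.array([1.0])
        np.testing.assert_array_equal(prognostic_index(fit, tied_cohort),
                                      tied_cohort.data["x1"].to_numpy())

    def test_scaling_beta_preserves_ranking(self, tied_cohort):
        fit = fit_cox(tied_cohort, ["x1", "x2"])
        r1 = np.argsort(prognostic_index(fit, tied_cohort))
        fit.beta = fit.beta * 2
        r2 = np.argsort(prognostic_index(fit, tied_cohort))
        np.testing.assert_array_equal(r1, r2)

    def test_ranking_matches_exp_linear_predictor(self, tied_cohort):
        fit = fit_cox(tied_cohort, ["x1", "x2"])
        lp = prognostic_index(fit, tied_cohort)
        np.testing.assert_array_equal(np.argsort(lp), np.argsort(np.exp(lp)))

    def test_missing_variable_rejected(self, tied_cohort):
        fit = fit_cox(tied_cohort, ["x1"])
        fit.variable_subset = ["zz"]
        with pytest.raises(Exception):
            prognostic_index(fit, tied_cohort)
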