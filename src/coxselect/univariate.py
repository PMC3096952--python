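"""Univariate Cox screening: one single-variable model per cohort variable,
reported as hazard ratios with Wald 95% confidence intervals and p-values
(the usual first table of a prognostic-marker study)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SurvivalCohort
from .cox import CoxWorkspace

__all__ = ["UnivariateResult", "univariate_analysis", "univariate_table"]


@dataclass
class UnivariateResult:
    variable: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool
    message: str = ""


def univariate_analysis(cohort: SurvivalCohort) -> list[UnivariateResult]:
    """Single-variable Cox fit for every cohort variable, in declared order.

    A degenerate variable (constant column, separation) yields a
    non-converged row with NaN statistics; the remaining variables are
    unaffected.
    """
    ws = CoxWorkspace(cohort)
    out: list[UnivariateResult] = []
    z = stats.norm.ppf(0.975)
    for v in cohort.variable_names:
        fit = ws.fit([v])
        if not fit.converged or fit.se is None or not np.isfinite(fit.se[0]):
            out.append(UnivariateResult(v, np.nan, np.nan, np.nan, np.nan,
                                        False, fit.message))
            continue
        beta, se = fit.beta[0], fit.se[0]
        wald = beta / se
        p = float(2 * stats.norm.sf(abs(wald)))
        out.append(UnivariateResult(
            variable=v,
            hazard_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - z * se)),
            ci_high=float(np.exp(beta + z * se)),
            p_value=max(p, np.finfo(float).tiny),
            converged=True,
        ))
    return out


def univariate_table(results: list[UnivariateResult]) -> pd.DataFrame:
    """Tabular view of univariate results."""
    return pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "hazard_ratio": [r.hazard_ratio for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_value": [r.p_value for r in results],
            "converged": [r.converged for r in results],
        }
    )
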