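import numpy as np
import pandas as pd
import pytest

from coxselect import (SurvivalCohort, binarize_age, default_breast_cohort_spec,
                       generate_cohort, prepare_endpoint)
from coxselect.simulate import betas_for_hr_per_sd


def brute_force_atd(scores, time, event, ties="strict"):
    """Independent O(events * n^2) enumeration of the average
    time-dependent staircase AUC, written directly from its definition."""
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    aucs = []
    for i in range(len(time)):
        if event[i] != 1:
            continue
        t = time[i]
        cases = [scores[j] for j in range(len(time)) if time[j] <= t and event[j] == 1]
        controls = [scores[j] for j in range(len(time)) if time[j] > t]
        if not cases or not controls:
            continue
        wins = 0.0
        for cs in cases:
            for ks in controls:
                if cs > ks:
                    wins += 1.0
                elif ties == "half" and cs == ks:
                    wins += 0.5
        aucs.append(wins / (len(cases) * len(controls)))
    return float(np.mean(aucs)) if aucs else None


@pytest.fixture
def toy_cohort():
    """Six patients, hand-constructed, mixed events and censoring."""
    data = pd.DataFrame({
        "x1": [4.0, 3.0, 2.0, 1.0, 5.0, 0.0],
        "x2": [0.0, 1.0, 0.0, 1.0, 1.0, 0.0],
        "age": [49.0, 50.0, 24.0, 88.0, 61.0, 35.0],
    })
    time = np.array([1.0, 2.0, 3.0, 4.0, 12.0, 16.0])
    event = np.array([1, 1, 0, 0, 1, 1])
    return SurvivalCohort(data, time, event)


@pytest.fixture(scope="session")
def signal_cohort():
    """A 600-patient cohort with hazard-ratio-2-per-SD signal on two
    markers and two clinical variables, endpoint-prepared."""
    spec = default_breast_cohort_spec(n_patients=600, seed=42)
    betas = betas_for_hr_per_sd(
        spec, {"AURKA": 2.0, "BCL2": 2.0, "nodal_status": 2.0, "tumor_size": 2.0})
    spec = default_breast_cohort_spec(betas=betas, n_patients=600, seed=42)
    cohort = prepare_endpoint(generate_cohort(spec), 15.0)
    return binarize_age(cohort)
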