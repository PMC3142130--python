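import numpy as np
import pandas as pd
import pytest

from mrcohort.config import causal_scenario
from mrcohort.simulate import generate_cohort


@pytest.fixture(scope="session")
def causal_cohort():
    """One moderate causal cohort shared across read-only tests."""
    return generate_cohort(causal_scenario(n_subjects=1500, seed=42))


@pytest.fixture(scope="session")
def toy_survival():
    """Six-subject tie-free survival toy with one binary covariate."""
    return pd.DataFrame(
        {
            "time_years": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 1, 1, 0, 0],
            "x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
        },
        index=pd.Index([f"S{i}" for i in range(6)], name="subject_id"),
    )


def breslow_loglik(beta, times, events, x):
    """Breslow partial log-likelihood for a single covariate (test oracle).

    On tie-free data this equals the Efron partial likelihood exactly.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.where(events == 1)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll


def breslow_score(beta, times, events, x):
    """Derivative of the Breslow partial log-likelihood (test oracle)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    u = 0.0
    for i in np.where(events == 1)[0]:
        risk = times >= times[i]
        w = np.exp(beta * x[risk])
        u += x[i] - (x[risk] * w).sum() / w.sum()
    return u
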