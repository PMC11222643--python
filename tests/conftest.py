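import numpy as np
import pandas as pd
import pytest

from survrec.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Shared confounded cohort with ground truth (n=1500)."""
    cohort, truth = generate_cohort(CohortConfig(n=1500, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def ph_arm_data():
    """Two-arm proportional-hazards data with known coefficients
    (beta = [0.7, -0.3], exponential baselines 0.02 / 0.01 per month)."""
    rng = np.random.default_rng(42)
    n = 5000
    out = {}
    for arm, lam_base in ((0, 0.02), (1, 0.01)):
        X = rng.normal(0, 1, (n, 2))
        lam = lam_base * np.exp(X @ np.array([0.7, -0.3]))
        t_event = rng.exponential(1 / lam)
        censor = np.minimum(rng.exponential(300, n), 132.0)
        out[arm] = {
            "X": X, "lam": lam,
            "time": np.minimum(t_event, censor),
            "event": (t_event <= censor).astype(int),
        }
    return out
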