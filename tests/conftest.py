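import numpy as np
import pandas as pd
import pytest

from cfsurv.synthetic import default_params, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """1,500-row default synthetic cohort shared across tests."""
    return generate_cohort(default_params(n=1500, seed=11))


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(default_params(n=400, seed=7))


@pytest.fixture()
def km_hand_example():
    """Worked 3-subject censored example: S(2)=2/3, S(6)=1/3.

    Event at 2, censoring after the last event time, event at 6, so the
    hand product-limit is (1 - 1/3) * (1 - 1/2).
    """
    times = np.array([2.0, 7.0, 6.0])
    events = np.array([1, 0, 1])
    return times, events


def toy_covariates(n, rng):
    """In-schema covariate table with randomized levels (for contract tests)."""
    from cfsurv.encoding import CATEGORICAL
    cols = {
        "age": rng.uniform(20, 90, n).round(1),
        "tumor_size": rng.uniform(10, 90, n).round(1),
    }
    for col, levels in CATEGORICAL.items():
        cols[col] = rng.choice(levels, size=n)
    return pd.DataFrame(cols)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
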