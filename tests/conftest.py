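import numpy as np
import pandas as pd
import pytest

import crashlogit as cl
from crashlogit.mixed_logit import ParameterVector, RandomCoef


@pytest.fixture
def toy_table():
    """Four-record table with one covariate, both outcome classes."""
    frame = pd.DataFrame(
        {"male": [1, 1, 0, 0], "fatal": [1, 0, 1, 0], "year": [2018, 2018, 2018, 2018]}
    )
    return cl.CrashTable(frame, outcome_col="fatal", year_col="year")


@pytest.fixture(scope="session")
def demo_table():
    """Three-year demo scenario data (3 x 2000 records, two random coefs)."""
    return cl.make_temporal_dataset(cl.demo_scenario(seed=7))


@pytest.fixture(scope="session")
def single_random_setup():
    """A small table plus truth/spec with one normal random coefficient,
    shared across the quadrature-oracle tests."""
    params = ParameterVector(
        constant=0.0, fixed={}, random={"x": RandomCoef(beta=0.8, sigma=1.2)}
    )
    spec = cl.ModelSpec(random=(cl.RandomSpec("x"),), n_draws=500)
    frame = pd.DataFrame({"x": [1, 0, 1], "fatal": [1, 0, 1], "year": [1, 1, 1]})
    table = cl.CrashTable(frame)
    return params, spec, table


def make_table(cov: pd.DataFrame, y: np.ndarray, year: int = 2018) -> cl.CrashTable:
    frame = cov.copy()
    frame["fatal"] = y
    frame["year"] = year
    return cl.CrashTable(frame)
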