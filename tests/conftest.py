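import numpy as np
import pandas as pd
import pytest

from sealflux.study import load_study_table


@pytest.fixture(scope="session")
def table1():
    return load_study_table("table1")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_profiles(rng):
    """Two well-separated 5-FA compositional groups, 15 profiles each."""
    a = np.array([30.0, 20.0, 20.0, 15.0, 15.0])
    b = np.array([10.0, 35.0, 20.0, 15.0, 20.0])
    rows = [a + rng.normal(0, 0.3, 5) for _ in range(15)]
    rows += [b + rng.normal(0, 0.3, 5) for _ in range(15)]
    df = pd.DataFrame(np.abs(rows), columns=[f"FA_{i}" for i in range(5)])
    labels = np.array([1] * 15 + [2] * 15)
    return df, labels
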