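import numpy as np
import pandas as pd
import pytest

from qboost.cohort import generate_cohort
from qboost.simstudy import simulate


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-child synthetic cohort shared by pipeline tests."""
    return generate_cohort(300, seed=77)


@pytest.fixture(scope="session")
def linear_sample():
    """One draw of the linear-setup DGP (n=600, p=6)."""
    return simulate("linear", 600, 6, np.random.default_rng(4))


def toy_frame(n, rng, p=3):
    return pd.DataFrame(rng.uniform(0, 1, size=(n, p)),
                        columns=[f"x{j + 1}" for j in range(p)])
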