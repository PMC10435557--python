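import numpy as np
import pytest

from careless_screen import (ScaleDesign, assemble_cohort, compute_index_table)


@pytest.fixture(scope="session")
def default_design():
    return ScaleDesign()


@pytest.fixture(scope="session")
def default_cohort():
    """The study-scale cohort: 361 regular + 244 careless, fixed seed."""
    return assemble_cohort(seed=1)


@pytest.fixture(scope="session")
def default_index_table(default_cohort):
    return compute_index_table(default_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast model-fitting tests."""
    return assemble_cohort(n_regular=120, n_careless=80, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
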