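import copy

import numpy as np
import pytest

import soameta as sm


@pytest.fixture(scope="session")
def default_params():
    return sm.default_params()


@pytest.fixture(scope="session")
def small_cohort():
    """6 participants/group at the calibrated defaults — quick module tests."""
    p = copy.deepcopy(sm.default_params())
    p.control.n_participants = 6
    p.psychosis.n_participants = 6
    return sm.build_cohort(p, seed=123)


@pytest.fixture(scope="session")
def small_retained(small_cohort):
    ds, _ = sm.apply_exclusions(small_cohort)
    return ds


@pytest.fixture(scope="session")
def cohort_seed0():
    """Full study-size cohort (30/group) at the canonical seed."""
    return sm.build_cohort(seed=0)


@pytest.fixture(scope="session")
def retained_seed0(cohort_seed0):
    ds, _ = sm.apply_exclusions(cohort_seed0)
    return ds


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
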