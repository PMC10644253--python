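import numpy as np
import pytest

from vnfc.montage import assign_groups, load_montage
from vnfc.synthetic import simulate_cohort


@pytest.fixture(scope="session")
def montage64():
    return load_montage("physionet64")


@pytest.fixture(scope="session")
def groups8(montage64):
    return assign_groups(montage64, g=8)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small separable cohort shared by pipeline-level tests."""
    return simulate_cohort(n_subjects=4, runs_per_subject=2, duration_s=15.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
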