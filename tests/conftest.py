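import numpy as np
import pytest
from hypothesis import settings

from anthroneck import build_default_model, moment_arm_matrix, make_toy_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def male_model():
    return build_default_model("male")


@pytest.fixture(scope="session")
def female_model():
    return build_default_model("female")


@pytest.fixture(scope="session")
def male_moment_arms(male_model):
    return moment_arm_matrix(male_model)


@pytest.fixture()
def single_hinge():
    return make_toy_fixture("single_hinge")


@pytest.fixture()
def twin_muscle():
    return make_toy_fixture("twin_muscle")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
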