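import numpy as np
import pytest

from rsipipe.phantom import make_study_scheme
from rsipipe.rsi_core import CompartmentModel, build_design_matrix


@pytest.fixture(scope="session")
def model():
    return CompartmentModel()


@pytest.fixture(scope="session")
def study_scheme():
    return make_study_scheme(seed=0)


@pytest.fixture(scope="session")
def study_design(study_scheme, model):
    return build_design_matrix(study_scheme, model)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
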