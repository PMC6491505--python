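import numpy as np
import pytest

from precistim.dcm_generative import build_model_space


@pytest.fixture(scope="session")
def model_space():
    return build_model_space()


@pytest.fixture(scope="session")
def models_by_name(model_space):
    return {m.name: m for m in model_space}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
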