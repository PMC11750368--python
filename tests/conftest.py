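import numpy as np
import pytest

from antsim.body import AntMorphology, build_ant_model

try:
    from hypothesis import settings
    settings.register_profile("ci", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def model():
    return build_ant_model()


@pytest.fixture(scope="session")
def morphology():
    return AntMorphology.from_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
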