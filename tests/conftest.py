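import numpy as np
import pytest

from reflexgait.model_core import load_model
from reflexgait.reflex_controller import load_wiring


@pytest.fixture(scope="session")
def model():
    return load_model()


@pytest.fixture(scope="session")
def wiring():
    params, entries, cfg = load_wiring()
    return params, entries, cfg


@pytest.fixture(scope="session")
def params(wiring):
    return wiring[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
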