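import numpy as np
import pytest

from kmotion import phantoms as ph


@pytest.fixture(scope="session")
def brain64():
    return ph.make_brain_phantom(0, (64, 64, 32))


@pytest.fixture(scope="session")
def cardiac64():
    return ph.make_cardiac_phantom(0, (64, 64, 32))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
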