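import numpy as np
import pytest

from seizuredyn import make_fixture


@pytest.fixture(scope="session")
def tiny_recording():
    """Small 4-channel synthetic recording with ground truth (session-wide)."""
    return make_fixture("tiny", seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
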