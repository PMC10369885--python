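import numpy as np
import pytest

from msaforge import demo


@pytest.fixture(scope="session")
def demo_result():
    """One full synthetic study, shared across tests."""
    return demo(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
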