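import numpy as np
import pytest

from vidbold import design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def canonical_schedule():
    """Full-scale participant schedule (1000 train x 3, 102 test x 10, 4 sessions)."""
    return design.canonical_schedule(seed=7)
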