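import numpy as np
import pytest

from cdchannel.model import InputGrid, PromoterControl


@pytest.fixture
def ctrl():
    """Default promoter control used throughout: alpha = 1/min, 1% leak."""
    return PromoterControl(alpha=1.0, leak=0.01)


@pytest.fixture
def grid11():
    """The 11-level input grid X = 0.0, 0.1, ..., 1.0."""
    return InputGrid.uniform(11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
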