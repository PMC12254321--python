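import numpy as np
import pytest

from nucphase.config import SimConfig


@pytest.fixture
def cfg():
    """Default calibration: 0.133 um/px, 10 fps tracer imaging, 256^2 px."""
    return SimConfig(seed=11, frame_interval=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
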