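import numpy as np
import pytest

from eegrqa.io import Recording
from eegrqa.montage import STANDARD_1020


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_recording():
    """A 19-channel 60-s recording of seeded noise at 256 Hz."""
    gen = np.random.default_rng(7)
    data = 20.0 * gen.standard_normal((19, 60 * 256))
    return Recording(
        subject_id="subj_a", group="case", fs=256.0,
        channels=list(STANDARD_1020), data=data,
    )
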