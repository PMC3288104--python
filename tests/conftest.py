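import numpy as np
import pytest

from gabashift.schedule import make_frame_schedule
from gabashift.synthetic_data import default_input_fit


@pytest.fixture(scope="session")
def schedule():
    return make_frame_schedule()


@pytest.fixture(scope="session")
def input_fit():
    return default_input_fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
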