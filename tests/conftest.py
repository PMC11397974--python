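import numpy as np
import pytest

from hystereon.protocol import build_timeline
from hystereon.streams import SensorStream
from hystereon.synthdata import SubjectProfile


@pytest.fixture
def profile():
    return SubjectProfile(seed=7)


@pytest.fixture
def timeline():
    return build_timeline()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_stream(values, fs=1.0, name="hr"):
    values = np.asarray(values, dtype=float)
    return SensorStream(name, np.arange(values.size) / fs, values, fs)


@pytest.fixture
def stream_factory():
    return make_stream
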