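import numpy as np
import pytest

from balancenet.core import EegRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_epoch():
    """One 2 s, 250 Hz two-channel epoch: 10 Hz cosine and its +90 deg lag."""
    fs = 250.0
    t = np.arange(int(2 * fs)) / fs
    x = np.cos(2 * np.pi * 10 * t)
    y = np.cos(2 * np.pi * 10 * t - np.pi / 2)
    return np.vstack([x, y]), fs


def make_recording(data, fs=250.0, eog=None):
    labels = tuple(f"ch{i:02d}" for i in range(data.shape[0]))
    return EegRecording(np.asarray(data, float), fs, labels, eog)
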