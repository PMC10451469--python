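import numpy as np
import pytest

from bioradar import (RadarConfig, SlowTimeSignal, StateLabel, TrainConfig,
                      sample_truth, simulate_echo_matrix, train_and_evaluate)
from bioradar.datasets import make_scalogram_dataset

FS = 17.0


def tone(freqs, amps, duration=30.0, fs=FS, noise=0.0, seed=0):
    """Sum-of-sinusoids test signal as a SlowTimeSignal."""
    t = np.arange(int(duration * fs)) / fs
    x = sum(a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs, amps))
    if noise:
        x = x + noise * np.random.default_rng(seed).normal(size=t.size)
    return SlowTimeSignal(x, fs)


@pytest.fixture(scope="session")
def radar_cfg():
    return RadarConfig()


@pytest.fixture(scope="session")
def two_tone():
    return tone([0.3, 1.2], [1.0, 0.3])


@pytest.fixture(scope="session")
def small_trained_model():
    """A compression-state network trained on a small synthetic set.

    Shared session-wide; big enough to separate the five states, small
    enough to train in about a minute.
    """
    images, labels = make_scalogram_dataset(40, image_size=32, seed=5)
    cfg = TrainConfig(epochs=12, seed=5, patience=3)
    result = train_and_evaluate(images, labels, cfg)
    return result
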