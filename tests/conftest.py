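import numpy as np
import pytest

from neuroflow.recording import EEGRecording
from neuroflow.synthetic import ContinuumSpec, generate_continuum_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Low-noise continuum cohort used across alignment/flow tests."""
    spec = ContinuumSpec(n_per_class=60, noise_sd=0.3, seed=11)
    return generate_continuum_cohort(spec)


@pytest.fixture(scope="session")
def noise_recording():
    """19-channel white-noise recording, short enough for fast MSE."""
    rng = np.random.default_rng(42)
    return EEGRecording(rng.normal(size=(19, 800)), fs=200.0)


@pytest.fixture(scope="session")
def sine_recording():
    """19 identical channels of a pure 10 Hz sine at 500 Hz."""
    fs = 500.0
    t = np.arange(0, 20, 1 / fs)
    data = np.tile(np.sin(2 * np.pi * 10 * t), (19, 1))
    return EEGRecording(data, fs)
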