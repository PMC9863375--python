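import numpy as np
import pytest

from htdspeech.signal_io import RunConfig, Waveform

RATE = 8000
DUR = 0.5


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig(seed=0)


@pytest.fixture(scope="session")
def time_axis() -> np.ndarray:
    return np.arange(int(RATE * DUR)) / RATE


@pytest.fixture(scope="session")
def tone(time_axis) -> Waveform:
    """0.5 s pure tone at 1 kHz, 8 kHz rate."""
    return Waveform(0.5 * np.cos(2 * np.pi * 1000.0 * time_axis), RATE)


@pytest.fixture(scope="session")
def chirp(time_axis) -> Waveform:
    """Linear chirp 500 -> 2000 Hz over 0.5 s: f(t) = 500 + 3000 t."""
    return Waveform(0.5 * np.cos(2 * np.pi * (500.0 * time_axis + 1500.0 * time_axis**2)), RATE)


@pytest.fixture(scope="session")
def small_dataset():
    """Small but learnable synthetic corpus shared across tests."""
    from htdspeech.synthetic_speech import generate_dataset

    return generate_dataset(
        n_classes=6, n_healthy_speakers=6, n_patients=5, reps_healthy=2, reps_aphasic=1, seed=3
    )
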