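import numpy as np
import pytest

from titiduet.audio import AudioSignal, preprocess
from titiduet.synth import profile_library, synthesize_duet

# moderate rate keeps synthesis cheap while leaving headroom above every
# profile's highest harmonic (max ~6.6 kHz)
TEST_RATE = 22050


@pytest.fixture(scope="session")
def profiles():
    return profile_library()


@pytest.fixture(scope="session")
def discolor_duet(profiles):
    """One moloch-pattern duet reused across spectral/temporal tests."""
    signal, truth = synthesize_duet(profiles["discolor"], 3, TEST_RATE, seed=5)
    return signal, truth


@pytest.fixture(scope="session")
def discolor_preprocessed(discolor_duet):
    signal, truth = discolor_duet
    return preprocess(signal, high_pass=80.0), truth


def tone(freq, duration=1.0, rate=44100, amp=1.0, channels=1):
    t = np.arange(int(duration * rate)) / rate
    x = amp * np.sin(2 * np.pi * freq * t)
    if channels == 2:
        x = np.stack([x, x], axis=1)
    return AudioSignal(x, rate)
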