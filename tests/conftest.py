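import numpy as np
import pytest

from voicescreen import SynthesisSpec, VoiceRecording, synthesize_vowel

RATE = 8000.0


@pytest.fixture
def tone():
    """Factory for pure-tone recordings."""

    def make(freq=200.0, duration=5.0, amplitude=0.5, rate=RATE):
        t = np.arange(int(round(duration * rate))) / rate
        return VoiceRecording(samples=amplitude * np.sin(2 * np.pi * freq * t), rate=rate)

    return make


@pytest.fixture
def impulse_train():
    """Factory for periodic impulse trains."""

    def make(period_s=0.005, duration=5.0, amplitude=1.0, rate=RATE):
        n = int(round(duration * rate))
        x = np.zeros(n)
        step = int(round(period_s * rate))
        x[::step] = amplitude
        return VoiceRecording(samples=x, rate=rate)

    return make


@pytest.fixture
def white_noise():
    """Factory for seeded white-noise recordings."""

    def make(seed=0, duration=5.0, amplitude=0.1, rate=RATE):
        rng = np.random.default_rng(seed)
        return VoiceRecording(samples=amplitude * rng.standard_normal(int(duration * rate)), rate=rate)

    return make


@pytest.fixture(scope="session")
def clean_vowel():
    """One unperturbed, noiseless synthetic vowel at 200 Hz."""
    return synthesize_vowel(SynthesisSpec(f0=200.0, seed=1))


@pytest.fixture(scope="session")
def noisy_vowel():
    """Unperturbed vowel with a 20 dB harmonics-to-noise ratio."""
    return synthesize_vowel(SynthesisSpec(f0=200.0, hnr_target=20.0, seed=1))
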