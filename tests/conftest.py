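import numpy as np
import pytest

from emopso.preprocess import AudioSignal
from emopso.synthetic import ClusterSpec, VowelSpec, synth_table, synth_vowel


@pytest.fixture(scope="session")
def clean_vowel():
    """A clean, periodic 120 Hz vowel with its true glottal flow."""
    return synth_vowel(VowelSpec(jitter=0.0, shimmer=0.0, noise_snr=np.inf, seed=7))


@pytest.fixture(scope="session")
def noisy_vowel():
    """A realistic (jittered, 30 dB SNR) vowel."""
    return synth_vowel(VowelSpec(seed=11))


@pytest.fixture(scope="session")
def cluster_table():
    """Default synthetic Gaussian-cluster table (4 classes, 5+45 dims)."""
    return synth_table(ClusterSpec(seed=42))


@pytest.fixture(scope="session")
def small_table():
    """A cheap, fairly separable table for wrapper/classifier tests."""
    return synth_table(
        ClusterSpec(n_classes=3, n_per_class=15, n_informative=3, n_noise=7,
                    separation=6.0, seed=5)
    ).table


@pytest.fixture
def tone_8k():
    """One second of a 440 Hz tone at 8 kHz."""
    t = np.arange(8000) / 8000.0
    return AudioSignal(np.sin(2 * np.pi * 440.0 * t), 8000)
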