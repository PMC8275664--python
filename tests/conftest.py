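import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ffrpitch import (
    make_piano_tone, make_complex_tone, make_da_syllable,
    SimulationConfig, SubjectGroundTruth, simulate_subject_recording,
)


@pytest.fixture(scope="session")
def piano_stim():
    return make_piano_tone()


@pytest.fixture(scope="session")
def complex_stim():
    return make_complex_tone()


@pytest.fixture(scope="session")
def da_stim():
    return make_da_syllable()


@pytest.fixture(scope="session")
def flat_truth(piano_stim):
    """Unit encoding gain at every piano harmonic."""
    return SubjectGroundTruth("S000", {k: 1.0 for k in piano_stim.harmonic_set})


@pytest.fixture(scope="session")
def small_recording(piano_stim, flat_truth):
    """30 epochs/polarity piano recording with a few injected artifacts."""
    cfg = SimulationConfig(epochs_per_polarity=30, artifact_rate=0.1, rng_seed=11)
    return simulate_subject_recording(piano_stim, flat_truth, cfg), cfg


def spectral_peak_freqs(x, fs, n_peaks, pad=8):
    """Frequencies of the n strongest local maxima of the padded periodogram."""
    n = len(x)
    nfft = pad * n
    p = np.abs(np.fft.rfft(x * np.hanning(n), nfft)) ** 2
    f = np.fft.rfftfreq(nfft, 1.0 / fs)
    local = (p[1:-1] > p[:-2]) & (p[1:-1] > p[2:])
    idx = np.flatnonzero(local) + 1
    idx = idx[np.argsort(p[idx])[::-1][:n_peaks]]
    return np.sort(f[idx])
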