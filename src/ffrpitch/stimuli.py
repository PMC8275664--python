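"""Synthesis of the three FFR-eliciting stimuli.

Three stimulus classes are supported: an "unfamiliar" complex tone built
from a sparse set of upper harmonics (F0 = 207.65 Hz, harmonics 3, 7, 8,
10), a piano-like tone (F0 = 261.63 Hz) with decaying envelope and
harmonic roll-off, and a short synthetic /da/ syllable (F0 = 100 Hz)
produced by passing a glottal pulse train through a small formant filter
bank. Tone durations default to 200 ms and the syllable to 80 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Stimulus",
    "make_complex_tone",
    "make_piano_tone",
    "make_da_syllable",
    "DA_FORMANT_TRACKS",
]

#: Canonical alveolar-stop CV formant trajectory used for the /da/ syllable.
#: Each entry: (formant label, onset Hz, steady-state Hz, bandwidth Hz).
#: Transition spans the first 40 ms; values are a documented design choice.
DA_FORMANT_TRACKS = (
    ("F1", 400.0, 700.0, 90.0),
    ("F2", 1700.0, 1200.0, 110.0),
    ("F3", 2580.0, 2500.0, 170.0),
)


@dataclass(frozen=True)
class Stimulus:
    """A synthesised auditory stimulus with known harmonic content.

    Attributes
    ----------
    name : str
        Stimulus class identifier: ``"complex"``, ``"piano"``, or ``"da"``.
    samples : ndarray
        Waveform, peak-normalised to [-1, 1] (arbitrary units).
    sample_rate : float
        Sampling rate in Hz.
    f0 : float
        Fundamental frequency in Hz.
    harmonic_set : frozenset[int]
        Integer harmonic numbers carrying energy (1 = fundamental).
    duration_ms : float
        Nominal duration in milliseconds.
    """

    name: str
    samples: np.ndarray = field(repr=False)
    sample_rate: float
    f0: float
    harmonic_set: frozenset
    duration_ms: float

    def __post_init__(self):
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if not self.harmonic_set:
            raise ValueError("harmonic_set must be non-empty")
        n_expected = self.duration_ms * self.sample_rate / 1000.0
        if abs(len(self.samples) - n_expected) > 1.0:
            raise ValueError(
                f"sample count {len(self.samples)} inconsistent with "
                f"duration {self.duration_ms} ms at {self.sample_rate} Hz"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def time_axis(self) -> np.ndarray:
        """Time of each sample in seconds."""
        return np.arange(self.n_samples) / self.sample_rate


def _n_samples(duration_ms: float, sample_rate: float) -> int:
    return int(round(duration_ms * sample_rate / 1000.0))


def _check_aliasing(f_max: float, sample_rate: float) -> None:
    if sample_rate <= 2.0 * f_max:
        raise ValueError(
            f"component at {f_max:.2f} Hz exceeds Nyquist "
            f"({sample_rate / 2:.2f} Hz); raise sample_rate"
        )


def _normalize(x: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def make_complex_tone(
    f0: float = 207.65,
    harmonics=(3, 7, 8, 10),
    duration_ms: float = 200.0,
    sample_rate: float = 10_000.0,
    include_fundamental: bool = False,
) -> Stimulus:
    """Sum of equal-amplitude sinusoids at ``k * f0`` for k in ``harmonics``.

    The default harmonic set {3, 7, 8, 10} omits the fundamental; pass
    ``include_fundamental=True`` to add energy at F0 itself (FFRs can show
    F0 energy even without stimulus energy there, via nonlinearities, so
    both variants are useful when simulating).
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    harmonics = sorted(set(int(k) for k in harmonics))
    if any(k < 1 for k in harmonics):
        raise ValueError("harmonic numbers must be >= 1")
    if include_fundamental and 1 not in harmonics:
        harmonics = [1] + harmonics
    _check_aliasing(max(harmonics) * f0, sample_rate)
    t = np.arange(_n_samples(duration_ms, sample_rate)) / sample_rate
    wave = np.zeros_like(t)
    for k in harmonics:
        wave += np.sin(2 * np.pi * k * f0 * t)
    return Stimulus(
        name="complex",
        samples=_normalize(wave),
        sample_rate=sample_rate,
        f0=f0,
        harmonic_set=frozenset(harmonics),
        duration_ms=duration_ms,
    )


def make_piano_tone(
    f0: float = 261.63,
    duration_ms: float = 200.0,
    sample_rate: float = 10_000.0,
    n_harmonics: int = 8,
    decay_ms: float = 150.0,
    rolloff: float = 1.0,
) -> Stimulus:
    """Piano-like tone: harmonics 1..n with 1/k**rolloff amplitudes and an
    exponentially decaying envelope (time constant ``decay_ms``).

    ``decay_ms = inf`` yields a stationary harmonic complex.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    _check_aliasing(n_harmonics * f0, sample_rate)
    t = np.arange(_n_samples(duration_ms, sample_rate)) / sample_rate
    wave = np.zeros_like(t)
    for k in range(1, n_harmonics + 1):
        wave += (1.0 / k**rolloff) * np.sin(2 * np.pi * k * f0 * t)
    if np.isfinite(decay_ms):
        wave = wave * np.exp(-t / (decay_ms / 1000.0))
    return Stimulus(
        name="piano",
        samples=_normalize(wave),
        sample_rate=sample_rate,
        f0=f0,
        harmonic_set=frozenset(range(1, n_harmonics + 1)),
        duration_ms=duration_ms,
    )


def _resonator_coeffs(freq: float, bandwidth: float, sample_rate: float):
    """Two-pole resonator (digital formant filter) coefficients."""
    r = np.exp(-np.pi * bandwidth / sample_rate)
    theta = 2 * np.pi * freq / sample_rate
    a1 = -2 * r * np.cos(theta)
    a2 = r * r
    b0 = 1 - r  # rough gain normalisation near the peak
    return b0, a1, a2


def make_da_syllable(
    f0: float = 100.0,
    duration_ms: float = 80.0,
    sample_rate: float = 10_000.0,
    transition_ms: float = 40.0,
    formant_tracks=DA_FORMANT_TRACKS,
    flat_filter: bool = False,
) -> Stimulus:
    """Synthetic /da/ syllable: a glottal pulse train at ``f0`` shaped by a
    time-varying formant filter bank.

    Formant centre frequencies move linearly from their consonant-release
    onset values to vowel steady-state values over ``transition_ms``
    (see :data:`DA_FORMANT_TRACKS`). With ``flat_filter=True`` the filter
    bank is bypassed and the plain pulse train is returned (useful as a
    degenerate check). Harmonic bookkeeping lists every harmonic of F0 up
    to 1500 Hz, matching the feature-extraction cutoff used downstream.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    _check_aliasing(max(max(tr[1], tr[2]) for tr in formant_tracks), sample_rate)
    n = _n_samples(duration_ms, sample_rate)
    period = int(round(sample_rate / f0))
    source = np.zeros(n)
    source[::period] = 1.0  # impulse train at the glottal pulse rate

    if flat_filter:
        out = source.copy()
    else:
        n_trans = min(n, _n_samples(transition_ms, sample_rate))
        out = np.zeros(n)
        for _, f_on, f_ss, bw in formant_tracks:
            freqs = np.full(n, f_ss)
            if n_trans > 0:
                freqs[:n_trans] = np.linspace(f_on, f_ss, n_trans)
            # direct-form biquad with per-sample coefficient update; the
            # signal is short so a Python loop is fine
            y = np.zeros(n)
            w1 = w2 = 0.0
            for i in range(n):
                b0, a1, a2 = _resonator_coeffs(freqs[i], bw, sample_rate)
                w0 = source[i] - a1 * w1 - a2 * w2
                y[i] = b0 * w0
                w2, w1 = w1, w0
            out += y

    harmonic_set = frozenset(range(1, int(1500.0 // f0) + 1))
    return Stimulus(
        name="da",
        samples=_normalize(out),
        sample_rate=sample_rate,
        f0=f0,
        harmonic_set=harmonic_set,
        duration_ms=duration_ms,
    )
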