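"""Harmonic-power features of the averaged FFR.

The power spectrum is a Hann-tapered periodogram computed over the
0 -> stimulus-duration span of the averaged response (the pre-stimulus
baseline and post-stimulus tail are excluded), optionally zero-padded to a
finer frequency grid. Features are the power at the fundamental (F0) and
at every integer harmonic k*F0 up to 1500 Hz of the eliciting stimulus,
read off at the nearest spectral bin. Powers are left uncorrected for the
1/f background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import windows

from .preprocessing import FFRWaveform
from .stimuli import Stimulus

__all__ = [
    "PowerSpectrum",
    "HarmonicPowerVector",
    "compute_spectrum",
    "extract_harmonic_powers",
    "feature_table",
]


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided periodogram: ``power[i]`` at ``frequencies[i]`` (Hz).

    Scaling convention: ``power`` sums (over the one-sided spectrum, with
    the usual doubling of non-DC/Nyquist bins folded in) to the energy of
    the tapered, padded signal, i.e. Parseval holds exactly.
    """

    frequencies: np.ndarray = field(repr=False)
    power: np.ndarray = field(repr=False)
    resolution_hz: float

    def at(self, freq_hz: float) -> float:
        """Power at the bin nearest ``freq_hz``."""
        i = int(np.argmin(np.abs(self.frequencies - freq_hz)))
        return float(self.power[i])


@dataclass(frozen=True)
class HarmonicPowerVector:
    """FFR power at F0 and harmonics of the eliciting stimulus (<= 1500 Hz)."""

    stimulus_name: str
    f0: float
    f0_power: float
    harmonic_powers: dict  # k -> power at k*f0, k >= 2
    spectral_resolution: float

    def __post_init__(self):
        if self.f0_power < 0 or any(p < 0 for p in self.harmonic_powers.values()):
            raise ValueError("powers must be non-negative")
        if any(k * self.f0 > 1500.0 + 1e-9 for k in self.harmonic_powers):
            raise ValueError("harmonic above the 1500 Hz cutoff")

    def to_series(self) -> pd.Series:
        """Feature row with columns F0, H2, H3, ..."""
        data = {"F0": self.f0_power}
        for k in sorted(self.harmonic_powers):
            data[f"H{k}"] = self.harmonic_powers[k]
        return pd.Series(data)

    @property
    def n_features(self) -> int:
        return 1 + len(self.harmonic_powers)


def compute_spectrum(
    ffr: FFRWaveform,
    stimulus: Stimulus,
    pad_to_resolution_hz: float | None = 1.0,
) -> PowerSpectrum:
    """Hann-tapered power spectrum of the FFR over the stimulus span.

    The taper covers only the 0 -> ``stimulus.duration_ms`` window of the
    averaged response. With the default 1 Hz padded grid, harmonics that
    fall between the native bins (duration 200 ms -> 5 Hz spacing) are
    resolved to the nearest 1 Hz; pass ``pad_to_resolution_hz=None`` for
    the unpadded periodogram.
    """
    start_ms, end_ms = ffr.window_ms
    if start_ms > 0 or end_ms < stimulus.duration_ms:
        raise ValueError(
            f"FFR window {ffr.window_ms} does not cover the stimulus span "
            f"[0, {stimulus.duration_ms}] ms"
        )
    fs = ffr.sample_rate
    i0 = int(round(-start_ms / 1000.0 * fs))
    n_win = int(round(stimulus.duration_ms / 1000.0 * fs))
    seg = ffr.samples[i0 : i0 + n_win] * windows.hann(n_win, sym=False)

    if pad_to_resolution_hz is None:
        nfft = n_win
    else:
        nfft = max(n_win, int(round(fs / pad_to_resolution_hz)))
    spec = np.fft.rfft(seg, nfft)
    power = np.abs(spec) ** 2 / nfft
    power[1:] *= 2.0
    if nfft % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return PowerSpectrum(frequencies=freqs, power=power, resolution_hz=fs / nfft)


def extract_harmonic_powers(
    spectrum: PowerSpectrum,
    f0: float,
    cutoff_hz: float = 1500.0,
    stimulus_name: str = "",
) -> HarmonicPowerVector:
    """Read the power at k*f0 for k = 1, 2, ... while k*f0 <= cutoff.

    Each harmonic's power is the value at the nearest spectral bin
    (resolution is recorded so callers can judge the lookup error).
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    k_max = int(cutoff_hz // f0)
    if k_max < 1:
        warnings.warn(
            f"f0={f0} Hz is at or above the {cutoff_hz} Hz cutoff; "
            "returning the F0 entry only"
        )
        k_max = 1
    harmonic_powers = {k: spectrum.at(k * f0) for k in range(2, k_max + 1)}
    return HarmonicPowerVector(
        stimulus_name=stimulus_name,
        f0=f0,
        f0_power=spectrum.at(f0),
        harmonic_powers=harmonic_powers,
        spectral_resolution=spectrum.resolution_hz,
    )


def feature_table(vectors: dict) -> pd.DataFrame:
    """Stack per-subject :class:`HarmonicPowerVector`s into a DataFrame
    (rows: subject id, columns: F0, H2, ...)."""
    return pd.DataFrame({sid: v.to_series() for sid, v in vectors.items()}).T
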