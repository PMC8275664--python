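"""Synthetic FFR cohort generator with full ground-truth bookkeeping.

Two levels of simulation are provided:

* **Recording level** — :func:`simulate_subject_recording` renders a
  continuous single-channel EEG-like voltage trace plus an audio monitor
  channel for a train of alternating-polarity stimulus presentations.
  The response of each presentation decomposes into (i) a
  polarity-invariant periodic "neural" component at the stimulus
  harmonics, scaled by per-subject encoding gains, (ii) a
  polarity-following cochlear-microphonic-like component that inverts with
  stimulus polarity, (iii) 1/f plus white noise, and (iv) occasional
  large-amplitude artifacts. All injected onsets and artifacts are
  recorded so downstream preprocessing can be checked against ground
  truth.

* **Feature level** — :func:`simulate_feature_cohort` skips the EEG
  rendering and draws per-subject harmonic-power features directly, then
  generates behavioral outcomes through a logistic link on the
  standardized features. This is the fast path for testing the modeling
  and inference stages at cohort scale.

Every function is driven by an explicit seed; identical configuration and
seed give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stimuli import Stimulus
from .behavior import BehavioralProfile, score_ap, logit_score, APTrial

__all__ = [
    "SimulationConfig",
    "SubjectGroundTruth",
    "RawRecording",
    "simulate_subject_recording",
    "simulate_behavior",
    "simulate_ap_trials",
    "simulate_feature_cohort",
    "pink_noise",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the recording-level simulation.

    Defaults mirror the acquisition conditions the pipeline expects:
    1500 presentations per stimulus polarity, a 35 uV-scale artifact
    threshold downstream, and an audio channel whose stimulus peaks exceed
    the 700 mV onset-detection threshold.
    """

    n_subjects: int = 31
    epochs_per_polarity: int = 1500
    artifact_rate: float = 0.0
    artifact_amplitude_uV: float = 100.0
    cm_amplitude_uV: float = 0.2
    response_amplitude_uV: float = 0.5
    noise_sd_uV: float = 1.0
    noise_exponent: float = 1.0  # spectral exponent chi of the 1/f^chi part
    white_noise_fraction: float = 0.3
    isi_ms: float = 150.0
    lead_ms: float = 100.0
    sample_rate: float = 10_000.0
    audio_peak_mV: float = 1000.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.epochs_per_polarity < 1:
            raise ValueError("epochs_per_polarity must be >= 1")
        for name in ("artifact_rate", "white_noise_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class SubjectGroundTruth:
    """Per-subject generative parameters, kept for recovery tests.

    ``encoding_gains`` maps harmonic number -> non-negative relative gain
    of the neural response at that harmonic. ``behavior_weights`` maps
    feature name (e.g. ``"H4"``) -> weight on the logit scale applied to
    the cohort-standardized harmonic power. ``noise_sd`` is the residual
    SD of the latent logit score.
    """

    subject_id: str
    encoding_gains: dict
    behavior_weights: dict = field(default_factory=dict)
    behavior_intercept: float = 0.0
    noise_sd: float = 0.0
    group_label: bool = False

    def __post_init__(self):
        if any(g < 0 for g in self.encoding_gains.values()):
            raise ValueError("encoding gains must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class RawRecording:
    """Continuous simulated recording plus ground truth.

    ``eeg`` is in uV, ``audio`` in mV; both share ``sample_rate``.
    ``true_onsets`` are the exact sample indices where each presentation's
    stimulus begins; ``artifact_presentations`` indexes presentations that
    received an injected artifact.
    """

    eeg: np.ndarray = field(repr=False)
    audio: np.ndarray = field(repr=False)
    sample_rate: float
    polarity_schedule: np.ndarray = field(repr=False)
    true_onsets: np.ndarray = field(repr=False)
    stimulus_name: str = ""
    artifact_presentations: np.ndarray = field(default_factory=lambda: np.array([], int), repr=False)

    def __post_init__(self):
        if len(self.eeg) != len(self.audio):
            raise ValueError("eeg and audio must be the same length")


def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f**exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0  # avoid the DC singularity
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_subject_recording(
    stimulus: Stimulus,
    truth: SubjectGroundTruth,
    config: SimulationConfig,
) -> RawRecording:
    """Render one subject's continuous recording for one stimulus.

    Presentations strictly alternate polarity (+, -, +, ...), totalling
    ``2 * config.epochs_per_polarity``. The audio channel carries the
    stimulus waveform (sign following polarity) scaled to
    ``config.audio_peak_mV`` so onsets are detectable with an absolute
    700 mV threshold.
    """
    fs = config.sample_rate
    if fs != stimulus.sample_rate:
        raise ValueError("stimulus and config sample rates differ")
    rng = np.random.default_rng(config.rng_seed)
    n_pres = 2 * config.epochs_per_polarity
    stim_len = stimulus.n_samples
    period = stim_len + int(round(config.isi_ms / 1000.0 * fs))
    lead = int(round(config.lead_ms / 1000.0 * fs))
    total = lead + n_pres * period + lead

    # polarity-invariant neural response: stimulus harmonics scaled by gains
    t = np.arange(stim_len) / fs
    neural = np.zeros(stim_len)
    for k in sorted(stimulus.harmonic_set):
        gain = truth.encoding_gains.get(k, 0.0)
        if gain > 0:
            neural += gain * np.sin(2 * np.pi * k * stimulus.f0 * t)
    peak = np.max(np.abs(neural))
    if peak > 0:
        neural = neural / peak * config.response_amplitude_uV

    cm = config.cm_amplitude_uV * stimulus.samples  # follows the waveform

    eeg = np.zeros(total)
    audio = np.zeros(total)
    if config.noise_sd_uV > 0:
        w = config.white_noise_fraction
        noise = np.sqrt(1 - w) * pink_noise(total, config.noise_exponent, rng)
        noise += np.sqrt(w) * rng.standard_normal(total)
        eeg += config.noise_sd_uV * noise

    polarity = np.empty(n_pres, int)
    polarity[0::2] = 1
    polarity[1::2] = -1
    onsets = lead + period * np.arange(n_pres)

    artifact_mask = rng.random(n_pres) < config.artifact_rate
    # 20 ms, 500 Hz tone burst: stays inside the downstream analysis band so
    # filtering does not remove it before amplitude-based rejection
    art_len = int(round(0.020 * fs))
    art_t = np.arange(art_len) / fs
    art_shape = np.sin(np.pi * np.arange(art_len) / art_len) * np.sin(2 * np.pi * 500.0 * art_t)

    for i in range(n_pres):
        s = onsets[i]
        eeg[s : s + stim_len] += neural + polarity[i] * cm
        audio[s : s + stim_len] += polarity[i] * config.audio_peak_mV * stimulus.samples
        if artifact_mask[i]:
            # place the excursion shortly after onset, inside the epoch window
            a = s + int(round(0.030 * fs))
            eeg[a : a + art_len] += config.artifact_amplitude_uV * art_shape

    return RawRecording(
        eeg=eeg,
        audio=audio,
        sample_rate=fs,
        polarity_schedule=polarity,
        true_onsets=onsets,
        stimulus_name=stimulus.name,
        artifact_presentations=np.flatnonzero(artifact_mask),
    )


# ---------------------------------------------------------------------------
# behavior generation


def simulate_ap_trials(
    accuracy: float,
    n_trials: int,
    rng: np.random.Generator,
    timbre: str = "piano",
    semitone_error_share: float = 0.1,
    note_range: tuple = (48, 84),
) -> list:
    """Draw AP labeling trials whose expected conservative score is ``accuracy``.

    Errors are a one-semitone miss with probability ``semitone_error_share``
    (earning 0.75 credit) and a uniformly random wrong label otherwise, so
    the exact-hit probability is solved from
    ``p + 0.75 * q * (1 - p) = accuracy``.
    """
    q = semitone_error_share
    p_exact = (accuracy - 0.75 * q) / (1.0 - 0.75 * q)
    p_exact = float(np.clip(p_exact, 0.0, 1.0))
    lo, hi = note_range
    trials = []
    for _ in range(n_trials):
        note = int(rng.integers(lo, hi + 1))
        u = rng.random()
        if u < p_exact:
            resp = note
        elif u < p_exact + q * (1 - p_exact):
            resp = note + (1 if rng.random() < 0.5 else -1)
        else:
            # a genuine miss: at least two semitones away, earning no credit
            resp = note
            while abs(resp - note) < 2:
                resp = int(rng.integers(lo, hi + 1))
        trials.append(APTrial(presented_note=note, timbre=timbre, response_note=resp))
    return trials


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_behavior(
    features: pd.Series | dict,
    truth: SubjectGroundTruth,
    rng: np.random.Generator,
    n_trials_per_test: int = 40,
    jnd_correlation: float = 0.4,
    adjustment_correlation: float = -0.3,
    age_onset_correlation: float = -0.3,
) -> tuple:
    """Generate one subject's behavioral profile from standardized features.

    The latent score is ``intercept + weights . features + N(0, noise_sd)``
    on the logit scale; its inverse logit is the subject's expected
    conservative AP accuracy, from which trial-level sine- and piano-timbre
    AP responses are drawn. JND, pitch-adjustment error and age of music
    onset are drawn with the configured correlations to the (standardized
    scale of the) latent score.

    Returns ``(BehavioralProfile, trials, latent)`` where ``trials`` is a
    dict with the sine and piano trial lists.
    """
    if isinstance(features, dict):
        features = pd.Series(features)
    latent = truth.behavior_intercept
    for name, w in truth.behavior_weights.items():
        latent += w * float(features[name])
    latent += truth.noise_sd * rng.standard_normal() if truth.noise_sd > 0 else 0.0
    acc = float(_sigmoid(latent))

    trials = {
        "sine": simulate_ap_trials(acc, n_trials_per_test, rng, timbre="sine"),
        "piano": simulate_ap_trials(acc, n_trials_per_test, rng, timbre="piano"),
    }
    ap_sine = score_ap(trials["sine"], measure="conservative")
    ap_piano = score_ap(trials["piano"], measure="conservative")
    ap_avg = 0.5 * (ap_sine + ap_piano)

    def correlated(rho):
        return rho * latent + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal()

    jnd = float(np.clip(0.8 + 0.08 * correlated(jnd_correlation), 0.5, 1.0))
    adjustment = float(np.exp(1.0 + 0.5 * correlated(adjustment_correlation)))
    age_onset = float(np.clip(7.0 + 2.5 * correlated(age_onset_correlation), 2.0, 18.0))

    profile = BehavioralProfile(
        ap_sine=ap_sine,
        ap_piano=ap_piano,
        ap_avg=ap_avg,
        ap_logit=logit_score(ap_avg, epsilon=1.0 / (4 * n_trials_per_test)),
        jnd=jnd,
        adjustment=adjustment,
        age_onset=age_onset,
        tonal_language=bool(rng.random() < 0.3),
    )
    return profile, trials, latent


# ---------------------------------------------------------------------------
# fast feature-level cohort


def simulate_feature_cohort(
    n_subjects: int = 31,
    f0: float = 261.63,
    cutoff_hz: float = 1500.0,
    weights: dict | None = None,
    noise_sd: float = 0.3,
    power_spread: float = 0.6,
    seed: int = 0,
) -> tuple:
    """Draw a cohort of harmonic-power features and latent logit outcomes.

    Per-subject powers at F0 and each harmonic ``k*f0 <= cutoff_hz`` are
    log-normal (``power_spread`` is the SD of log power across subjects).
    The latent outcome is a linear function, with ``weights`` (feature
    name -> weight), of the cohort-z-scored powers plus N(0, noise_sd)
    noise on the logit scale.

    Returns ``(X, y, truth)``: a raw (un-standardized) feature DataFrame
    with columns ``F0, H2, H3, ...``, the latent logit outcome Series, and
    a dict with the generative weights, noise SD and latent values.
    """
    if weights is None:
        weights = {}
    rng = np.random.default_rng(seed)
    n_harm = int(cutoff_hz // f0)
    cols = ["F0"] + [f"H{k}" for k in range(2, n_harm + 1)]
    log_power = rng.normal(0.0, power_spread, size=(n_subjects, len(cols)))
    X = pd.DataFrame(np.exp(log_power), columns=cols,
                     index=[f"S{i:03d}" for i in range(n_subjects)])
    Z = (X - X.mean()) / X.std(ddof=0)
    latent = np.zeros(n_subjects)
    for name, w in weights.items():
        if name not in Z.columns:
            raise KeyError(f"unknown feature {name!r}")
        latent += w * Z[name].to_numpy()
    latent += noise_sd * rng.standard_normal(n_subjects)
    y = pd.Series(latent, index=X.index, name="ap_logit")
    truth = {"weights": dict(weights), "noise_sd": noise_sd, "latent": latent.copy()}
    return X, y, truth
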