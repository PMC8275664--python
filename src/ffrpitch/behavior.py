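"""Scoring of the behavioral battery.

Covers the absolute-pitch (AP) labeling tests (conservative semitone-credit
scoring, raw accuracy, and mean absolute deviation), the just-noticeable-
difference (JND) same/different task around a 1000 Hz standard, and the
pitch-adjustment task (match a probe sine tone to a masked target), plus
assembly of the z-scored behavioral predictor table used in modeling.

Notes are represented as integer chromatic indices (MIDI convention,
A4 = 69 = 440 Hz, equal temperament); enharmonic spellings are collapsed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "APTrial",
    "JNDTrial",
    "AdjustmentTrial",
    "BehavioralProfile",
    "score_ap",
    "logit_score",
    "score_jnd",
    "score_adjustment",
    "assemble_behavioral_predictors",
    "note_frequency",
    "cents_between",
    "adjustment_target_frequencies",
]

A4_MIDI = 69
A4_HZ = 440.0


def note_frequency(midi_note: int, cents_offset: float = 0.0) -> float:
    """Equal-tempered frequency of a MIDI note number, optionally detuned
    by ``cents_offset`` cents (A4 = 440 Hz)."""
    return A4_HZ * 2.0 ** ((midi_note - A4_MIDI) / 12.0 + cents_offset / 1200.0)


def cents_between(f_a: float, f_b: float) -> float:
    """Signed interval from ``f_b`` to ``f_a`` in cents."""
    if f_a <= 0 or f_b <= 0:
        raise ValueError("frequencies must be positive")
    return 1200.0 * math.log2(f_a / f_b)


def adjustment_target_frequencies(n_targets: int = 10) -> np.ndarray:
    """Target frequencies of the pitch-adjustment task.

    Targets span B4 minus 80 cents up to C5 plus 80 cents (i.e. across the
    B4 and C5 note categories), spaced evenly in cents.
    """
    lo = -80.0                      # cents relative to B4
    hi = 100.0 + 80.0               # C5 is 100 cents above B4
    cents = np.linspace(lo, hi, n_targets)
    b4 = A4_MIDI + 2
    return np.array([note_frequency(b4, c) for c in cents])


@dataclass(frozen=True)
class APTrial:
    """One pitch-labeling trial: the presented note, its timbre, and the
    participant's labeled note, both as chromatic (MIDI) indices."""

    presented_note: int
    timbre: str  # "piano" | "sine"
    response_note: int


@dataclass(frozen=True)
class JNDTrial:
    """One same/different discrimination trial around the 1000 Hz standard."""

    deviation_cents: float  # 0 if both tones were the standard
    responded_different: bool

    @property
    def is_different(self) -> bool:
        return self.deviation_cents != 0.0

    @property
    def correct(self) -> bool:
        return self.responded_different == self.is_different


@dataclass(frozen=True)
class AdjustmentTrial:
    """One pitch-adjustment trial: target frequency and the participant's
    final adjusted frequency, both in Hz."""

    target_hz: float
    final_hz: float


@dataclass(frozen=True)
class BehavioralProfile:
    """Per-subject behavioral summary used as modeling inputs/targets."""

    ap_sine: float
    ap_piano: float
    ap_avg: float
    ap_logit: float
    jnd: float
    adjustment: float
    age_onset: float
    tonal_language: bool

    def __post_init__(self):
        for name in ("ap_sine", "ap_piano", "ap_avg", "jnd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def score_ap(trials, measure: str = "conservative", timbre: str | None = None) -> float:
    """Score a list of AP labeling trials.

    measure
        ``"conservative"`` — 1 point for an exact label, 0.75 if exactly
        one semitone off, 0 otherwise; total points / number of trials.
        ``"raw"`` — proportion of exact labels.
        ``"mad"`` — mean absolute deviation in semitones (lower is better).
    timbre
        If given, restrict scoring to trials of that timbre.
    """
    if timbre is not None:
        trials = [t for t in trials if t.timbre == timbre]
    if not trials:
        raise ValueError("no trials to score")
    deltas = np.array([abs(t.response_note - t.presented_note) for t in trials])
    if measure == "conservative":
        credit = np.where(deltas == 0, 1.0, np.where(deltas == 1, 0.75, 0.0))
        return float(credit.mean())
    if measure == "raw":
        return float((deltas == 0).mean())
    if measure == "mad":
        return float(deltas.mean())
    raise ValueError(f"unknown measure {measure!r}")


def logit_score(score: float, epsilon: float = 0.0125) -> float:
    """Logit transform of a [0, 1]-bounded score.

    Boundary scores are clipped to ``[epsilon, 1 - epsilon]`` before the
    transform; the default epsilon corresponds to half a trial's worth of
    credit on a 40-trial test (1 / (2 * 40)).
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError("score must lie in [0, 1]")
    p = min(max(score, epsilon), 1.0 - epsilon)
    return math.log(p / (1.0 - p))


def score_jnd(trials, per_block: bool = False):
    """Proportion of correct same/different judgments.

    With ``per_block=True`` also returns a dict keyed by the block's
    deviation magnitude (56/28/14/7 cents in the standard protocol).
    """
    if not trials:
        raise ValueError("no trials to score")
    overall = float(np.mean([t.correct for t in trials]))
    if not per_block:
        return overall
    blocks: dict = {}
    for t in trials:
        blocks.setdefault(abs(t.deviation_cents), []).append(t.correct)
    return overall, {k: float(np.mean(v)) for k, v in sorted(blocks.items())}


def score_adjustment(trials, step_cents: float = 10.0) -> float:
    """Mean absolute matching error of the pitch-adjustment task.

    Per-trial error is ``|1200 * log2(final / target)|`` cents; the score
    is the mean error expressed in units of the smallest adjustment step
    (default 10 cents), so lower is better.
    """
    if not trials:
        raise ValueError("no trials to score")
    errors = []
    for t in trials:
        if t.target_hz <= 0 or t.final_hz <= 0:
            raise ValueError("frequencies must be positive")
        errors.append(abs(cents_between(t.final_hz, t.target_hz)))
    return float(np.mean(errors) / step_cents)


def assemble_behavioral_predictors(profiles: dict | pd.DataFrame) -> tuple:
    """Build the z-scored behavioral predictor table.

    Parameters
    ----------
    profiles : dict of subject_id -> BehavioralProfile, or DataFrame with
        columns ``age_onset, tonal_language, adjustment, jnd``.

    Returns
    -------
    (Z, scaling) : the z-scored table and a DataFrame of the column means
        and SDs so the raw table can be reconstructed. Zero-variance
        columns are dropped with a warning; missing values raise.
    """
    if isinstance(profiles, dict):
        rows = {
            sid: dict(age_onset=p.age_onset, tonal_language=float(p.tonal_language),
                      adjustment=p.adjustment, jnd=p.jnd)
            for sid, p in profiles.items()
        }
        table = pd.DataFrame.from_dict(rows, orient="index")
    else:
        table = profiles[["age_onset", "tonal_language", "adjustment", "jnd"]].astype(float)
    if table.isna().any().any():
        raise ValueError("missing behavioral values; no imputation is performed")
    means = table.mean()
    sds = table.std(ddof=0)
    keep = sds > 0
    if not keep.all():
        dropped = list(table.columns[~keep])
        warnings.warn(f"dropping zero-variance behavioral columns: {dropped}")
    Z = (table.loc[:, keep] - means[keep]) / sds[keep]
    scaling = pd.DataFrame({"mean": means[keep], "sd": sds[keep]})
    return Z, scaling
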