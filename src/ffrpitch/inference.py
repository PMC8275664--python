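"""Fisher-z inference on cross-validated correlation distributions.

Each model's per-run held-out correlations are mapped through the Fisher
z-transformation (atanh), compared to chance (z = 0) with one-sample
t-tests, and compared between models with Welch's unequal-variance
t-test. Twelve planned tests are corrected with a Bonferroni-adjusted
threshold alpha = 0.05 / 12 = 0.00417. Welch's test also accepts
summary statistics (mean, SD, n per group) so printed group summaries can
be re-tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .modeling import CVResultSet

__all__ = [
    "ComparisonResult",
    "fisher_z",
    "one_sample_t",
    "welch_t",
    "welch_t_from_summary",
    "bonferroni_alpha",
    "run_comparison_suite",
    "SUITE_MODEL_LABELS",
]

#: Model labels the 12-test comparison suite expects.
SUITE_MODEL_LABELS = (
    "complex", "piano", "speech",
    "piano_to_piano", "piano_to_sine",
    "behavioral", "combined",
)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one t-test in the comparison suite."""

    label: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant_at_corrected_alpha: bool
    mean_r: float = float("nan")
    mean_z: float = float("nan")

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.degrees_of_freedom <= 0:
            raise ValueError("degrees of freedom must be positive")


def fisher_z(r):
    """Fisher z-transformation, z = atanh(r).

    Correlations of exactly +/-1 are nudged inside the open interval by
    one machine epsilon (with a warning) so the transform stays finite.
    """
    r = np.asarray(r, float)
    if np.any(np.abs(r) > 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(r) == 1.0):
        warnings.warn("|r| = 1 clipped by machine epsilon before atanh")
        r = np.clip(r, -1.0 + np.finfo(float).eps, 1.0 - np.finfo(float).eps)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def one_sample_t(values, mu: float = 0.0, label: str = "",
                 corrected_alpha: float | None = None) -> ComparisonResult:
    """Two-sided one-sample t-test of ``mean(values) == mu``.

    ``df = n - 1``; with 1000 cross-validation runs this is the familiar
    df = 999.
    """
    v = np.asarray(values, float)
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero standard deviation; t is undefined")
    t = (v.mean() - mu) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    alpha = 0.00417 if corrected_alpha is None else corrected_alpha
    return ComparisonResult(
        label=label, t_statistic=float(t), degrees_of_freedom=float(df),
        p_value=float(p), significant_at_corrected_alpha=bool(p < alpha),
        mean_z=float(v.mean()),
    )


def _welch(m1, s1, n1, m2, s2, n2):
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0.0:
        raise ValueError("zero variance in both samples; t is undefined")
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t(sample_a, sample_b, label: str = "",
            corrected_alpha: float | None = None) -> ComparisonResult:
    """Welch's two-sample t-test with Welch-Satterthwaite (fractional) df."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 values")
    t, df, p = _welch(a.mean(), a.std(ddof=1), len(a),
                      b.mean(), b.std(ddof=1), len(b))
    alpha = 0.00417 if corrected_alpha is None else corrected_alpha
    return ComparisonResult(
        label=label, t_statistic=t, degrees_of_freedom=df, p_value=p,
        significant_at_corrected_alpha=bool(p < alpha),
    )


def welch_t_from_summary(mean_a: float, sd_a: float, n_a: int,
                         mean_b: float, sd_b: float, n_b: int,
                         label: str = "",
                         corrected_alpha: float | None = None) -> ComparisonResult:
    """Welch's test from group summary statistics (mean, SD, n)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need n >= 2")
    t, df, p = _welch(mean_a, sd_a, n_a, mean_b, sd_b, n_b)
    alpha = 0.00417 if corrected_alpha is None else corrected_alpha
    return ComparisonResult(
        label=label, t_statistic=t, degrees_of_freedom=df, p_value=p,
        significant_at_corrected_alpha=bool(p < alpha),
    )


def bonferroni_alpha(alpha: float = 0.05, m: int = 12) -> float:
    """Bonferroni-corrected significance threshold alpha / m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def run_comparison_suite(cv_results: dict, alpha: float = 0.05,
                         m_tests: int = 12) -> list:
    """The planned 12-test battery over a family of CV result sets.

    ``cv_results`` maps model label -> :class:`CVResultSet` and must
    contain every label in :data:`SUITE_MODEL_LABELS`. Tests: the six
    models {complex, piano, speech, piano_to_piano, piano_to_sine,
    behavioral} against chance; the three pairwise stimulus contrasts
    (complex-piano, piano-speech, complex-speech); piano_to_piano vs
    piano_to_sine; combined vs piano (FFR-only); combined vs behavioral.
    Each result is flagged against the Bonferroni-corrected threshold.
    Between-model tests are unpaired Welch tests on the two z samples
    (runs are split independently per model).
    """
    missing = [lbl for lbl in SUITE_MODEL_LABELS if lbl not in cv_results]
    if missing:
        raise KeyError(f"missing model result sets: {missing}")
    corrected = bonferroni_alpha(alpha, m_tests)
    z = {lbl: fisher_z(cv_results[lbl].r_values) for lbl in SUITE_MODEL_LABELS}
    mean_r = {lbl: cv_results[lbl].mean_r for lbl in SUITE_MODEL_LABELS}

    results = []
    for lbl in ("complex", "piano", "speech", "piano_to_piano",
                "piano_to_sine", "behavioral"):
        res = one_sample_t(z[lbl], 0.0, label=f"{lbl} vs chance",
                           corrected_alpha=corrected)
        results.append(ComparisonResult(
            label=res.label, t_statistic=res.t_statistic,
            degrees_of_freedom=res.degrees_of_freedom, p_value=res.p_value,
            significant_at_corrected_alpha=res.significant_at_corrected_alpha,
            mean_r=mean_r[lbl], mean_z=res.mean_z,
        ))
    pairs = [
        ("complex", "piano"),
        ("piano", "speech"),
        ("complex", "speech"),
        ("piano_to_piano", "piano_to_sine"),
        ("combined", "piano"),
        ("combined", "behavioral"),
    ]
    for a, b in pairs:
        results.append(welch_t(z[a], z[b], label=f"{a} vs {b}",
                               corrected_alpha=corrected))
    assert len(results) == m_tests
    return results


def comparison_table(results: list) -> pd.DataFrame:
    """Tabulate a list of :class:`ComparisonResult` for saving/printing."""
    return pd.DataFrame(
        [{
            "label": r.label,
            "t": r.t_statistic,
            "df": r.degrees_of_freedom,
            "p": r.p_value,
            "significant": r.significant_at_corrected_alpha,
            "mean_r": r.mean_r,
            "mean_z": r.mean_z,
        } for r in results]
    )
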