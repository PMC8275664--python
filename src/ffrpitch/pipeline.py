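"""Config-driven end-to-end execution of the synthetic experiment.

One call to :func:`run_pipeline` simulates a cohort (recording-level EEG
plus behavior), preprocesses every recording to an averaged FFR, extracts
harmonic-power features, scores behavior, evaluates the seven prediction
models (complex / piano / speech FFR -> average AP; piano FFR -> piano AP
and -> sine AP; behavioral-only; combined) by repeated nested
cross-validation, and runs the 12-test comparison suite. Outputs are
plain CSV/JSON plus a manifest carrying the config hash and all seeds, so
a rerun from the same config reproduces every number bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .stimuli import make_complex_tone, make_piano_tone, make_da_syllable
from .simulate import (
    SimulationConfig, SubjectGroundTruth, simulate_subject_recording, simulate_behavior,
)
from .preprocessing import preprocess_recording
from .spectral import compute_spectrum, extract_harmonic_powers, feature_table
from .behavior import assemble_behavioral_predictors, logit_score
from .modeling import LassoPitchModel, fit_full_model, default_lambda_grid
from .inference import run_comparison_suite, comparison_table

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "simulate_cohort_features"]

MODEL_LABELS = ("complex", "piano", "speech", "piano_to_piano",
                "piano_to_sine", "behavioral", "combined")


@dataclass
class RunConfig:
    """Everything needed to rerun the synthetic experiment.

    Defaults reproduce the acquisition-scale conditions (31 subjects,
    1500 epochs per polarity, 1000 CV runs); pass smaller values for
    quick demonstrations.
    """

    n_subjects: int = 31
    epochs_per_polarity: int = 1500
    artifact_rate: float = 0.02
    cm_amplitude_uV: float = 0.2
    response_amplitude_uV: float = 0.5
    noise_sd_uV: float = 1.0
    sample_rate: float = 10_000.0
    gain_spread: float = 0.6           # SD of log encoding gains across subjects
    behavior_weights: dict = field(default_factory=lambda: {"F0": -0.6, "H4": 0.6})
    behavior_noise_sd: float = 0.5
    n_trials_per_test: int = 40
    n_runs: int = 1000
    lambda_grid_size: int = 50
    alpha: float = 0.05
    m_tests: int = 12
    base_seed: int = 0
    output_dir: str | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _make_stimuli(fs: float) -> dict:
    return {
        "complex": make_complex_tone(sample_rate=fs),
        "piano": make_piano_tone(sample_rate=fs),
        "da": make_da_syllable(sample_rate=fs),
    }


def simulate_cohort_features(config: RunConfig) -> tuple:
    """Simulate the cohort through recording, preprocessing and features.

    Returns ``(features, behavior, truths, trials)`` where ``features``
    maps stimulus name -> per-subject harmonic-power DataFrame,
    ``behavior`` is the per-subject behavioral table, ``truths`` the
    ground-truth records, and ``trials`` the trial-level AP responses.
    """
    fs = config.sample_rate
    stimuli = _make_stimuli(fs)
    master = np.random.SeedSequence(config.base_seed)
    subj_seeds = master.generate_state(config.n_subjects * 4).reshape(config.n_subjects, 4)

    truths = {}
    vectors = {name: {} for name in stimuli}
    for i in range(config.n_subjects):
        sid = f"S{i:03d}"
        rng_gain = np.random.default_rng(subj_seeds[i, 0])
        gains = {}
        for stim in stimuli.values():
            for k in stim.harmonic_set:
                gains.setdefault(k, float(np.exp(rng_gain.normal(0.0, config.gain_spread))))
        truth = SubjectGroundTruth(
            subject_id=sid,
            encoding_gains=gains,
            behavior_weights=dict(config.behavior_weights),
            noise_sd=config.behavior_noise_sd,
        )
        truths[sid] = truth
        for j, (name, stim) in enumerate(stimuli.items()):
            sim_cfg = SimulationConfig(
                n_subjects=config.n_subjects,
                epochs_per_polarity=config.epochs_per_polarity,
                artifact_rate=config.artifact_rate,
                cm_amplitude_uV=config.cm_amplitude_uV,
                response_amplitude_uV=config.response_amplitude_uV,
                noise_sd_uV=config.noise_sd_uV,
                sample_rate=fs,
                rng_seed=int(subj_seeds[i, 1]) + j,
            )
            rec = simulate_subject_recording(stim, truth, sim_cfg)
            ffr = preprocess_recording(rec, rng_seed=int(subj_seeds[i, 2]) + j)
            spec = compute_spectrum(ffr, stim)
            vectors[name][sid] = extract_harmonic_powers(
                spec, stim.f0, stimulus_name=name
            )

    features = {name: feature_table(v) for name, v in vectors.items()}

    # behavioral link runs on cohort-standardized piano features
    piano = features["piano"]
    Zpiano = (piano - piano.mean()) / piano.std(ddof=0)
    behavior_rows = {}
    trials = {}
    for i, sid in enumerate(piano.index):
        rng_b = np.random.default_rng(subj_seeds[i, 3])
        profile, subj_trials, latent = simulate_behavior(
            Zpiano.loc[sid], truths[sid], rng_b,
            n_trials_per_test=config.n_trials_per_test,
        )
        behavior_rows[sid] = {
            "ap_sine": profile.ap_sine, "ap_piano": profile.ap_piano,
            "ap_avg": profile.ap_avg, "ap_logit": profile.ap_logit,
            "jnd": profile.jnd, "adjustment": profile.adjustment,
            "age_onset": profile.age_onset,
            "tonal_language": float(profile.tonal_language),
            "latent": latent,
        }
        trials[sid] = subj_trials
    behavior = pd.DataFrame.from_dict(behavior_rows, orient="index")
    return features, behavior, truths, trials


def _model_datasets(features: dict, behavior: pd.DataFrame,
                    n_trials_per_test: int) -> dict:
    """Assemble (X, y) per model label."""
    eps = 1.0 / (2 * n_trials_per_test)
    y_avg = behavior["ap_logit"]
    y_piano = behavior["ap_piano"].map(lambda p: logit_score(p, eps))
    y_sine = behavior["ap_sine"].map(lambda p: logit_score(p, eps))
    Zbehav, _ = assemble_behavioral_predictors(behavior)
    combined = pd.concat([features["piano"], Zbehav], axis=1)
    return {
        "complex": (features["complex"], y_avg),
        "piano": (features["piano"], y_avg),
        "speech": (features["da"], y_avg),
        "piano_to_piano": (features["piano"], y_piano),
        "piano_to_sine": (features["piano"], y_sine),
        "behavioral": (Zbehav, y_avg),
        "combined": (combined, y_avg),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic experiment described by ``config``.

    Returns a results bundle: feature tables, behavioral table, per-model
    CV result sets and full-data fits, the 12-row comparison table, and a
    manifest (config, hash, seeds, version). If ``config.output_dir`` is
    set, everything is also written there as CSV/JSON.
    """
    from . import __version__

    t0 = time.time()
    log.info("stage simulate+preprocess+features: starting")
    try:
        features, behavior, truths, trials = simulate_cohort_features(config)
    except Exception as e:
        raise RuntimeError(f"[simulate/preprocess/features] {e}") from e
    log.info("stage simulate+preprocess+features: %.1f s", time.time() - t0)

    datasets = _model_datasets(features, behavior, config.n_trials_per_test)
    grid = default_lambda_grid(config.lambda_grid_size)
    model_seeds = np.random.SeedSequence(config.base_seed + 1).generate_state(len(MODEL_LABELS))

    cv_results, fits = {}, {}
    for seed, label in zip(model_seeds, MODEL_LABELS):
        t1 = time.time()
        X, y = datasets[label]
        try:
            model = LassoPitchModel(y, X, lambda_grid=grid, label=label)
            cv_results[label] = model.fit_repeated_cv(
                n_runs=config.n_runs, base_seed=int(seed))
            fits[label] = model.fit()
        except Exception as e:
            raise RuntimeError(f"[model:{label}] {e}") from e
        log.info("stage model:%s: %.1f s (mean r = %.3f)",
                 label, time.time() - t1, cv_results[label].mean_r)

    try:
        comparisons = run_comparison_suite(cv_results, config.alpha, config.m_tests)
    except Exception as e:
        raise RuntimeError(f"[inference] {e}") from e
    table = comparison_table(comparisons)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "base_seed": config.base_seed,
        "model_labels": list(MODEL_LABELS),
        "elapsed_s": round(time.time() - t0, 2),
    }
    bundle = {
        "features": features,
        "behavior": behavior,
        "truths": truths,
        "trials": trials,
        "cv_results": cv_results,
        "fits": fits,
        "comparisons": table,
        "manifest": manifest,
    }
    if config.output_dir:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle["features"].items():
        df.to_csv(outdir / f"features_{name}.csv")
    bundle["behavior"].to_csv(outdir / "behavior.csv")
    rows = []
    for sid, per_timbre in bundle["trials"].items():
        for timbre, tl in per_timbre.items():
            for t in tl:
                rows.append({"subject": sid, "timbre": timbre,
                             "presented_note": t.presented_note,
                             "response_note": t.response_note})
    pd.DataFrame(rows).to_csv(outdir / "ap_trials.csv", index=False)
    for label, cv in bundle["cv_results"].items():
        cv.save_json(outdir / f"cv_{label}.json")
    fits_json = {
        label: {
            "coefficients": res.params.to_dict(),
            "intercept": res.intercept,
            "lambda": res.lam,
            "support": res.support,
        }
        for label, res in bundle["fits"].items()
    }
    with open(outdir / "fits.json", "w") as fh:
        json.dump(fits_json, fh, indent=2)
    bundle["comparisons"].to_csv(outdir / "comparisons.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2)
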