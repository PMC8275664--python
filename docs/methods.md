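# Methods

This note records the scientific and numerical choices behind `ffrpitch`:
what each stage computes, which parameters matter, what the synthetic
cohorts do and do not emulate, and the known limitations of the inference
procedure.

## Signal model

A frequency-following response to a periodic stimulus with fundamental F0
is modeled as the sum of

* a **polarity-invariant neural component**: energy at the stimulus
  harmonics k·F0, scaled by subject-specific encoding gains. This is the
  quantity of scientific interest — it reflects how faithfully a subject's
  auditory pathway encodes each spectral component;
* a **polarity-following component** (cochlear microphonic and stimulus
  artifact): follows the stimulus waveform and inverts when the stimulus
  polarity inverts. Averaging equal numbers of opposite-polarity epochs
  cancels it in expectation while the neural component survives;
* **background noise** with a 1/f^χ spectrum (χ = 1 by default) plus a
  white component, and occasional large-amplitude artifacts.

The behavioral link assumes the (logit-transformed, [0,1]-bounded)
conservative AP score is linear in the cohort-standardized harmonic powers
plus Gaussian noise; the inverse logit of the latent score is the
subject's expected per-trial labeling accuracy.

## Preprocessing

Fixed order: filter → onset detection → epoching → artifact rejection →
baseline correction → polarity equalization → averaging.

* "12 dB/octave roll-off" is realized as a 2nd-order Butterworth bandpass
  (100–2000 Hz for the tonal stimuli, 70–2000 Hz for /da/), applied
  forward–backward (zero phase) so the averaged response is not delayed
  relative to the audio channel. The 60 Hz notch is an IIR notch with
  Q = 30 (≈2 Hz −3 dB width). Filtering runs on the continuous recording,
  not on epochs, to keep filter transients away from analysis windows.
* Onset detection uses an **absolute** ±700 mV threshold on the audio
  channel. Using |x| rather than a one-sided threshold marks inverted and
  non-inverted presentations at identical latencies, preserving the phase
  difference that makes polarity-averaging cancel the cochlear
  microphonic. A refractory period (default 210 ms — longer than either
  stimulus, shorter than a presentation period) suppresses re-triggering
  within a stimulus.
* Epoch windows: (−50, +250) ms for the 200 ms tonal stimuli,
  (−10, +120) ms for the 80 ms /da/; the pre-onset span is the baseline.
  Epochs exceeding ±35 µV anywhere are discarded. Rejection precedes
  baseline correction by default (the narrative order); the opposite
  order is available via `reject_before_baseline=False` and differs only
  when an epoch's offset straddles the threshold.
* Polarity equalization randomly subsamples the more numerous polarity
  (seeded); averaging requires exactly balanced counts.

## Spectral features

The power spectrum is a Hann-tapered periodogram over the 0 → stimulus-
duration span only (baseline and tail excluded); powers are left
uncorrected for the 1/f background. A 200 ms window gives a 5 Hz native
grid, so harmonics of 207.65 or 261.63 Hz fall between bins; by default
the segment is zero-padded to a 1 Hz grid and each harmonic's power read
at the nearest bin (nearest-bin on the native grid is available via
`pad_to_resolution_hz=None`). Features are the powers at F0 and each
k·F0 ≤ 1500 Hz; they enter the models linearly (no dB transform) and are
z-scored inside the fitting routines.

## Behavioral scoring

* Conservative AP score: credit 1 for an exact chromatic label, 0.75 for
  a ±1-semitone error, 0 otherwise (octave errors included), averaged
  over trials. Raw accuracy and mean absolute deviation (semitones) are
  provided as alternatives. Notes are MIDI-style integer indices with
  enharmonic equivalence.
* The logit transform clips boundary scores to [ε, 1−ε] with
  ε = 1/(2·n_trials) — half a trial's credit — before log(p/(1−p)).
* JND: proportion of correct same/different judgments around the 1000 Hz
  standard (blocks at 56/28/14/7 cents deviation).
* Pitch adjustment: per-trial error |1200·log₂(final/target)| cents,
  averaged and expressed in 10-cent step units (the task's smallest
  adjustment step); the ten targets span B4 − 80 cents to C5 + 80 cents
  in equal steps of cents (equal temperament, A4 = 440 Hz).

## Penalised regression

The loss is `L(β) = Σᵢ(ŷᵢ − yᵢ)² + λ·Σⱼ|βⱼ|` — the SSE is **unscaled**,
so penalty values are comparable across implementations only after
rescaling (`λ = 2n·α` for solvers minimizing `(1/2n)·SSE + α‖β‖₁`). The
solver is cyclic coordinate descent with soft thresholding on Gram
matrices, converged when no coefficient moves more than 1e−12 (cap
10 000 sweeps); leave-one-out CV rank-1-downdates the Gram matrices and
warm-starts along the descending-λ path. Hot loops are numba-compiled,
with an equivalent pure-Python fallback.

Choices where the procedure was underdetermined:

* **λ grid**: 50 log-spaced values spanning 0.01–10¹⁰ (the span is part
  of the procedure; the density is a package choice).
* **LOOCV criterion**: mean squared prediction error over held-out
  points. (A correlation criterion is undefined for single held-out
  observations and would never select the empty model.) Ties break toward
  the larger λ, i.e. the sparser model.
* **Standardization**: per training set — predictors z-scored, response
  standardized; inner LOOCV folds re-center implicitly via the Gram
  downdates but reuse the outer-training scale. Full-data fits are
  reported in these normalized units, which forces the intercept to zero
  at machine precision.
* **Splits**: train size = ⌈2n/3⌉ (21 of 31), the rest test. A constant
  prediction on the test set (typical when λ hits the all-zero region
  under the null) yields r = 0 with a warning.
* Every run's split derives from one base seed via `SeedSequence`; the
  entire pipeline is a pure function of (config, seeds).

## Inference

Per-run test correlations are mapped through z = atanh(r). Each model's
z-sample is compared to chance by a one-sample t-test (df = n_runs − 1);
models are compared to each other by Welch's unequal-variance t-test on
the two z-samples, since splits are drawn independently per model. The
12 planned tests share a Bonferroni threshold α = 0.05/12 ≈ 0.00417.
Welch's test also accepts summary statistics so group contrasts can be
recomputed from published means and SDs.

## Synthetic cohorts: what they emulate, and what they do not

The recording-level generator reproduces the *structure* the pipeline
assumes — alternating polarity, harmonically precise neural energy,
an invertible microphonic, 1/f noise, threshold-crossing artifacts, an
audio channel hot enough for ±700 mV detection — with full ground-truth
bookkeeping. It does not attempt cochlear or brainstem biophysics,
realistic response latencies or adaptation, electrode/skull volume
conduction, or acoustically faithful piano/Klatt synthesis; formant
defaults for /da/ (F1 400→700, F2 1700→1200, F3 2580→2500 Hz over a
40 ms transition) are canonical alveolar-stop values chosen once. The
complex tone omits its fundamental by default (only harmonics 3/7/8/10
carry energy); `include_fundamental=True` adds it, since real FFRs can
show F0 energy through pathway nonlinearities and both generator
settings are useful. Passing recovery tests on these cohorts shows the
*pipeline* is correct, not that real FFRs behave this way.

Problem sizes used in the validation suite are deliberately modest: the
EEG-level chain is exercised at tens-to-hundreds of epochs per polarity
(the generator defaults to the acquisition-scale 1500), and the
cohort-scale model checks use feature-level simulation with 31 subjects,
100-run CV for recovery and 200 null cohorts × 50 runs for calibration.

## Known limitations

* **The repeated-CV t-test is anti-conservative.** The n_runs test-set
  correlations for one cohort are not independent — every split reuses
  the same subjects. Under a pure null, each cohort carries a
  chance-level but *consistent* mean r, so the between-cohort spread of
  mean r (~0.08 at n = 31) dwarfs the within-cohort standard error once
  n_runs is large, and the one-sample t-test rejects far more often than
  its nominal level (measured ≈18% at α = 0.00417 with 50 runs). The
  calibration test in the acceptance suite documents this; enormous
  t-statistics from this procedure should be read as effect-size
  summaries, not as calibrated evidence. Corrected alternatives
  (e.g. Nadeau–Bengio variance inflation) are out of scope here.
* CV-argmin λ over-selects: full-data fits typically include small
  spurious coefficients beside the dominant true ones.
* Single-channel EEG only. The BrainVision loader (`ffrpitch.io`) is a
  thin optional path requiring `mne` and a caller-supplied polarity
  schedule; real-data results depend on acquisition details the synthetic
  generator does not model.
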