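"""Preprocessing chain: filtering, onsets, epoching, rejection, averaging."""

import numpy as np
import pytest
from scipy import signal

from ffrpitch import (
    SimulationConfig, SubjectGroundTruth, simulate_subject_recording,
    bandpass_and_notch, detect_onsets, epoch, reject_artifacts,
    baseline_correct, equalize_polarity, average_ffr, preprocess_recording,
)
from ffrpitch.preprocessing import EpochSet, _design_filters
from ffrpitch.simulate import RawRecording

FS = 10_000.0


def _epochset(data, polarity=None, window=(-50.0, 250.0), name="piano"):
    data = np.asarray(data, float)
    if polarity is None:
        polarity = np.resize([1, -1], len(data))
    return EpochSet(epochs=data, polarity=np.asarray(polarity, int),
                    window_ms=window, sample_rate=FS, stimulus_name=name)


def _recording(eeg, audio=None, polarity=(1,), onsets=(0,)):
    if audio is None:
        audio = np.zeros_like(eeg)
    return RawRecording(eeg=np.asarray(eeg, float), audio=np.asarray(audio, float),
                        sample_rate=FS, polarity_schedule=np.asarray(polarity, int),
                        true_onsets=np.asarray(onsets, int), stimulus_name="piano")


class TestFilter:
    def test_dc_removed(self):
        rec = _recording(np.full(20_000, 5.0))
        out = bandpass_and_notch(rec, "piano")
        assert abs(out.eeg[5_000:15_000].mean()) < 1e-6

    def test_60hz_notched(self):
        t = np.arange(40_000) / FS
        rec = _recording(np.sin(2 * np.pi * 60.0 * t))
        out = bandpass_and_notch(rec, "piano")
        assert np.max(np.abs(out.eeg[10_000:30_000])) < 0.05

    def test_magnitude_response_matches_closed_form(self):
        # impulse response spectrum vs |H_bp * H_notch|^4 (zero-phase = twice)
        n = 2 ** 16
        x = np.zeros(n)
        x[n // 2] = 1.0
        out = bandpass_and_notch(_recording(x), "piano").eeg
        H_obs = np.abs(np.fft.rfft(out))
        freqs = np.fft.rfftfreq(n, 1.0 / FS)
        sos, (b, a) = _design_filters("piano", FS, 60.0, 30.0)
        w = 2 * np.pi * freqs / FS
        _, Hbp = signal.sosfreqz(sos, worN=w)
        _, Hn = signal.freqz(b, a, worN=w)
        H_exp = (np.abs(Hbp) * np.abs(Hn)) ** 2
        for f_test in (50.0, 500.0):
            i = int(round(f_test / (FS / n)))
            assert H_obs[i] == pytest.approx(H_exp[i], rel=0.01)
        # and the 500 Hz vs 50 Hz power ratio follows the analytic response
        i50, i500 = int(round(50 / (FS / n))), int(round(500 / (FS / n)))
        assert (H_obs[i500] / H_obs[i50]) ** 2 == pytest.approx(
            (H_exp[i500] / H_exp[i50]) ** 2, rel=0.05)

    def test_band_depends_on_stimulus(self):
        # 80 Hz tone: inside the /da/ band (70-2000) but outside the tonal band
        t = np.arange(40_000) / FS
        rec = _recording(np.sin(2 * np.pi * 80.0 * t))
        mid = slice(10_000, 30_000)
        tonal = bandpass_and_notch(rec, "piano").eeg[mid]
        da = bandpass_and_notch(rec, "da").eeg[mid]
        assert np.max(np.abs(da)) > 2 * np.max(np.abs(tonal))

    def test_edge_above_nyquist_rejected(self):
        eeg = np.zeros(1000)
        rec = RawRecording(eeg=eeg, audio=eeg.copy(), sample_rate=3000.0,
                           polarity_schedule=np.array([1]),
                           true_onsets=np.array([0]), stimulus_name="piano")
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_and_notch(rec, "piano")


class TestOnsets:
    def test_all_zero_audio_warns_empty(self):
        with pytest.warns(UserWarning, match="no threshold crossings"):
            onsets = detect_onsets(np.zeros(1000), sample_rate=FS)
        assert onsets.size == 0

    def test_pulses_detected_at_known_samples(self):
        audio = np.zeros(50_000)
        true = np.array([100, 4100, 8100, 12_100])
        audio[true] = 800.0
        assert np.array_equal(detect_onsets(audio, sample_rate=FS, refractory_ms=200),
                              true)

    def test_absolute_threshold_polarity_invariant(self):
        rng = np.random.default_rng(0)
        audio = np.zeros(50_000)
        for s in (500, 5500, 10_500):
            audio[s : s + 100] = 900.0 * np.sin(2 * np.pi * 300 * np.arange(100) / FS)
        a = detect_onsets(audio, sample_rate=FS)
        b = detect_onsets(-audio, sample_rate=FS)
        assert np.array_equal(a, b)

    def test_simulator_ground_truth_recovered(self, small_recording):
        rec, _ = small_recording
        onsets = detect_onsets(rec.audio, sample_rate=rec.sample_rate)
        assert len(onsets) == len(rec.true_onsets)
        lags = onsets - rec.true_onsets
        # constant small detection latency, identical across presentations
        assert lags.min() == lags.max()
        assert 0 <= lags[0] < 20


class TestEpoching:
    def test_epoch_lengths(self, small_recording):
        rec, _ = small_recording
        ep = epoch(rec, rec.true_onsets)
        assert ep.epochs.shape == (60, 3000)  # 300 ms at 10 kHz

    def test_da_epoch_length(self):
        eeg = np.zeros(30_000)
        rec = RawRecording(eeg=eeg, audio=eeg.copy(), sample_rate=FS,
                           polarity_schedule=np.array([1, -1]),
                           true_onsets=np.array([5000, 15_000]), stimulus_name="da")
        ep = epoch(rec, rec.true_onsets)
        assert ep.epochs.shape[1] == 1300  # 130 ms at 10 kHz

    def test_onset_at_recording_start_dropped(self):
        eeg = np.zeros(10_000)
        rec = _recording(eeg, polarity=[1, -1], onsets=[0, 5000])
        ep = epoch(rec, np.array([0, 5000]))
        assert ep.n_epochs == 1


class TestRejection:
    def test_all_clean_retained(self):
        ep = _epochset(np.zeros((10, 3000)))
        assert reject_artifacts(ep).n_epochs == 10

    def test_exact_count_removed(self):
        data = np.zeros((20, 3000))
        bad = [2, 7, 13]
        data[bad, 1500] = 100.0
        kept = reject_artifacts(_epochset(data))
        assert kept.n_epochs == 17

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 15, size=(50, 100))
        strict = reject_artifacts(_epochset(data, window=(-5, 5)), 35.0)
        loose = reject_artifacts(_epochset(data, window=(-5, 5)), 70.0)
        assert strict.n_epochs <= loose.n_epochs

    def test_all_rejected_errors(self):
        data = np.full((3, 3000), 50.0)
        with pytest.raises(ValueError, match="all epochs rejected"):
            reject_artifacts(_epochset(data))


class TestBaseline:
    def test_constant_offset_removed_exactly(self):
        data = np.full((4, 3000), 3.25)
        out = baseline_correct(_epochset(data))
        assert np.array_equal(out.epochs, np.zeros((4, 3000)))

    def test_zero_mean_baseline_unchanged(self):
        data = np.zeros((2, 3000))
        data[:, 500:] = 1.0  # post-onset only; 50 ms baseline = first 500 samples
        out = baseline_correct(_epochset(data))
        assert np.array_equal(out.epochs, data)

    def test_random_epochs_baseline_zeroed(self):
        rng = np.random.default_rng(0)
        out = baseline_correct(_epochset(rng.normal(size=(8, 3000))))
        assert np.allclose(out.epochs[:, :500].mean(axis=1), 0.0, atol=1e-12)


class TestPolarityAndAverage:
    def test_balanced_counts_unchanged(self):
        ep = _epochset(np.zeros((10, 3000)))
        assert equalize_polarity(ep, 0) is ep

    def test_subsampling_hits_larger_class(self):
        pol = np.array([1] * 16 + [-1] * 15)
        ep = _epochset(np.zeros((31, 3000)), polarity=pol)
        out = equalize_polarity(ep, rng_seed=1)
        assert out.counts() == (15, 15)

    def test_subsampling_deterministic(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(25, 100))
        pol = np.array([1] * 13 + [-1] * 12)
        a = equalize_polarity(_epochset(data, pol, window=(-5, 5)), rng_seed=7)
        b = equalize_polarity(_epochset(data, pol, window=(-5, 5)), rng_seed=7)
        assert np.array_equal(a.epochs, b.epochs)

    def test_missing_polarity_errors(self):
        ep = _epochset(np.zeros((4, 3000)), polarity=[1, 1, 1, 1])
        with pytest.raises(ValueError, match="both polarities"):
            equalize_polarity(ep)

    def test_average_of_identical_epochs(self):
        row = np.sin(np.arange(3000) / 50.0)
        ep = _epochset(np.tile(row, (6, 1)))
        assert np.allclose(average_ffr(ep).samples, row)

    def test_polarity_following_component_cancels(self):
        row = np.sin(np.arange(3000) / 10.0)
        pol = np.resize([1, -1], 10)
        data = np.outer(pol, row)
        ffr = average_ffr(_epochset(data, pol))
        assert np.max(np.abs(ffr.samples)) < 1e-12

    def test_epoch_bookkeeping_full_session(self):
        # 1500 per polarity with no rejections -> 3000 averaged
        pol = np.resize([1, -1], 3000)
        ep = _epochset(np.zeros((3000, 100)), polarity=pol, window=(-5, 5))
        assert average_ffr(ep).n_epochs_averaged == 3000

    def test_unbalanced_average_rejected(self):
        ep = _epochset(np.zeros((3, 3000)), polarity=[1, 1, -1])
        with pytest.raises(ValueError, match="polarity counts"):
            average_ffr(ep)


class TestFullChain:
    def test_recovers_invariant_component(self, piano_stim, flat_truth):
        cfg = SimulationConfig(epochs_per_polarity=150, artifact_rate=0.0,
                               noise_sd_uV=0.5, rng_seed=7)
        rec = simulate_subject_recording(piano_stim, flat_truth, cfg)
        ffr = preprocess_recording(rec)
        # injected polarity-invariant component, aligned for detection latency
        t = np.arange(piano_stim.n_samples) / piano_stim.sample_rate
        neural = sum(np.sin(2 * np.pi * k * piano_stim.f0 * t)
                     for k in piano_stim.harmonic_set)
        neural = neural / np.abs(neural).max()
        onsets = detect_onsets(rec.audio, sample_rate=rec.sample_rate)
        lag = onsets[0] - rec.true_onsets[0]
        i0 = int(round(50 / 1000 * rec.sample_rate)) - lag
        seg = ffr.samples[i0 : i0 + piano_stim.n_samples]
        assert np.corrcoef(seg, neural)[0, 1] > 0.95

    def test_deterministic(self, small_recording):
        rec, _ = small_recording
        a = preprocess_recording(rec, rng_seed=5)
        b = preprocess_recording(rec, rng_seed=5)
        assert np.array_equal(a.samples, b.samples)
        assert a.n_epochs_averaged == b.n_epochs_averaged

    def test_rejection_removes_injected_artifacts(self, small_recording):
        rec, cfg = small_recording
        filt = bandpass_and_notch(rec)
        onsets = detect_onsets(filt.audio, sample_rate=rec.sample_rate)
        ep = epoch(filt, onsets)
        kept = reject_artifacts(ep)
        assert ep.n_epochs - kept.n_epochs == len(rec.artifact_presentations)
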