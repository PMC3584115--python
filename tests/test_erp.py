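"""Preprocessing chain: artifact screens, ocular regression, epoching,
frequency-domain filtering, and end-to-end ground-truth recovery."""

import numpy as np
import pytest

from gate50 import (
    ClickProtocol,
    RawRecording,
    SubjectTruth,
    average_and_filter,
    bandpass_frequency_domain,
    correct_eog,
    epoch,
    flag_online_artifacts,
    preprocess,
    reject_epochs,
    synthesize_eeg,
)
from gate50.erp import EpochSet
from gate50.errors import PipelineError


def make_recording(n_ms=30000, events=(5000, 15000, 25000), noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    cz = rng.standard_normal(n_ms) * noise
    eog = rng.standard_normal(n_ms) * noise
    return RawRecording(
        np.vstack([cz, eog]), 1000.0, ["Cz", "EOG"],
        np.array(events, dtype=float),
    )


class TestOnlineFlagging:
    def test_threshold_is_exclusive_at_100(self):
        rec = make_recording()
        rec.samples[0, 5200] = 99.9
        flags, _ = flag_online_artifacts(rec)
        assert not flags.any()
        rec.samples[0, 5200] = 150.0  # +200 ms into trial 0
        flags, reasons = flag_online_artifacts(rec)
        assert flags.tolist() == [True, False, False]
        assert reasons[0] == "online_artifact"

    def test_eog_channel_also_screened(self):
        rec = make_recording()
        rec.samples[1, 15100] = -130.0
        flags, _ = flag_online_artifacts(rec)
        assert flags.tolist() == [False, True, False]

    def test_out_of_bounds_trial(self):
        rec = make_recording(events=(50, 15000))
        flags, reasons = flag_online_artifacts(rec)
        assert flags[0] and reasons[0] == "out_of_bounds"

    def test_injected_artifacts_flagged_exactly(self):
        truth = SubjectTruth(true_s1_amp=2.0, true_s2_amp=1.0, noise_sd=3.0,
                             blink_rate=0.0, artifact_rate=2.0)
        rec = synthesize_eeg(truth, ClickProtocol(n_pairs=60), seed=9)
        injected = rec.meta["artifact_trials"]
        assert injected  # the session actually contains artifacts
        flags, _ = flag_online_artifacts(rec)
        assert sorted(np.nonzero(flags)[0].tolist()) == sorted(injected)


class TestEOGCorrection:
    def test_exact_linear_contamination_removed(self):
        rng = np.random.default_rng(1)
        signal = rng.standard_normal(20000)
        eogv = rng.standard_normal(20000) * 30
        # orthogonalize so the fitted slope is exactly the injected one
        ec = eogv - eogv.mean()
        signal = signal - (signal @ ec) / (ec @ ec) * ec
        rec = RawRecording(np.vstack([signal + 0.2 * eogv, eogv]), 1000.0,
                           ["Cz", "EOG"], np.array([5000.0]))
        out = correct_eog(rec)
        assert np.allclose(out.channel("Cz"), signal, atol=1e-8)
        assert np.array_equal(out.channel("EOG"), eogv)

    def test_zero_eog_is_identity(self):
        rec = make_recording(noise=1.0, seed=3)
        rec.samples[1] = 0.0
        with pytest.warns(UserWarning):
            out = correct_eog(rec)
        assert np.array_equal(out.channel("Cz"), rec.channel("Cz"))

    def test_random_slope_recovered_within_1pct(self):
        rng = np.random.default_rng(5)
        b = rng.uniform(0.05, 0.5)
        eogv = rng.standard_normal(60000) * 50
        cz = rng.standard_normal(60000) + b * eogv
        rec = RawRecording(np.vstack([cz, eogv]), 1000.0, ["Cz", "EOG"],
                           np.array([5000.0]))
        out = correct_eog(rec)
        b_hat = out.meta["eog_slopes"][0]
        assert b_hat == pytest.approx(b, rel=0.01)


class TestEpoching:
    def test_120_clean_pairs_give_1024_sample_epochs(self):
        truth = SubjectTruth(noise_sd=1.0, blink_rate=0.0, artifact_rate=0.0)
        rec = synthesize_eeg(truth, ClickProtocol(n_pairs=120), seed=2)
        eps = epoch(rec)
        assert eps.epochs.shape == (120, 1024)
        assert eps.n_retained == 120

    def test_early_onset_excluded(self):
        rec = make_recording(events=(50, 15000))
        eps = epoch(rec)
        assert not eps.retained[0] and eps.reasons[0] == "out_of_bounds"

    def test_constant_recording_gives_constant_epochs(self):
        rec = make_recording()
        rec.samples[0] = 7.0
        eps = epoch(rec)
        assert np.all(eps.epochs[eps.retained] == 7.0)

    def test_no_usable_trials_errors(self):
        rec = make_recording()
        rec.samples[0] = 200.0
        with pytest.raises(PipelineError, match="no_usable_trials"):
            epoch(rec)

    def test_manual_exclusion_list(self):
        rec = make_recording()
        eps = epoch(rec, exclude_trials=[1])
        assert not eps.retained[1] and eps.reasons[1] == "manual"


class TestOfflineRejection:
    def _epochs(self, peaks):
        data = np.zeros((len(peaks), 1024))
        for i, v in enumerate(peaks):
            data[i, 500] = v
        return EpochSet(data, (-100, 923), 1000.0,
                        np.ones(len(peaks), bool), [None] * len(peaks))

    def test_threshold_is_exclusive_at_50(self):
        out = reject_epochs(self._epochs([50.0, 50.1, -50.1, 10.0]))
        assert out.retained.tolist() == [True, False, False, True]
        assert out.reasons[1] == "offline_artifact"

    def test_all_within_threshold_unchanged(self):
        eps = self._epochs([10.0, -20.0])
        out = reject_epochs(eps)
        assert out.retained.all()

    def test_rejection_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        eps = self._epochs(rng.uniform(-80, 80, 60))
        counts = [reject_epochs(eps, thr).n_retained
                  for thr in (79.0, 60.0, 45.0, 30.0)]
        assert counts == sorted(counts, reverse=True)

    def test_all_rejected_errors(self):
        with pytest.raises(PipelineError, match="no_usable_trials"):
            reject_epochs(self._epochs([60.0, 70.0]))


class TestFilter:
    def test_passband_center_gain(self):
        t = np.arange(1024) / 1000.0
        x = np.sin(2 * np.pi * 30 * t)
        y = bandpass_frequency_domain(x, 1000.0)
        assert np.abs(y).max() >= 0.99 * np.abs(x).max()

    def test_stopband_gain(self):
        t = np.arange(1024) / 1000.0
        # tone on the DFT bin nearest 5 Hz, so the window is periodic and
        # the measured attenuation reflects the filter rather than leakage
        f = round(5 * 1024 / 1000) * 1000 / 1024
        x = np.sin(2 * np.pi * f * t)
        y = bandpass_frequency_domain(x, 1000.0)
        assert np.abs(y).max() <= 0.01 * np.abs(x).max()

    def test_linearity(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal(1024), rng.standard_normal(1024)
        a, b = 2.3, -0.7
        lhs = bandpass_frequency_domain(a * x + b * y, 1000.0)
        rhs = a * bandpass_frequency_domain(x, 1000.0) \
            + b * bandpass_frequency_domain(y, 1000.0)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_average_then_filter_commutes(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((8, 1024)) * 5
        eps = EpochSet(data, (-100, 923), 1000.0, np.ones(8, bool), [None] * 8)
        erp = average_and_filter(eps)
        per_trial = np.mean(
            [bandpass_frequency_domain(tr, 1000.0) for tr in data], axis=0
        )
        assert np.allclose(erp.waveform, per_trial, atol=1e-10)

    def test_opposite_epochs_cancel(self):
        x = np.random.default_rng(5).standard_normal(1024)
        eps = EpochSet(np.vstack([x, -x]), (-100, 923), 1000.0,
                       np.ones(2, bool), [None, None])
        erp = average_and_filter(eps)
        assert np.allclose(erp.waveform, 0.0, atol=1e-12)


class TestEndToEndRecovery:
    def test_noise_free_ground_truth(self, clean_result):
        result, erp, epochs = clean_result
        assert epochs.n_retained == 120
        assert result.valid
        assert abs(result.s1_latency_ms - 60.0) <= 2.0
        assert result.s1_uv == pytest.approx(2.0, rel=0.10)
        assert result.s2_uv == pytest.approx(1.0, rel=0.10)
        assert result.ratio == pytest.approx(0.5, abs=0.05)

    def test_recovery_across_latencies(self):
        for latency in (50.0, 68.0):
            truth = SubjectTruth(true_s1_amp=3.0, true_s2_amp=0.9,
                                 true_s1_latency=latency, noise_sd=0.0,
                                 blink_rate=0.0, artifact_rate=0.0)
            rec = synthesize_eeg(truth, ClickProtocol(n_pairs=30), seed=8)
            erp, _ = preprocess(rec)
            from gate50 import measure_pair
            r = measure_pair(erp, 0.0, 500.0)
            assert abs(r.s1_latency_ms - latency) <= 2.0
            assert r.s1_uv == pytest.approx(3.0, rel=0.10)
            assert r.ratio == pytest.approx(0.3, abs=0.05)
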