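import numpy as np
import pytest
from scipy import signal

from tbrloop.io import EEGRecording
from tbrloop.mr import (ArtifactOccurrences, TemplateParams, build_template,
                        clean_mr_pipeline, detect_qrs, lowpass_downsample,
                        subtract_artifact)
from tbrloop.synth import (AttentionParams, MRContaminationParams, SynthEEGParams,
                           contaminate_mr, simulate_attention_trace, synthesize_eeg)

CHS = ["Fz", "Cz", "Pz", "T7", "ECG"]


def make_contaminated(seed=3, duration=70.0, **mr_kwargs):
    p = SynthEEGParams(theta_amp=40, alpha_amp=18, beta_amp=15, pink_amp=8,
                       heart_rate=70, blink_amp=0, phase_drift=4.0)
    tr = simulate_attention_trace(duration, 10, seed=seed + 100)
    rec = synthesize_eeg(tr, CHS, 500.0, p, seed=seed + 200)
    return contaminate_mr(rec, MRContaminationParams(**mr_kwargs), seed=seed)


def bandpass_1_40(x, fs=500.0):
    sos = signal.butter(4, [1, 40], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


class TestBuildTemplate:
    def test_hand_evaluated_trim(self):
        epochs = np.array([[10.0], [0.0], [3.0], [100.0], [5.0]])
        np.testing.assert_allclose(build_template(epochs, K=1), [6.0])

    def test_k0_is_plain_mean(self, rng):
        epochs = rng.standard_normal((7, 20))
        np.testing.assert_allclose(build_template(epochs, 0), epochs.mean(axis=0))

    def test_identical_epochs(self, rng):
        e = rng.standard_normal(15)
        epochs = np.tile(e, (6, 1))
        np.testing.assert_allclose(build_template(epochs, 2), e)

    def test_requires_l_gt_2k(self, rng):
        with pytest.raises(ValueError):
            build_template(rng.standard_normal((4, 5)), K=2)

    def test_breakdown_robustness(self, rng):
        """Replacing up to K epochs with huge outliers moves the template no
        more than replacing them with the max of the remaining values."""
        base = rng.standard_normal((10, 30))
        t0 = build_template(base, K=2)
        corrupted = base.copy()
        corrupted[:2] = 1e6
        bounded = base.copy()
        bounded[:2] = base[2:].max(axis=0)
        t_corr = build_template(corrupted, K=2)
        t_bound = build_template(bounded, K=2)
        assert (np.abs(t_corr - t0) <= np.abs(t_bound - t0) + 1e-9).all()


class TestSubtractArtifact:
    def test_pure_periodic_artifact_removed(self):
        sfreq, period, n_occ = 500.0, 0.5, 40
        tmpl = np.sin(2 * np.pi * np.arange(int(period * sfreq)) / 25.0) * 100
        n = int(n_occ * period * sfreq)
        data = np.tile(tmpl, n_occ)[None, :]
        rec = EEGRecording(data.copy(), sfreq, ["Fz"], ["eeg"])
        occ = ArtifactOccurrences(np.arange(n_occ) * period, len(tmpl))
        out = subtract_artifact(rec, occ, TemplateParams(L=30, K=6))
        assert np.sqrt((out.data ** 2).mean()) < 0.01 * np.sqrt((data ** 2).mean())

    def test_outlier_epoch_does_not_pollute_neighbors(self, rng):
        """Once an epoch is extreme enough to be trimmed everywhere, making it
        arbitrarily more extreme cannot change any template (bounded
        influence of the trimmed mean)."""
        sfreq, period, n_occ = 500.0, 0.5, 45
        plen = int(period * sfreq)
        tmpl = rng.standard_normal(plen) * 50
        eeg = rng.standard_normal((1, n_occ * plen)) * 5
        base = eeg + np.tile(tmpl, n_occ)[None, :]
        mild = base.copy()
        mild[0, 20 * plen:21 * plen] += 1e4     # movement-like offset, 50x RMS
        wild = base.copy()
        wild[0, 20 * plen:21 * plen] += 1e7
        occ = ArtifactOccurrences(np.arange(n_occ) * period, plen)
        params = TemplateParams(L=30, K=6)
        out_mild = subtract_artifact(
            EEGRecording(mild.copy(), sfreq, ["Fz"], ["eeg"]), occ, params)
        out_wild = subtract_artifact(
            EEGRecording(wild.copy(), sfreq, ["Fz"], ["eeg"]), occ, params)
        # every non-outlier epoch cleaned identically regardless of magnitude
        probe = np.r_[0:20 * plen, 21 * plen:n_occ * plen]
        np.testing.assert_allclose(out_wild.data[0, probe],
                                   out_mild.data[0, probe], atol=1e-9)
        # and with K = 0 (plain mean) the same corruption does propagate
        p0 = TemplateParams(L=30, K=0)
        m0 = subtract_artifact(
            EEGRecording(mild.copy(), sfreq, ["Fz"], ["eeg"]), occ, p0)
        w0 = subtract_artifact(
            EEGRecording(wild.copy(), sfreq, ["Fz"], ["eeg"]), occ, p0)
        assert not np.allclose(w0.data[0, probe], m0.data[0, probe], atol=1e-3)

    def test_too_few_occurrences(self, rng):
        rec = EEGRecording(rng.standard_normal((1, 1000)), 100.0, ["Fz"], ["eeg"])
        occ = ArtifactOccurrences(np.arange(5, dtype=float), 50)
        with pytest.raises(ValueError, match="L="):
            subtract_artifact(rec, occ, TemplateParams(L=30, K=6))


class TestLowpassDownsample:
    def _rec(self, freq, sfreq=5000.0, dur=4.0):
        t = np.arange(int(dur * sfreq)) / sfreq
        return EEGRecording(np.sin(2 * np.pi * freq * t)[None, :], sfreq,
                            ["Fz"], ["eeg"])

    def test_passband_amplitude(self):
        out = lowpass_downsample(self._rec(30.0))
        mid = out.data[0, 200:-200]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.02)

    def test_stopband_attenuation(self):
        out = lowpass_downsample(self._rec(120.0))
        rms_in = 1 / np.sqrt(2)
        rms_out = np.sqrt((out.data[0, 200:-200] ** 2).mean())
        assert rms_out < 0.01 * rms_in

    def test_output_rate_and_annotations(self):
        rec = self._rec(10.0)
        rec.annotations.append((1.0, 0.5, "mark"))
        out = lowpass_downsample(rec)
        assert out.sfreq == 500.0
        assert out.annotations[-1] == (1.0, 0.5, "mark")

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            lowpass_downsample(self._rec(10.0, sfreq=1250.0))

    def test_cutoff_above_target_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_downsample(self._rec(10.0), cutoff=300.0)


class TestDetectQRS:
    def _ecg(self, bpm=60, dur=60.0, sfreq=500.0, seed=0):
        tr = simulate_attention_trace(dur, 10, AttentionParams(0.5, 0.0, 0.0), 0)
        rec = synthesize_eeg(tr, CHS, sfreq,
                             SynthEEGParams(heart_rate=bpm, blink_amp=0),
                             seed=seed)
        return rec.pick("ECG"), rec.metadata["r_peaks"]

    def test_peak_count_60bpm(self):
        ecg, truth = self._ecg(60)
        peaks = detect_qrs(ecg, 500.0)
        assert abs(len(peaks) - 60) <= 1

    def test_timing_accuracy(self):
        ecg, truth = self._ecg(75, seed=2)
        peaks = detect_qrs(ecg, 500.0)
        hits = sum(np.min(np.abs(peaks - t)) < 0.020 for t in truth)
        assert hits / len(truth) >= 0.99

    def test_polarity_robust(self):
        ecg, _ = self._ecg(75, seed=3)
        a = detect_qrs(ecg, 500.0)
        b = detect_qrs(-ecg, 500.0)
        assert len(a) == len(b)
        np.testing.assert_allclose(a, b, atol=0.02)

    def test_flat_signal_raises(self):
        with pytest.raises(ValueError, match="flat|beats"):
            detect_qrs(np.zeros(5000), 500.0)


class TestFullPipeline:
    def test_injection_recovery(self):
        cont, clean, ev = make_contaminated(seed=3)
        cleaned, qc = clean_mr_pipeline(cont, cont.metadata["tr_onsets"], 1.760)
        ref = lowpass_downsample(clean)
        edge = 3000
        corrs = []
        for i in range(4):
            a = bandpass_1_40(cleaned.data[i][edge:-edge])
            b = bandpass_1_40(ref.data[i][edge:-edge])
            corrs.append(np.corrcoef(a, b)[0, 1])
        assert np.mean(corrs) >= 0.95
        # harmonic-excess power at TR harmonics drops >= 20 dB
        post = max(qc["tr_harmonic_power_post"],
                   1e-4 * qc["tr_harmonic_power_pre"])
        assert 10 * np.log10(qc["tr_harmonic_power_pre"] / post) >= 20.0

    def test_null_contamination_matches_downsample(self):
        cont, clean, ev = make_contaminated(seed=4, gradient_amp=0.0, bcg_amp=0.0)
        cleaned, _ = clean_mr_pipeline(cont, cont.metadata["tr_onsets"], 1.760)
        ref = lowpass_downsample(clean)
        edge = 2000
        for i in range(4):
            resid = cleaned.data[i][edge:-edge] - ref.data[i][edge:-edge]
            # only the trimmed-mean EEG leak remains (no artifact energy)
            assert (resid ** 2).mean() < 0.2 * (ref.data[i][edge:-edge] ** 2).mean()

    def test_qc_reports_params(self):
        cont, clean, ev = make_contaminated(seed=5, duration=65.0)
        _, qc = clean_mr_pipeline(cont, cont.metadata["tr_onsets"], 1.760)
        assert qc["gradient_params"] == {"L": 30, "K": 6}
        assert qc["pulse_params"] == {"L": 40, "K": 5}
        assert qc["target_sfreq_hz"] == 500.0

    def test_ecg_channel_not_pulse_subtracted(self):
        cont, clean, ev = make_contaminated(seed=6)
        cleaned, _ = clean_mr_pipeline(cont, cont.metadata["tr_onsets"], 1.760)
        # re-detect on the output ECG: identical peaks (channel untouched
        # after gradient cleaning + downsampling)
        ecg = cleaned.pick("ECG")
        peaks = detect_qrs(ecg, 500.0)
        np.testing.assert_allclose(peaks, cleaned.metadata["r_peaks"], atol=1e-9)

    def test_missing_markers(self):
        cont, clean, ev = make_contaminated(seed=7, duration=65.0)
        with pytest.raises(ValueError, match="TR"):
            clean_mr_pipeline(cont, [], 1.760)
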