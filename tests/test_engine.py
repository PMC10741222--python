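import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tbrloop.engine import (CalibrationBounds, CalibrationError, EngineConfig,
                            TBRSample, TBRStream, average_reference, band_power,
                            calibrate, gate_muscle, normalize, stream_tbr)
from tbrloop.synth import (AttentionParams, SynthEEGParams, inject_muscle_bursts,
                           simulate_attention_trace, synthesize_eeg)

CHS = ["Fz", "Cz", "Pz", "T7", "ECG"]


def dft_band_power_oracle(x, sfreq, band):
    """Independent brute-force DFT with explicit basis vectors."""
    x = np.asarray(x, float)
    n = len(x)
    w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / (n - 1))  # Hanning
    xw = w * x
    total = 0.0
    for k in range(n // 2 + 1):
        f = k * sfreq / n
        if band[0] <= f <= band[1]:
            basis = np.exp(-2j * np.pi * k * np.arange(n) / n)
            coef = np.sum(xw * basis)
            p = abs(coef) ** 2 / w.sum() ** 2
            if 0 < k < n / 2:
                p *= 2
            total += p
    return total


class TestAverageReference:
    def test_two_channel_antisymmetric_unchanged(self):
        w = np.array([[1.0, 1.0], [-1.0, -1.0]])
        out = average_reference(w, ["eeg", "eeg"])
        np.testing.assert_allclose(out, w)

    def test_common_mode_removed(self):
        w = np.full((4, 10), 3.7)
        out = average_reference(w, ["eeg"] * 4)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_random_matrix_zero_mean(self, rng):
        w = rng.standard_normal((31, 1500))
        out = average_reference(w, ["eeg"] * 31)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)

    def test_ecg_untouched(self, rng):
        w = rng.standard_normal((3, 100))
        out = average_reference(w, ["eeg", "eeg", "ecg"])
        np.testing.assert_array_equal(out[2], w[2])

    def test_needs_two_eeg(self, rng):
        with pytest.raises(ValueError):
            average_reference(rng.standard_normal((2, 10)), ["eeg", "ecg"])


class TestBandPower:
    def test_pure_theta_sine_ratio(self):
        t = np.arange(1500) / 500.0
        x = 10 * np.sin(2 * np.pi * 6 * t)
        theta = band_power(x, 500.0, (4, 7.5))
        beta = band_power(x, 500.0, (13, 19))
        assert theta / max(beta, 1e-30) > 100

    def test_zero_signal(self):
        assert band_power(np.zeros(1500), 500.0, (4, 7.5)) == 0.0

    def test_equal_amplitude_tones_equal_power(self):
        t = np.arange(1500) / 500.0
        x = 5 * np.sin(2 * np.pi * 6 * t) + 5 * np.sin(2 * np.pi * 16 * t)
        theta = band_power(x, 500.0, (4, 7.5))
        beta = band_power(x, 500.0, (13, 19))
        assert theta == pytest.approx(beta, rel=0.05)

    def test_matches_dft_oracle(self, rng):
        x = rng.standard_normal(750)
        for band in [(4, 7.5), (13, 19)]:
            assert band_power(x, 250.0, band) == pytest.approx(
                dft_band_power_oracle(x, 250.0, band), rel=1e-9)

    def test_band_above_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(np.zeros(100), 100.0, (40, 60))


class TestGate:
    def test_fires_above_threshold(self):
        assert gate_muscle(4.0, 1.0)

    def test_boundary_strict(self):
        assert not gate_muscle(3.0, 1.0)

    def test_burst_gates_overlapping_windows(self):
        trace = simulate_attention_trace(20, 10,
                                         AttentionParams(0.5, volatility=0.0), 0)
        chs = ["Fz", "F3", "F4", "Cz", "Pz", "Oz", "C3", "T7", "ECG"]
        rec = synthesize_eeg(trace, chs, 500.0, SynthEEGParams(blink_amp=0), seed=3)
        rec = inject_muscle_bursts(rec, [(8.0, 3.0)], ["T7"], 200.0,
                                   band=(14.0, 100.0), seed=4)
        samples = stream_tbr(rec)
        for s in samples:
            overlaps = (s.t - 3.0) < 11.0 and s.t > 8.0
            if overlaps:
                assert s.gated, f"window ending {s.t} should be gated"
            elif s.t <= 7.0 or s.t - 3.0 >= 12.0:
                assert not s.gated, f"window ending {s.t} should be clean"


class TestStreamTBR:
    def test_sample_count_and_times(self, rng):
        from tbrloop.io import EEGRecording
        rec = EEGRecording(rng.standard_normal((5, 5000)), 500.0, CHS,
                           ["eeg"] * 4 + ["ecg"])
        samples = stream_tbr(rec)
        assert len(samples) == 8
        np.testing.assert_allclose([s.t for s in samples], np.arange(3, 11))

    def test_stationary_signal_stable_ratio(self):
        # deterministic constant-amplitude oscillators -> near-constant ratio
        tr = simulate_attention_trace(15, 10, AttentionParams(0.5, volatility=0.0), 0)
        rec = synthesize_eeg(tr, CHS, 500.0,
                             SynthEEGParams(pink_amp=0, blink_amp=0, phase_drift=0),
                             seed=6)
        samples = stream_tbr(rec)
        raws = np.array([s.tbr_raw for s in samples])
        assert raws.std() / raws.mean() < 0.10

    def test_chunked_equals_batch(self, constant_attention_recording):
        rec = constant_attention_recording
        batch = stream_tbr(rec)
        stream = TBRStream(rec.sfreq, rec.ch_names, rec.ch_roles)
        chunked = []
        for i in range(rec.n_samples):
            chunked.extend(stream.push(rec.data[:, i:i + 1]))
        assert len(batch) == len(chunked)
        for a, b in zip(batch, chunked):
            assert a.t == b.t
            assert a.theta_power == pytest.approx(b.theta_power, rel=1e-12)
            assert a.tbr_raw == pytest.approx(b.tbr_raw, rel=1e-12)

    def test_oracle_equivalence_per_window(self, constant_attention_recording):
        rec = constant_attention_recording
        samples = stream_tbr(rec)
        fz = rec.ch_names.index("Fz")
        for s in samples[:5]:
            end = int(round(s.t * rec.sfreq))
            win = rec.data[:, end - 1500:end]
            ref = average_reference(win, rec.ch_roles)
            assert s.theta_power == pytest.approx(
                dft_band_power_oracle(ref[fz], 500.0, (4, 7.5)), rel=1e-6)
            assert s.beta_power == pytest.approx(
                dft_band_power_oracle(ref[fz], 500.0, (13, 19)), rel=1e-6)

    def test_missing_channel(self, rng):
        from tbrloop.io import EEGRecording
        rec = EEGRecording(rng.standard_normal((3, 5000)), 500.0,
                           ["Cz", "Pz", "Oz"], ["eeg"] * 3)
        with pytest.raises(KeyError):
            stream_tbr(rec)

    def test_too_short(self, rng):
        from tbrloop.io import EEGRecording
        rec = EEGRecording(rng.standard_normal((5, 1000)), 500.0, CHS,
                           ["eeg"] * 4 + ["ecg"])
        with pytest.raises(ValueError, match="shorter"):
            stream_tbr(rec)

    def test_monotone_chain_attention_vs_tbr(self):
        """Raw TBR decreases and nfb increases with latent attention."""
        levels = np.linspace(0.05, 0.95, 10)
        means = []
        bounds = CalibrationBounds(1.0, 4.0, 10, 0)
        nfbs = []
        for i, a in enumerate(levels):
            tr = simulate_attention_trace(10, 10,
                                          AttentionParams(a, volatility=0.0), 0)
            rec = synthesize_eeg(tr, CHS, 500.0, SynthEEGParams(blink_amp=0), seed=5)
            samples = stream_tbr(rec, bounds=bounds)
            means.append(np.mean([s.tbr_raw for s in samples]))
            nfbs.append(np.mean([s.nfb for s in samples]))
        from scipy.stats import spearmanr
        rho_tbr = spearmanr(levels, means).statistic
        rho_nfb = spearmanr(levels, nfbs).statistic
        assert rho_tbr < -0.9
        assert rho_nfb > 0.9


def _mk(vals, gated=None):
    gated = gated or [False] * len(vals)
    return [TBRSample(t=float(i), theta_power=1, beta_power=1, tbr_raw=v, gated=g)
            for i, (v, g) in enumerate(zip(vals, gated))]


class TestCalibrate:
    def test_hand_computed_bounds(self):
        b = calibrate(_mk([1, 2, 3, 4, 5, 6, 7, 8]))
        assert b.tbr_min == 1
        assert b.tbr_max == pytest.approx(7.5)   # mean of top ceil(8/4)=2

    def test_gated_removed_then_insufficient(self):
        samples = _mk([5.0] + [9.0] * 10, gated=[False] + [True] * 10)
        with pytest.raises(CalibrationError):
            calibrate(samples)

    def test_permutation_invariance(self, rng):
        vals = rng.uniform(0.5, 6.0, 40)
        b1 = calibrate(_mk(list(vals)))
        b2 = calibrate(_mk(list(rng.permutation(vals))))
        assert b1.tbr_min == b2.tbr_min
        assert b1.tbr_max == pytest.approx(b2.tbr_max)

    @given(st.lists(st.floats(0.01, 100.0), min_size=4, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_matches_sort_rule(self, vals):
        b = calibrate(_mk(vals))
        arr = np.sort(vals)
        top = int(np.ceil(len(arr) / 4))
        assert b.tbr_min == pytest.approx(arr[0])
        assert b.tbr_max == pytest.approx(arr[-top:].mean())


class TestNormalize:
    BOUNDS = CalibrationBounds(1.0, 3.0, 10, 0)

    def test_endpoints(self):
        assert normalize(1.0, self.BOUNDS) == 1.0
        assert normalize(3.0, self.BOUNDS) == 0.0

    def test_midpoint(self):
        assert normalize(2.0, self.BOUNDS) == pytest.approx(0.5)

    def test_clipping(self):
        assert normalize(0.0, self.BOUNDS) == 1.0
        assert normalize(10.0, self.BOUNDS) == 0.0

    def test_degenerate_bounds_warn(self):
        with pytest.warns(UserWarning):
            assert normalize(2.0, CalibrationBounds(2.0, 2.0, 4, 0)) == 0.5

    @given(st.floats(1.0, 3.0), st.floats(1.0, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing(self, a, b):
        if a < b:
            assert normalize(a, self.BOUNDS) >= normalize(b, self.BOUNDS)
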