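"""Offline removal of MR gradient and cardioballistic artifacts.

The core primitive is a hybrid mean/median moving-template subtraction:
for each artifact occurrence and each template time point, the values of
the L temporally neighbouring occurrences are sorted, the K smallest and
K largest are discarded, and the remaining L-2K are averaged. Defaults:
(L=30, K=6) for gradient artifacts epoch-locked to TR markers, (L=40,
K=5) for pulse artifacts locked to detected R-peaks. The full chain runs
gradient subtraction -> 70 Hz FIR low-pass -> downsample to 500 Hz -> QRS
detection -> pulse subtraction, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EEGRecording

__all__ = [
    "TemplateParams",
    "ArtifactOccurrences",
    "build_template",
    "subtract_artifact",
    "lowpass_downsample",
    "detect_qrs",
    "clean_mr_pipeline",
]


@dataclass(frozen=True)
class TemplateParams:
    L: int
    K: int

    def __post_init__(self):
        if not (self.L > 2 * self.K >= 0):
            raise ValueError("require L > 2K >= 0")


GRADIENT_PARAMS = TemplateParams(L=30, K=6)
PULSE_PARAMS = TemplateParams(L=40, K=5)


@dataclass(frozen=True)
class ArtifactOccurrences:
    onsets: np.ndarray   # seconds
    epoch_len: int       # samples

    def __post_init__(self):
        object.__setattr__(self, "onsets", np.asarray(self.onsets, dtype=float))
        if np.any(np.diff(self.onsets) < 0):
            raise ValueError("onsets must be sorted")
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")


def build_template(epochs: np.ndarray, K: int) -> np.ndarray:
    """Trimmed-mean template over the leading axis.

    ``epochs`` is (L, n) — or (L, channels, n); sorting and trimming happen
    independently per time point.
    """
    epochs = np.asarray(epochs, dtype=float)
    L = epochs.shape[0]
    if not L > 2 * K:
        raise ValueError(f"need L > 2K (L={L}, K={K})")
    s = np.sort(epochs, axis=0)
    if K:
        s = s[K:L - K]
    return s.mean(axis=0)


def _neighbor_slices(n_occ: int, L: int) -> list[slice]:
    """For each occurrence, the window of its L nearest occurrences
    (centered, shifted inward at the edges)."""
    half = L // 2
    out = []
    for i in range(n_occ):
        a = min(max(i - half, 0), n_occ - L)
        out.append(slice(a, a + L))
    return out


def subtract_artifact(rec: EEGRecording, occ: ArtifactOccurrences,
                      params: TemplateParams,
                      channels: np.ndarray | None = None) -> EEGRecording:
    """Subtract a moving trimmed-mean template at every occurrence.

    Each occurrence's template is built from its L temporally nearest
    occurrences. ``channels`` restricts the cleaned rows (e.g. to exclude
    the ECG during pulse subtraction); default: all channels.
    """
    n_occ = len(occ.onsets)
    if n_occ < params.L:
        raise ValueError(f"need at least L={params.L} occurrences, got {n_occ}")
    out = rec.copy()
    rows = np.arange(rec.n_channels) if channels is None else np.asarray(channels)
    starts = np.round(occ.onsets * rec.sfreq).astype(int)
    # stack all full epochs once: (n_occ, n_rows, epoch_len)
    epochs = np.zeros((n_occ, len(rows), occ.epoch_len))
    valid = np.zeros(n_occ, dtype=bool)
    for j, s0 in enumerate(starts):
        if s0 < 0 or s0 + occ.epoch_len > rec.n_samples:
            continue  # partial edge epoch: excluded from templates, not cleaned
        valid[j] = True
        epochs[j] = rec.data[rows, s0:s0 + occ.epoch_len]
    vidx = np.flatnonzero(valid)
    if len(vidx) < params.L:
        raise ValueError("fewer than L complete artifact epochs inside the recording")
    slices = _neighbor_slices(len(vidx), params.L)
    for k, j in enumerate(vidx):
        neigh = epochs[vidx[slices[k]]]
        template = build_template(neigh, params.K)
        s0 = starts[j]
        out.data[rows[:, None], np.arange(s0, s0 + occ.epoch_len)] -= template
    return out


def lowpass_downsample(rec: EEGRecording, cutoff: float = 70.0,
                       target_sfreq: float = 500.0,
                       stop_atten_db: float = 60.0,
                       transition_hz: float = 30.0) -> EEGRecording:
    """Zero-phase FIR low-pass then integer-factor decimation.

    The filter is a Kaiser-designed linear-phase FIR applied by centered
    FFT convolution (symmetric taps -> zero phase). Annotations are stored
    in seconds and survive unchanged.
    """
    if cutoff >= target_sfreq / 2:
        raise ValueError("cutoff must be below the target Nyquist")
    factor = rec.sfreq / target_sfreq
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"target rate must divide source rate (factor {factor})")
    factor = int(round(factor))
    numtaps, beta = signal.kaiserord(stop_atten_db, transition_hz / (rec.sfreq / 2))
    numtaps |= 1  # odd length -> integer group delay, exact symmetry
    b = signal.firwin(numtaps, cutoff, window=("kaiser", beta), fs=rec.sfreq)
    filtered = signal.fftconvolve(rec.data, b[None, :], mode="same", axes=1)
    out = rec.copy()
    out.data = filtered[:, ::factor]
    out.sfreq = target_sfreq
    return out


def detect_qrs(ecg: np.ndarray, sfreq: float, min_rr_s: float = 0.35) -> np.ndarray:
    """R-peak onsets (seconds) via a derivative-energy detector.

    Band-pass 5-30 Hz, differentiate, square, integrate over 150 ms, pick
    peaks above an adaptive threshold, then refine each to the local
    maximum of |filtered ECG|. Polarity-robust by squaring.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < int(2 * min_rr_s * sfreq):
        raise ValueError("ECG shorter than two beats")
    if np.ptp(ecg) < 1e-12:
        raise ValueError("flat ECG signal: no beats detectable")
    sos = signal.butter(3, [5.0, min(30.0, 0.45 * sfreq)], btype="bandpass",
                        fs=sfreq, output="sos")
    f = signal.sosfiltfilt(sos, ecg)
    energy = np.gradient(f) ** 2
    win = max(int(0.15 * sfreq), 1)
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    thresh = 0.3 * np.percentile(integ, 99)
    peaks, _ = signal.find_peaks(integ, height=thresh, distance=int(min_rr_s * sfreq))
    if len(peaks) == 0:
        raise ValueError("no QRS complexes found")
    # refine to the |f| maximum within +/-60 ms
    r = int(0.06 * sfreq)
    refined = []
    for p in peaks:
        a, b = max(p - r, 0), min(p + r + 1, len(f))
        refined.append(a + int(np.argmax(np.abs(f[a:b]))))
    refined = np.unique(refined)
    return refined / sfreq


def clean_mr_pipeline(rec: EEGRecording, tr_onsets, tr: float,
                      params_grad: TemplateParams = GRADIENT_PARAMS,
                      params_pulse: TemplateParams = PULSE_PARAMS,
                      lowpass_cutoff: float = 70.0, target_sfreq: float = 500.0,
                      pulse_delay_s: float = 0.10) -> tuple[EEGRecording, dict]:
    """Full in-MRI cleaning chain; returns ``(cleaned, qc)``.

    Order is fixed: gradient template subtraction (TR-locked), FIR
    low-pass at ``lowpass_cutoff``, downsampling to ``target_sfreq``, QRS
    detection on the (gradient-cleaned) ECG channel, pulse template
    subtraction on the scalp channels. The ECG channel is left as logged
    after downsampling so detection remains reproducible.
    """
    if "ecg" not in rec.ch_roles:
        raise ValueError("recording has no ecg channel")
    tr_onsets = np.asarray(tr_onsets, dtype=float)
    if len(tr_onsets) == 0:
        raise ValueError("no TR markers supplied")

    epoch_len = int(round(tr * rec.sfreq))
    grad_occ = ArtifactOccurrences(tr_onsets, epoch_len)
    pre_rms = np.sqrt((rec.data ** 2).mean(axis=1))
    step1 = subtract_artifact(rec, grad_occ, params_grad)
    step2 = lowpass_downsample(step1, cutoff=lowpass_cutoff, target_sfreq=target_sfreq)

    ecg_idx = step2.ch_roles.index("ecg")
    r_peaks = detect_qrs(step2.data[ecg_idx], step2.sfreq)
    if len(r_peaks) > 1:
        rrs = np.diff(r_peaks)
        rr = float(np.median(rrs))
        # window just short of the shortest plausible RR: neighbouring pulse
        # epochs must never overlap, or the template tail picks up the next
        # beat's artifact and double-subtracts it
        win_rr = min(rr, 0.95 * float(np.percentile(rrs, 5)))
    else:
        rr = win_rr = 0.8
    pulse_len = int(round(win_rr * step2.sfreq))
    pulse_occ = ArtifactOccurrences(r_peaks + pulse_delay_s, pulse_len)
    eeg_rows = step2.eeg_picks()
    cleaned = subtract_artifact(step2, pulse_occ, params_pulse, channels=eeg_rows)

    post_rms = np.sqrt((cleaned.data ** 2).mean(axis=1))
    qc = {
        "gradient_params": {"L": params_grad.L, "K": params_grad.K},
        "pulse_params": {"L": params_pulse.L, "K": params_pulse.K},
        "n_tr_markers": int(len(tr_onsets)),
        "n_r_peaks": int(len(r_peaks)),
        "median_rr_s": float(rr),
        "pre_rms_uv": pre_rms.tolist(),
        "post_rms_uv": post_rms.tolist(),
        "tr_harmonic_power_pre": _harmonic_power(rec, tr),
        "tr_harmonic_power_post": _harmonic_power(cleaned, tr),
        "lowpass_cutoff_hz": lowpass_cutoff,
        "target_sfreq_hz": target_sfreq,
        "pulse_delay_s": pulse_delay_s,
    }
    cleaned.metadata["qc"] = qc
    cleaned.metadata["r_peaks"] = r_peaks
    return cleaned, qc


def _harmonic_power(rec: EEGRecording, tr: float, f_max: float = 40.0) -> float:
    """Mean scalp power in excess of the local spectral baseline at
    TR-harmonic frequencies below f_max (isolates the periodic-artifact
    signature from broadband EEG power in the same bins)."""
    eeg = rec.data[rec.eeg_picks()]
    n = eeg.shape[1]
    freqs = np.fft.rfftfreq(n, 1.0 / rec.sfreq)
    psd = (np.abs(np.fft.rfft(eeg, axis=1)) ** 2).mean(axis=0) / n
    f0 = 1.0 / tr
    df = freqs[1] if len(freqs) > 1 else 1.0
    total = 0.0
    k = 1
    while k * f0 < f_max:
        near = np.abs(freqs - k * f0) <= df
        ring = (np.abs(freqs - k * f0) > 2 * df) & (np.abs(freqs - k * f0) <= 6 * df)
        baseline = np.median(psd[ring]) if ring.any() else 0.0
        total += float((psd[near] - baseline).sum())
        k += 1
    # an artifact-free spectrum gives ~0 excess (noise cancels in the sum)
    return max(total, 0.0)
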