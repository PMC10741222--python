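"""Synthetic EEG, ECG, artifacts, MR contamination and simulated behavior.

Every generator here is a pure function of its parameters and seed and
emits its ground truth (band envelopes, R-peak times, TR onsets, the clean
signal) alongside the synthetic data, so downstream recovery metrics never
need a real recording.

Signal model: per channel, a sum of narrowband oscillations (theta, alpha,
beta) whose theta and beta amplitudes at frontal channels are linearly
coupled to a latent bounded "attention" trace — theta decreases and beta
increases with attention, which makes the raw theta/beta ratio strictly
decreasing in attention by construction — plus 1/f background noise,
optional eye blinks, and one ECG channel with QRS complexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import EEGRecording, EventTable

__all__ = [
    "AttentionTrace",
    "AttentionParams",
    "SynthEEGParams",
    "MRContaminationParams",
    "ResponseParams",
    "simulate_attention_trace",
    "synthesize_eeg",
    "inject_muscle_bursts",
    "contaminate_mr",
    "simulate_responses",
]


# ---------------------------------------------------------------------------
# latent attention

@dataclass(frozen=True)
class AttentionParams:
    """Clipped mean-reverting (OU-type) process on [0, 1]."""

    target: float = 0.5
    reversion: float = 0.5       # 1/s pull toward target
    volatility: float = 0.15     # diffusion scale (per sqrt(s))
    start: float | None = None   # defaults to target


@dataclass(frozen=True)
class AttentionTrace:
    values: np.ndarray
    rate: float
    seed: int

    @property
    def duration(self) -> float:
        return len(self.values) / self.rate

    def at(self, t) -> np.ndarray:
        """Sample the trace at arbitrary times (zero-order hold)."""
        idx = np.clip((np.asarray(t) * self.rate).astype(int), 0, len(self.values) - 1)
        return self.values[idx]


def simulate_attention_trace(duration_s: float, rate_hz: float,
                             params: AttentionParams = AttentionParams(),
                             seed: int = 0) -> AttentionTrace:
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration and rate must be positive")
    n = int(round(duration_s * rate_hz))
    dt = 1.0 / rate_hz
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = np.clip(params.target if params.start is None else params.start, 0.0, 1.0)
    noise = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        drift = params.reversion * (params.target - x[i - 1]) * dt
        x[i] = np.clip(x[i - 1] + drift + params.volatility * np.sqrt(dt) * noise[i - 1], 0.0, 1.0)
    return AttentionTrace(values=x, rate=rate_hz, seed=seed)


# ---------------------------------------------------------------------------
# EEG synthesis

@dataclass(frozen=True)
class SynthEEGParams:
    theta_band: tuple[float, float] = (4.0, 7.5)
    alpha_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (13.0, 19.0)
    theta_freq: float = 6.0
    alpha_freq: float = 10.0
    beta_freq: float = 16.0
    theta_amp: float = 20.0      # µV at zero attention-coupling
    alpha_amp: float = 10.0
    beta_amp: float = 8.0
    attention_gain: float = 0.8  # fractional amplitude swing, frontal channels
    phase_drift: float = 1.5     # rad/sqrt(s) phase diffusion of each oscillator
                                 # (0 -> pure tones; nonzero avoids spurious
                                 # phase-locking to e.g. the cardiac cycle)
    frontal_weight: float = 1.0  # coupling weight on F* channels
    posterior_weight: float = 0.3
    pink_amp: float = 5.0        # µV RMS of 1/f background
    blink_rate: float = 0.1      # Hz, on frontopolar/frontal channels
    blink_amp: float = 80.0
    heart_rate: float = 75.0     # bpm on the ECG channel
    hr_jitter: float = 0.02      # fractional RR variability
    ecg_amp: float = 600.0       # µV R-peak

    def __post_init__(self):
        for lo, hi in (self.theta_band, self.beta_band):
            if not lo < hi:
                raise ValueError("band edges must be ordered")
        if self.theta_band[1] > self.beta_band[0]:
            raise ValueError("theta and beta bands must not overlap")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / (x.std() + 1e-30)


def _qrs_template(sfreq: float) -> np.ndarray:
    """A stylized QRS complex (Q dip, R spike, S dip), unit R amplitude."""
    t = np.arange(int(0.12 * sfreq)) / sfreq - 0.06
    q = -0.15 * np.exp(-((t + 0.025) / 0.008) ** 2)
    r = 1.0 * np.exp(-(t / 0.009) ** 2)
    s = -0.25 * np.exp(-((t - 0.025) / 0.008) ** 2)
    return q + r + s


def _r_peak_times(duration: float, heart_rate: float, jitter: float,
                  rng: np.random.Generator) -> np.ndarray:
    rr = 60.0 / heart_rate
    times = []
    t = rr / 2
    while t < duration:
        times.append(t)
        t += rr * (1.0 + jitter * rng.standard_normal())
    return np.array(times)


def synthesize_eeg(trace: AttentionTrace, ch_names: list[str], sfreq: float,
                   params: SynthEEGParams = SynthEEGParams(),
                   seed: int = 0) -> EEGRecording:
    """Render a multichannel recording driven by a latent attention trace.

    The returned recording stores ground truth in ``metadata``:
    ``attention`` (the trace), ``r_peaks`` (s), and ``envelopes`` (per-band
    Fz amplitude envelope at the trace rate).
    """
    duration = trace.duration
    n = int(round(duration * sfreq))
    if n <= 0:
        raise ValueError("trace too short")
    t = np.arange(n) / sfreq
    att = trace.at(t)
    rng = np.random.default_rng(seed)

    roles = ["ecg" if nm.upper() == "ECG" else "eeg" for nm in ch_names]
    data = np.zeros((len(ch_names), n))

    env = {
        "theta": params.theta_amp * (1.0 + params.attention_gain * (0.5 - att)),
        "alpha": params.alpha_amp * np.ones(n),
        "beta": params.beta_amp * (1.0 + params.attention_gain * (att - 0.5)),
    }
    freqs = {"theta": params.theta_freq, "alpha": params.alpha_freq, "beta": params.beta_freq}

    r_peaks = _r_peak_times(duration, params.heart_rate, params.hr_jitter, rng)
    qrs = _qrs_template(sfreq)

    for i, (nm, role) in enumerate(zip(ch_names, roles)):
        if role == "ecg":
            ecg = np.zeros(n)
            half = len(qrs) // 2
            for rp in r_peaks:
                s0 = int(round(rp * sfreq)) - half
                a, b = max(s0, 0), min(s0 + len(qrs), n)
                if b > a:
                    ecg[a:b] += qrs[a - s0:b - s0]
            data[i] = params.ecg_amp * ecg + 2.0 * rng.standard_normal(n)
            continue
        w = params.frontal_weight if nm.upper().startswith("F") else params.posterior_weight
        for band, f0 in freqs.items():
            if band == "alpha":
                amp = env[band]
            else:
                base = params.theta_amp if band == "theta" else params.beta_amp
                amp = base + w * (env[band] - base)
            phase = rng.uniform(0, 2 * np.pi)
            if params.phase_drift > 0:
                phase = phase + np.cumsum(
                    params.phase_drift * np.sqrt(1.0 / sfreq) * rng.standard_normal(n))
            data[i] += amp * np.sin(2 * np.pi * f0 * t + phase)
        if params.pink_amp > 0:
            data[i] += params.pink_amp * _pink_noise(n, rng)
        if params.blink_amp > 0 and params.blink_rate > 0 and nm.upper().startswith(("FP", "F")):
            n_blinks = rng.poisson(params.blink_rate * duration)
            blink_t = rng.uniform(0, duration, n_blinks)
            width = 0.15
            for bt in blink_t:
                mask = np.abs(t - bt) < 3 * width
                data[i, mask] += params.blink_amp * np.exp(-(((t[mask] - bt) / width) ** 2))

    rec = EEGRecording(data, sfreq, list(ch_names), roles)
    rec.metadata.update(
        attention=trace,
        r_peaks=r_peaks,
        envelopes={k: v if isinstance(v, np.ndarray) else v for k, v in env.items()},
    )
    return rec


def inject_muscle_bursts(rec: EEGRecording, times: list[tuple[float, float]],
                         channels: list[str], amplitude: float,
                         band: tuple[float, float] = (20.0, 140.0),
                         seed: int = 0) -> EEGRecording:
    """Add broadband (band-limited white noise) bursts on the listed channels.

    ``times`` is a list of ``(onset_s, duration_s)``. Burst windows are
    recorded as ``"muscle"`` annotations. Channels not listed are untouched.
    """
    out = rec.copy()
    if not times:
        return out
    idx = []
    for ch in channels:
        if ch not in rec.ch_names:
            raise KeyError(f"channel {ch!r} not in recording")
        idx.append(rec.ch_names.index(ch))
    rng = np.random.default_rng(seed)
    nyq = rec.sfreq / 2
    hi = min(band[1], 0.95 * nyq)
    sos = signal.butter(4, [band[0], hi], btype="bandpass", fs=rec.sfreq, output="sos")
    for onset, dur in times:
        if onset < 0 or onset + dur > rec.duration + 1e-9:
            raise ValueError(f"burst ({onset}, {dur}) outside recording")
        a = int(round(onset * rec.sfreq))
        b = min(int(round((onset + dur) * rec.sfreq)), rec.n_samples)
        m = b - a
        taper = signal.windows.tukey(m, 0.25)
        for i in idx:
            burst = signal.sosfiltfilt(sos, rng.standard_normal(m + 200))[100:100 + m]
            out.data[i, a:b] += amplitude * taper * burst / (burst.std() + 1e-30)
        out.annotations.append((onset, dur, "muscle"))
    out.annotations.sort(key=lambda r: r[0])
    return out


# ---------------------------------------------------------------------------
# MR contamination

@dataclass(frozen=True)
class MRContaminationParams:
    tr: float = 1.760                   # s, fMRI repetition time
    target_sfreq: float = 5000.0
    gradient_amp: float = 10000.0       # µV (10 mV), ≫ EEG
    gradient_duty: float = 0.85         # fraction of TR occupied by the template
    gradient_jitter: float = 0.0        # s, uniform onset jitter (breaks periodicity)
    bcg_amp: float = 150.0              # µV
    bcg_width_s: float = 0.30           # s, extent of the damped BCG pulse
    bcg_delay: float = 0.21             # s after R-peak
    bcg_channel_jitter: float = 0.01    # s of per-channel delay spread
    bcg_scale_sd: float = 0.15          # per-channel amplitude spread

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0 < self.gradient_duty <= 1:
            raise ValueError("gradient_duty must be in (0, 1]")


def _gradient_template(n: int, rng: np.random.Generator) -> np.ndarray:
    """Spiky broadband waveform, unit peak, deterministic given rng."""
    x = rng.standard_normal(n)
    # emphasize high frequencies like slice-selection gradients
    x = np.diff(np.concatenate([[0.0], x]))
    x *= signal.windows.tukey(n, 0.05)
    return x / (np.abs(x).max() + 1e-30)


def _bcg_template(sfreq: float, width_s: float = 0.30) -> np.ndarray:
    """Damped low-frequency oscillation, unit peak."""
    t = np.arange(int(width_s * sfreq)) / sfreq
    w = np.sin(2 * np.pi * 6.0 * t) * np.exp(-t / (width_s / 3.0))
    return w / (np.abs(w).max() + 1e-30)


def contaminate_mr(rec_clean: EEGRecording, params: MRContaminationParams = MRContaminationParams(),
                   seed: int = 0) -> tuple[EEGRecording, EEGRecording, EventTable]:
    """Upsample a clean recording and add gradient + BCG artifacts.

    Returns ``(contaminated, ground_truth, events)`` where ``ground_truth``
    is the clean signal at the target rate and ``events`` holds TR markers
    (label ``"TR"``) and R-peaks (label ``"R"``).
    """
    if "ecg" not in rec_clean.ch_roles:
        raise ValueError("clean recording must contain an ecg channel")
    up = int(round(params.target_sfreq))
    down = int(round(rec_clean.sfreq))
    data5k = signal.resample_poly(rec_clean.data, up, down, axis=1)
    clean = EEGRecording(data5k.copy(), params.target_sfreq, list(rec_clean.ch_names),
                         list(rec_clean.ch_roles), list(rec_clean.annotations))
    n = clean.n_samples
    sf = params.target_sfreq
    rng = np.random.default_rng(seed)

    tmpl_len = int(round(params.gradient_duty * params.tr * sf))
    if tmpl_len > int(round(params.tr * sf)):
        raise ValueError("gradient template longer than TR")
    tmpl = _gradient_template(tmpl_len, rng)

    contaminated = clean.copy()
    tr_onsets = []
    t0 = 0.0
    while t0 * sf + tmpl_len <= n:
        jit = rng.uniform(-params.gradient_jitter, params.gradient_jitter) if params.gradient_jitter else 0.0
        s0 = int(round((t0 + jit) * sf))
        if s0 >= 0 and s0 + tmpl_len <= n:
            contaminated.data[:, s0:s0 + tmpl_len] += params.gradient_amp * tmpl
            tr_onsets.append(s0 / sf)
        t0 += params.tr
    # last (possibly partial) TR gets no marker — cleaning only sees full epochs

    r_peaks = rec_clean.metadata.get("r_peaks")
    if r_peaks is None:
        from .mr import detect_qrs  # fallback: detect on the clean ECG
        ecg_idx = rec_clean.ch_roles.index("ecg")
        r_peaks = detect_qrs(rec_clean.data[ecg_idx], rec_clean.sfreq)
    bcg = _bcg_template(sf, params.bcg_width_s)
    eeg_rows = [i for i, r in enumerate(clean.ch_roles) if r == "eeg"]
    delays = params.bcg_delay + params.bcg_channel_jitter * rng.standard_normal(len(eeg_rows))
    scales = 1.0 + params.bcg_scale_sd * rng.standard_normal(len(eeg_rows))
    if params.bcg_amp > 0:
        for rp in r_peaks:
            for j, i in enumerate(eeg_rows):
                s0 = int(round((rp + delays[j]) * sf))
                a, b = max(s0, 0), min(s0 + len(bcg), n)
                if b > a:
                    contaminated.data[i, a:b] += params.bcg_amp * scales[j] * bcg[a - s0:b - s0]

    rows = sorted(
        [(t, 0.0, "TR", {}) for t in tr_onsets] + [(t, 0.0, "R", {}) for t in r_peaks]
    )
    events = EventTable(rows)
    contaminated.metadata["clean"] = clean
    contaminated.metadata["tr_onsets"] = np.array(tr_onsets)
    contaminated.metadata["r_peaks"] = np.asarray(r_peaks)
    return contaminated, clean, events


# ---------------------------------------------------------------------------
# simulated behavior

@dataclass(frozen=True)
class ResponseParams:
    base_rt_ms: float = 450.0
    distraction_offset_ms: float = 40.0
    rt_noise_ms: float = 60.0
    omission_at_zero: float = 0.4    # omission probability at attention 0
    commission_at_zero: float = 0.3  # false-press probability on nogo at attention 0
    rt_attention_slope_ms: float = 80.0  # RT increase from attention 1 -> 0


def simulate_responses(trace: AttentionTrace, trials, params: ResponseParams = ResponseParams(),
                       seed: int = 0) -> list[tuple[bool, float | None]]:
    """Simulate per-trial behavior: returns ``(pressed, rt_ms or None)``.

    ``trials`` is a sequence of objects with attributes ``onset`` (s),
    ``is_nogo`` (bool) and ``distracted`` (bool) — or ``(onset, is_nogo,
    distracted)`` triplets. Omission probability decreases linearly in
    attention; RT mean increases by a fixed offset under distraction.
    """
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    rng = np.random.default_rng(seed)
    out = []
    for tr in trials:
        if hasattr(tr, "onset"):
            onset, is_nogo, distracted = tr.onset, tr.is_nogo, getattr(tr, "distracted", False)
        else:
            onset, is_nogo, distracted = tr
        a = float(trace.at(onset))
        if is_nogo:
            p_press = params.commission_at_zero * (1.0 - a)
            pressed = rng.random() < p_press
        else:
            p_omit = params.omission_at_zero * (1.0 - a)
            pressed = rng.random() >= p_omit
        if pressed:
            rt = (params.base_rt_ms
                  + params.rt_attention_slope_ms * (1.0 - a)
                  + (params.distraction_offset_ms if distracted else 0.0)
                  + params.rt_noise_ms * rng.standard_normal())
            rt = max(rt, 120.0)
            out.append((True, rt))
        else:
            out.append((False, None))
    return out
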