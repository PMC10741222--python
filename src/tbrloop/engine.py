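"""Streaming theta/beta-ratio computation, calibration and normalization.

The engine slides a 3 s Hanning-tapered window over the recording, hopping
every second. Each window is average-referenced across scalp channels,
band powers are taken on the feedback channel (Fz) as sums of tapered
periodogram bins inside the theta (4-7.5 Hz) and beta (13-19 Hz) bands,
and the raw ratio theta/beta is emitted. A jaw-muscle gate zeroes the
transmitted feedback whenever beta power on the temporal gate channel (T7)
exceeds 3x the beta power on the feedback channel.

Calibration collects raw ratios over a four-phase relax/focus routine,
drops gated samples, sorts, and takes the minimum and the mean of the top
quarter as per-child normalization bounds. Normalized feedback is
``(max - raw) / (max - min)`` clipped to [0, 1]: a *low* raw ratio (a
focused child) maps to 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .io import EEGRecording

__all__ = [
    "EngineConfig",
    "TBRSample",
    "CalibrationBounds",
    "CalibrationError",
    "average_reference",
    "band_power",
    "gate_muscle",
    "stream_tbr",
    "TBRStream",
    "calibrate",
    "normalize",
]


@dataclass(frozen=True)
class EngineConfig:
    window_s: float = 3.0
    hop_s: float = 1.0
    theta_band: tuple[float, float] = (4.0, 7.5)
    beta_band: tuple[float, float] = (13.0, 19.0)
    feedback_channel: str = "Fz"
    gate_channel: str = "T7"
    gate_factor: float = 3.0

    def __post_init__(self):
        if not (self.window_s >= self.hop_s > 0):
            raise ValueError("require window_s >= hop_s > 0")
        if self.gate_factor <= 0:
            raise ValueError("gate_factor must be positive")


@dataclass(frozen=True)
class TBRSample:
    """One emitted real-time value; ``t`` is the window-end time in seconds."""

    t: float
    theta_power: float
    beta_power: float
    tbr_raw: float
    gated: bool
    nfb: float | None = None

    @property
    def feedback(self) -> float:
        """The value actually transmitted: 0 when gated."""
        if self.gated:
            return 0.0
        return self.nfb if self.nfb is not None else 0.0


@dataclass(frozen=True)
class CalibrationBounds:
    tbr_min: float
    tbr_max: float
    n_samples_used: int
    n_rejected: int

    def __post_init__(self):
        if not (self.tbr_min <= self.tbr_max):
            raise ValueError("tbr_min must not exceed tbr_max")

    def to_dict(self) -> dict:
        return {"tbr_min": self.tbr_min, "tbr_max": self.tbr_max,
                "n_samples_used": self.n_samples_used, "n_rejected": self.n_rejected}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationBounds":
        return cls(d["tbr_min"], d["tbr_max"], d.get("n_samples_used", 0),
                   d.get("n_rejected", 0))


class CalibrationError(RuntimeError):
    pass


def average_reference(window: np.ndarray, roles: list[str]) -> np.ndarray:
    """Subtract the instantaneous mean over eeg-role channels; ecg untouched."""
    window = np.asarray(window, dtype=float)
    eeg = [i for i, r in enumerate(roles) if r == "eeg"]
    if len(eeg) < 2:
        raise ValueError("average reference needs at least 2 eeg channels")
    out = window.copy()
    mean = out[eeg].mean(axis=0, keepdims=True)
    out[eeg] -= mean
    return out


def band_power(window: np.ndarray, sfreq: float, band: tuple[float, float],
               taper: str = "hann") -> float:
    """Power (µV²) in ``band``: sum of one-sided tapered periodogram bins.

    Bins whose frequency lies in ``[band_lo, band_hi]`` (edges inclusive)
    are summed. Spectrum scaling: ``|X_k|² / (Σw)²``, doubled for interior
    bins, so a full-scale sine of amplitude A at a bin center yields ~A²/2
    (times the taper's coherent-gain correction).
    """
    x = np.asarray(window, dtype=float)
    n = x.size
    lo, hi = band
    if hi > sfreq / 2:
        raise ValueError(f"band {band} exceeds Nyquist ({sfreq / 2} Hz)")
    if lo >= hi or lo < 0:
        raise ValueError(f"invalid band {band}")
    if taper in ("hann", "hanning"):
        w = np.hanning(n)
    elif taper in (None, "boxcar", "rect"):
        w = np.ones(n)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    spec = np.fft.rfft(w * x)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    p = np.abs(spec) ** 2 / (w.sum() ** 2)
    p[1:] *= 2.0
    if n % 2 == 0:
        p[-1] /= 2.0
    mask = (freqs >= lo) & (freqs <= hi)
    return float(p[mask].sum())


def gate_muscle(beta_t7: float, beta_fz: float, gate_factor: float = 3.0) -> bool:
    """True iff T7 beta power strictly exceeds ``gate_factor`` x Fz beta power."""
    if beta_t7 < 0 or beta_fz < 0:
        raise ValueError("powers must be non-negative")
    return beta_t7 > gate_factor * beta_fz


def normalize(tbr_raw: float, bounds: CalibrationBounds) -> float:
    """Map a raw ratio to normalized feedback in [0, 1] (low raw -> 1)."""
    span = bounds.tbr_max - bounds.tbr_min
    if span == 0:
        warnings.warn("degenerate calibration bounds (min == max); nfb = 0.5",
                      stacklevel=2)
        return 0.5
    return float(np.clip((bounds.tbr_max - tbr_raw) / span, 0.0, 1.0))


def calibrate(samples) -> CalibrationBounds:
    """Derive normalization bounds from the four-phase calibration routine.

    Gated (muscle-artifact) samples are removed; remaining raw ratios are
    sorted ascending; the minimum is the first element and the maximum is
    the mean of the top ⌈n/4⌉ elements.
    """
    raw = [s.tbr_raw for s in samples if not s.gated and np.isfinite(s.tbr_raw)]
    n_rejected = len(list(samples)) - len(raw)
    if len(raw) < 4:
        raise CalibrationError(
            f"calibration needs at least 4 ungated samples, got {len(raw)}")
    arr = np.sort(np.asarray(raw, dtype=float))
    top = math.ceil(len(arr) / 4)
    return CalibrationBounds(
        tbr_min=float(arr[0]),
        tbr_max=float(arr[-top:].mean()),
        n_samples_used=len(arr),
        n_rejected=n_rejected,
    )


class TBRStream:
    """Incremental engine: push raw multichannel chunks, collect samples.

    Feeding the stream one sample at a time or the whole recording at once
    yields identical :class:`TBRSample` sequences — the offline entry point
    :func:`stream_tbr` is implemented on top of this class.
    """

    def __init__(self, sfreq: float, ch_names: list[str], ch_roles: list[str],
                 config: EngineConfig = EngineConfig(),
                 bounds: CalibrationBounds | None = None):
        self.config = config
        self.bounds = bounds
        self.sfreq = sfreq
        self.ch_roles = list(ch_roles)
        if config.beta_band[1] > sfreq / 2:
            raise ValueError("sampling rate too low for the beta band")
        try:
            self._fb = ch_names.index(config.feedback_channel)
            self._gate = ch_names.index(config.gate_channel)
        except ValueError as e:
            raise KeyError(f"engine channel missing from recording: {e}") from None
        self._win_n = int(round(config.window_s * sfreq))
        self._hop_n = int(round(config.hop_s * sfreq))
        self._buf = np.empty((len(ch_names), 0))
        self._n_seen = 0          # total samples consumed
        self._next_end = self._win_n

    def push(self, chunk: np.ndarray) -> list[TBRSample]:
        """Consume a channels x m chunk; return any newly completed samples."""
        chunk = np.atleast_2d(np.asarray(chunk, dtype=float))
        self._buf = np.concatenate([self._buf, chunk], axis=1)
        self._n_seen += chunk.shape[1]
        out = []
        while self._next_end <= self._n_seen:
            # window covers (t - window_s, t]
            start = self._next_end - self._win_n
            drop = start - (self._n_seen - self._buf.shape[1])
            if drop > 0:
                self._buf = self._buf[:, drop:]
            win = self._buf[:, :self._win_n]
            out.append(self._emit(win, self._next_end / self.sfreq))
            self._next_end += self._hop_n
        return out

    def _emit(self, win: np.ndarray, t: float) -> TBRSample:
        cfg = self.config
        ref = average_reference(win, self.ch_roles)
        theta = band_power(ref[self._fb], self.sfreq, cfg.theta_band)
        beta = band_power(ref[self._fb], self.sfreq, cfg.beta_band)
        beta_gate = band_power(ref[self._gate], self.sfreq, cfg.beta_band)
        tbr = theta / beta if beta > 0 else float("nan")
        gated = gate_muscle(beta_gate, beta, cfg.gate_factor)
        nfb = None
        if self.bounds is not None:
            nfb = 0.0 if gated else normalize(tbr, self.bounds)
        return TBRSample(t=t, theta_power=theta, beta_power=beta, tbr_raw=tbr,
                         gated=gated, nfb=nfb)


def stream_tbr(rec: EEGRecording, config: EngineConfig = EngineConfig(),
               bounds: CalibrationBounds | None = None,
               t_start: float = 0.0, t_stop: float | None = None) -> list[TBRSample]:
    """Run the engine over (a slice of) a recording.

    The first sample lands at ``t_start + window_s``; subsequent samples
    every ``hop_s``. Timestamps are absolute recording times.
    """
    a = int(round(t_start * rec.sfreq))
    b = rec.n_samples if t_stop is None else int(round(t_stop * rec.sfreq))
    seg = rec.data[:, a:b]
    if seg.shape[1] < int(round(config.window_s * rec.sfreq)):
        raise ValueError("recording shorter than one analysis window")
    stream = TBRStream(rec.sfreq, rec.ch_names, rec.ch_roles, config, bounds)
    samples = stream.push(seg)
    if t_start:
        samples = [TBRSample(s.t + a / rec.sfreq, s.theta_power, s.beta_power,
                             s.tbr_raw, s.gated, s.nfb) for s in samples]
    return samples
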