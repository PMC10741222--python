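"""Offline VR-session preprocessing and session/transfer TBR statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre
from scipy import signal

from .engine import TBRSample, band_power
from .io import EEGRecording, EventTable
from .montage import channel_positions

__all__ = [
    "SessionTBR",
    "TransferResult",
    "preprocess_vr",
    "spherical_spline_interpolate",
    "session_tbr",
    "period_summary",
    "transfer_tbr",
]


# ---------------------------------------------------------------------------
# VR preprocessing

def _g_matrix(cosang: np.ndarray, stiffness: int = 4, n_terms: int = 50) -> np.ndarray:
    """Spherical-spline kernel g(cos) as a truncated Legendre series."""
    n = np.arange(1, n_terms + 1)
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2 * n + 1) / (n ** stiffness * (n + 1) ** stiffness)
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coeffs) / (4 * np.pi)


def spherical_spline_interpolate(rec: EEGRecording, bad_channels: list[str],
                                 stiffness: int = 4, reg: float = 1e-5) -> EEGRecording:
    """Rebuild bad scalp channels from the good ones (Perrin-style splines)."""
    if not bad_channels:
        return rec.copy()
    picks = rec.eeg_picks()
    eeg_names = [rec.ch_names[i] for i in picks]
    for b in bad_channels:
        if b not in eeg_names:
            raise KeyError(f"bad channel {b!r} not an eeg channel of the recording")
    good = [n for n in eeg_names if n not in bad_channels]
    if not good:
        raise ValueError("all channels marked bad")
    pos_good = channel_positions(good)
    pos_bad = channel_positions(bad_channels)
    g_gg = _g_matrix(pos_good @ pos_good.T, stiffness)
    g_bg = _g_matrix(pos_bad @ pos_good.T, stiffness)
    m = len(good)
    a = np.zeros((m + 1, m + 1))
    a[:m, :m] = g_gg + reg * np.eye(m)
    a[:m, m] = 1.0
    a[m, :m] = 1.0
    out = rec.copy()
    good_idx = [rec.ch_names.index(n) for n in good]
    rhs = np.zeros((m + 1, rec.n_samples))
    rhs[:m] = rec.data[good_idx]
    sol = np.linalg.solve(a, rhs)
    interp = g_bg @ sol[:m] + sol[m]
    for j, b in enumerate(bad_channels):
        out.data[rec.ch_names.index(b)] = interp[j]
    return out


def preprocess_vr(rec: EEGRecording, bad_annotations=None, bad_channels=None,
                  ica_excluder=None, band: tuple[float, float] = (1.0, 40.0),
                  notch_hz: float = 50.0) -> EEGRecording:
    """Standard VR-session preprocessing chain.

    1-40 Hz zero-phase FIR bandpass, 50 Hz notch, optional external ICA
    component-removal hook, spherical-spline interpolation of bad
    channels, then average reference. Bad segments are recorded as
    ``"BAD"`` annotations and masked by downstream statistics, never
    silently dropped here.
    """
    picks = rec.eeg_picks()
    if len(picks) == 0:
        raise ValueError("no eeg channels")
    bad_channels = list(bad_channels or [])
    if set(bad_channels) == {rec.ch_names[i] for i in picks}:
        raise ValueError("all eeg channels marked bad")
    out = rec.copy()

    numtaps = int(3.3 * rec.sfreq / max(band[0], 0.5))
    numtaps |= 1
    b = signal.firwin(numtaps, band, pass_zero=False, fs=rec.sfreq)
    out.data[picks] = signal.fftconvolve(out.data[picks], b[None, :], mode="same", axes=1)
    if notch_hz and notch_hz < rec.sfreq / 2:
        bn, an = signal.iirnotch(notch_hz, Q=30.0, fs=rec.sfreq)
        out.data[picks] = signal.filtfilt(bn, an, out.data[picks], axis=1)

    if ica_excluder is not None:
        out.data[picks] = ica_excluder(out.data[picks], rec.sfreq)

    if bad_channels:
        out = spherical_spline_interpolate(out, bad_channels)
    # average reference last
    out.data[picks] -= out.data[picks].mean(axis=0, keepdims=True)

    for ann in (bad_annotations or []):
        onset, duration = ann[0], ann[1]
        out.annotations.append((float(onset), float(duration), "BAD"))
    out.annotations.sort(key=lambda r: r[0])
    out.metadata["bad_channels"] = bad_channels
    return out


# ---------------------------------------------------------------------------
# session TBR statistics

@dataclass(frozen=True)
class SessionTBR:
    session_id: int
    mean_tbr_helicopter: float
    mean_tbr_baseline: float
    n_helicopter: int
    n_baseline: int

    @property
    def tbr_relative(self) -> float:
        return self.mean_tbr_helicopter - self.mean_tbr_baseline


def _mean_in_windows(samples: list[TBRSample], windows) -> tuple[float, int]:
    vals = [s.tbr_raw for s in samples
            if not s.gated and np.isfinite(s.tbr_raw)
            and any(a <= s.t < b for a, b in windows)]
    return (float(np.mean(vals)) if vals else float("nan")), len(vals)


def session_tbr(samples: list[TBRSample], events: EventTable,
                session_id: int = 0, baseline_s: float = 20.0,
                helicopter_label: str = "helicopter",
                calc_label: str = "calc") -> SessionTBR:
    """Session summary: mean raw TBR over helicopter runs vs. the first
    ``baseline_s`` seconds of the calculation task (ungated samples only)."""
    heli = [(o, o + d) for o, d, lab, _ in events if lab == helicopter_label]
    calc = [o for o, _, lab, _ in events if lab == calc_label]
    if not heli:
        raise ValueError(f"no {helicopter_label!r} events found")
    if not calc:
        raise ValueError(f"no {calc_label!r} event found")
    base_win = [(calc[0], calc[0] + baseline_s)]
    m_heli, n_heli = _mean_in_windows(samples, heli)
    m_base, n_base = _mean_in_windows(samples, base_win)
    return SessionTBR(session_id=session_id, mean_tbr_helicopter=m_heli,
                      mean_tbr_baseline=m_base, n_helicopter=n_heli, n_baseline=n_base)


@dataclass(frozen=True)
class PeriodSummary:
    period1_mean: float           # sessions 1-4
    period2_mean: float           # sessions 5-8
    per_session: dict
    missing_sessions: tuple = ()


def period_summary(sessions: list[SessionTBR]) -> PeriodSummary:
    """Per-child training-period averages of the baseline-relative TBR."""
    by_id = {s.session_id: s for s in sessions}
    missing = tuple(i for i in range(1, 9) if i not in by_id)
    p1 = [by_id[i].tbr_relative for i in (1, 2, 3, 4) if i in by_id]
    p2 = [by_id[i].tbr_relative for i in (5, 6, 7, 8) if i in by_id]
    return PeriodSummary(
        period1_mean=float(np.mean(p1)) if p1 else float("nan"),
        period2_mean=float(np.mean(p2)) if p2 else float("nan"),
        per_session={i: by_id[i].tbr_relative for i in sorted(by_id)},
        missing_sessions=missing,
    )


# ---------------------------------------------------------------------------
# transfer task

@dataclass(frozen=True)
class TransferResult:
    conditions: dict = field(default_factory=dict)
    # per condition: theta_power, beta_power, tbr, n_epochs, n_rejected


def transfer_tbr(rec: EEGRecording, blocks: EventTable, reject_list=None,
                 epoch_s: float = 10.0, channel: str = "Fz",
                 theta_band=(4.0, 7.5), beta_band=(13.0, 19.0)) -> TransferResult:
    """Per-condition Fz theta/beta power and TBR over 10 s epochs.

    Each block is cut into non-overlapping ``epoch_s`` epochs fully inside
    the block; epoch indices in ``reject_list`` (global numbering, in
    temporal order) and epochs overlapping ``BAD`` annotations are
    dropped. Uses the same band-power estimator as the real-time engine.
    """
    reject = set(reject_list or [])
    sig = rec.pick(channel)
    bad_spans = [(o, o + d) for o, d, lab in rec.annotations if lab.upper() == "BAD"]
    n_ep = int(round(epoch_s * rec.sfreq))
    per_cond: dict[str, dict] = {}
    epoch_idx = 0
    for onset, duration, label, _ in blocks:
        c = per_cond.setdefault(label, {"theta": [], "beta": [], "tbr": [], "rejected": 0})
        n_fit = int(duration // epoch_s)
        for e in range(n_fit):
            t0 = onset + e * epoch_s
            t1 = t0 + epoch_s
            idx = epoch_idx
            epoch_idx += 1
            overlaps_bad = any(t0 < b and a < t1 for a, b in bad_spans)
            if idx in reject or overlaps_bad:
                c["rejected"] += 1
                continue
            a0 = int(round(t0 * rec.sfreq))
            win = sig[a0:a0 + n_ep]
            if len(win) < n_ep:
                c["rejected"] += 1
                continue
            th = band_power(win, rec.sfreq, theta_band)
            be = band_power(win, rec.sfreq, beta_band)
            c["theta"].append(th)
            c["beta"].append(be)
            c["tbr"].append(th / be if be > 0 else float("nan"))
    result = {}
    for label, c in per_cond.items():
        if not c["theta"]:
            raise ValueError(f"no surviving epochs in condition {label!r}")
        result[label] = {
            "theta_power": float(np.mean(c["theta"])),
            "beta_power": float(np.mean(c["beta"])),
            "tbr": float(np.nanmean(c["tbr"])),
            "n_epochs": len(c["theta"]),
            "n_rejected": c["rejected"],
        }
    return TransferResult(conditions=result)
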