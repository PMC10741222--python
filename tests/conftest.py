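import numpy as np
import pytest

from tbrloop.io import EEGRecording
from tbrloop.synth import (AttentionParams, SynthEEGParams,
                           simulate_attention_trace, synthesize_eeg)

STANDARD_CHS = ["Fz", "Cz", "Pz", "T7", "ECG"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_recording(rng):
    """32-channel-style random recording, 4 s @ 250 Hz, with an ECG row."""
    names = ["Fz", "Cz", "Pz", "T7", "Oz", "ECG"]
    roles = ["eeg"] * 5 + ["ecg"]
    data = rng.standard_normal((6, 1000)) * 10
    return EEGRecording(data, 250.0, names, roles,
                        annotations=[(0.5, 0.2, "blink"), (2.0, 0.0, "marker")])


@pytest.fixture
def constant_attention_recording():
    """20 s @ 500 Hz synthetic EEG at constant attention 0.5, no artifacts."""
    trace = simulate_attention_trace(
        20.0, 10.0, AttentionParams(target=0.5, volatility=0.0), seed=0)
    return synthesize_eeg(trace, STANDARD_CHS, 500.0,
                          SynthEEGParams(blink_amp=0.0), seed=7)


def planted_microstate_maps(k: int, n_channels: int, rng) -> np.ndarray:
    """Orthonormal zero-mean topographies (k, n_channels)."""
    x = rng.standard_normal((n_channels, k))
    x -= x.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(x)
    return q.T


def microstate_recording(maps: np.ndarray, n_samples: int, sfreq: float, rng,
                         noise: float = 0.2, run_len: int = 50):
    """Recording whose samples are noisy sign-flipped copies of planted maps."""
    k, c = maps.shape
    labels = np.repeat(rng.integers(k, size=n_samples // run_len + 1),
                       run_len)[:n_samples]
    gfp = 1.0 + 0.5 * rng.random(n_samples)
    signs = rng.choice([-1.0, 1.0], n_samples)
    data = (signs * gfp)[:, None] * maps[labels]
    data += noise * rng.standard_normal((n_samples, c))
    rec = EEGRecording(data.T, sfreq, [f"E{i}" for i in range(c)], ["eeg"] * c)
    return rec, labels
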