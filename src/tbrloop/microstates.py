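"""Microstate analysis: GFP-peak extraction, polarity-invariant modified
k-means, two-level (recording -> group) clustering, and smoothed
back-fitting.

Global field power (GFP) at time t is the standard deviation of the
average-referenced scalp potentials. Topographies at strict local GFP
maxima are clustered by a modified k-means that ignores polarity: a
topography is assigned to the map maximizing the squared spatial
correlation, and each map is re-estimated as the dominant eigenvector of
the outer-product sum of its members. The best of ``n_reps`` random
restarts by global explained variance (GEV) is kept. Back-fitting labels
every sample with the map of highest absolute spatial correlation; the
temporal smoothing follows the segmentation-smoothing scheme of the
modified k-means literature (a window/factor penalty rewarding the locally
dominant label), since the factor's exact formula is a configuration
choice — it is isolated in :func:`_smooth_labels`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import EEGRecording

__all__ = [
    "MicrostateMaps",
    "Segmentation",
    "gfp_peaks",
    "modified_kmeans",
    "two_level_cluster",
    "backfit",
    "match_maps",
]


@dataclass(frozen=True)
class MicrostateMaps:
    maps: np.ndarray          # (k, n_channels), unit L2 norm, zero channel-mean
    gev: float
    ch_names: list[str]
    source: str = "recording"  # "recording" | "group"

    @property
    def k(self) -> int:
        return self.maps.shape[0]


@dataclass(frozen=True)
class Segmentation:
    labels: np.ndarray        # per-sample map index (0-based)
    correlation: np.ndarray   # per-sample |spatial correlation| with its map
    gev_per_map: np.ndarray
    gev_total: float
    coverage: np.ndarray      # fraction of samples per map
    mean_duration_s: np.ndarray


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=-1, keepdims=True)


def gfp_peaks(rec: EEGRecording, min_gfp: float = 0.0) -> np.ndarray:
    """Topographies (n_peaks, n_eeg_channels) at strict local GFP maxima."""
    eeg = _center(rec.data[rec.eeg_picks()].T)   # (n_samples, C)
    gfp = eeg.std(axis=1)
    if np.ptp(gfp) < 1e-15:
        raise ValueError("constant GFP: no peaks")
    core = (gfp[1:-1] > gfp[:-2]) & (gfp[1:-1] > gfp[2:])
    idx = np.flatnonzero(core) + 1
    if min_gfp > 0:
        idx = idx[gfp[idx] >= min_gfp]
    return eeg[idx]


def _gev(topos: np.ndarray, maps: np.ndarray, labels: np.ndarray) -> float:
    """GFP-weighted squared-correlation explained variance."""
    gfp = topos.std(axis=1)
    norm_t = np.linalg.norm(topos, axis=1)
    corr = np.einsum("tc,tc->t", topos, maps[labels]) / (
        norm_t * np.linalg.norm(maps[labels], axis=1) + 1e-30)
    return float(((gfp * corr) ** 2).sum() / ((gfp ** 2).sum() + 1e-30))


def _kmeans_once(topos: np.ndarray, k: int, rng: np.random.Generator,
                 tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    n, c = topos.shape
    maps = topos[rng.choice(n, size=k, replace=False)].copy()
    maps /= np.linalg.norm(maps, axis=1, keepdims=True) + 1e-30
    prev_gev = -1.0
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        proj = topos @ maps.T                      # (n, k)
        labels = np.argmax(proj ** 2, axis=1)
        for j in range(k):
            members = topos[labels == j]
            if len(members) == 0:
                maps[j] = topos[rng.integers(n)]
                maps[j] /= np.linalg.norm(maps[j]) + 1e-30
                continue
            s = members.T @ members                # (c, c)
            w, v = np.linalg.eigh(s)
            maps[j] = v[:, -1]
        g = _gev(topos, maps, labels)
        if abs(g - prev_gev) < tol:
            prev_gev = g
            break
        prev_gev = g
    return maps, labels, prev_gev


def modified_kmeans(topos: np.ndarray, k: int = 5, n_reps: int = 100,
                    seed: int = 0, tol: float = 1e-8, max_iter: int = 300,
                    ch_names: list[str] | None = None,
                    source: str = "recording") -> MicrostateMaps:
    """Polarity-invariant k-means; best of ``n_reps`` restarts by GEV."""
    topos = _center(np.asarray(topos, dtype=float))
    n = topos.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of topographies ({n})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_reps):
        maps, labels, g = _kmeans_once(topos, k, rng, tol, max_iter)
        if best is None or g > best[2]:
            best = (maps, labels, g)
    maps, _, g = best
    maps = _center(maps)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True) + 1e-30
    names = ch_names if ch_names is not None else [f"ch{i}" for i in range(maps.shape[1])]
    return MicrostateMaps(maps=maps, gev=g, ch_names=list(names), source=source)


def two_level_cluster(recording_maps: list[MicrostateMaps], k: int = 5,
                      n_reps: int = 100, seed: int = 0) -> MicrostateMaps:
    """Pool per-recording maps and re-cluster them into group maps."""
    if not recording_maps:
        raise ValueError("no recording-level maps given")
    names = recording_maps[0].ch_names
    for m in recording_maps:
        if m.ch_names != names:
            raise ValueError("recording maps have mismatched channels")
    pooled = np.vstack([m.maps for m in recording_maps])
    return modified_kmeans(pooled, k=k, n_reps=n_reps, seed=seed,
                           ch_names=names, source="group")


def _smooth_labels(corr_abs: np.ndarray, labels: np.ndarray, half_w: int,
                   factor: float, max_passes: int = 20) -> np.ndarray:
    """Neighborhood-reward relabeling (Pascual-Marqui-style smoothing).

    Each sample's evidence for map k is its squared correlation plus a
    bonus proportional to ``factor`` times the fraction of samples within
    the window already labeled k; iterate to a fixed point.
    """
    k, n = corr_abs.shape
    evidence = corr_abs ** 2
    lab = labels.copy()
    kernel = np.ones(2 * half_w + 1)
    kernel[half_w] = 0.0  # exclude the center point itself
    denom = np.maximum(np.convolve(np.ones(n), kernel, mode="same"), 1.0)
    for _ in range(max_passes):
        counts = np.empty((k, n))
        for j in range(k):
            counts[j] = np.convolve((lab == j).astype(float), kernel, mode="same")
        # bonus = factor x fraction of window samples sharing the label
        score = evidence + factor * counts / denom
        new = np.argmax(score, axis=0)
        if np.array_equal(new, lab):
            break
        lab = new
    return lab


def backfit(rec: EEGRecording, maps: MicrostateMaps,
            smoothing_window_s: float = 0.050, smoothing_factor: float = 10.0,
            smooth: bool = True) -> Segmentation:
    """Label every sample with its best map by |spatial correlation|."""
    picks = rec.eeg_picks()
    if len(picks) != maps.maps.shape[1]:
        raise ValueError("recording channel count does not match maps")
    x = _center(rec.data[picks].T)               # (n, C)
    m = _center(maps.maps)
    m = m / (np.linalg.norm(m, axis=1, keepdims=True) + 1e-30)
    norm_x = np.linalg.norm(x, axis=1) + 1e-30
    corr = (x @ m.T) / norm_x[:, None]           # (n, k) signed correlation
    corr_abs = np.abs(corr).T                    # (k, n)
    labels = np.argmax(corr_abs, axis=0)
    if smooth and smoothing_factor > 0:
        half_w = max(int(round(smoothing_window_s * rec.sfreq / 2)), 1)
        labels = _smooth_labels(corr_abs, labels, half_w, smoothing_factor)

    n = len(labels)
    gfp = x.std(axis=1)
    sel = corr_abs[labels, np.arange(n)]
    denom = (gfp ** 2).sum() + 1e-30
    gev_per_map = np.array([
        (((gfp * sel)[labels == j]) ** 2).sum() / denom for j in range(maps.k)
    ])
    coverage = np.array([(labels == j).mean() for j in range(maps.k)])
    # mean segment duration per map
    bounds = np.flatnonzero(np.diff(labels)) + 1
    seg_starts = np.concatenate([[0], bounds])
    seg_ends = np.concatenate([bounds, [n]])
    seg_labels = labels[seg_starts]
    durs = (seg_ends - seg_starts) / rec.sfreq
    mean_dur = np.array([
        durs[seg_labels == j].mean() if np.any(seg_labels == j) else np.nan
        for j in range(maps.k)
    ])
    return Segmentation(labels=labels, correlation=sel, gev_per_map=gev_per_map,
                        gev_total=float(gev_per_map.sum()), coverage=coverage,
                        mean_duration_s=mean_dur)


def match_maps(estimated: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of map sets by |correlation|.

    Returns ``(permutation, correlations)`` such that ``estimated[permutation[i]]``
    corresponds to ``reference[i]``. Evaluation utility, not part of the method.
    """
    est = _center(estimated)
    ref = _center(reference)
    est = est / (np.linalg.norm(est, axis=1, keepdims=True) + 1e-30)
    ref = ref / (np.linalg.norm(ref, axis=1, keepdims=True) + 1e-30)
    c = np.abs(ref @ est.T)                      # (n_ref, n_est)
    rows, cols = linear_sum_assignment(-c)
    return cols, c[rows, cols]
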