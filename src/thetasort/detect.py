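"""Threshold spike detection, snippet extraction, PCA features, k-means sorting.

Detection follows the amplitude-threshold rule: the threshold is a
negative multiple (default −5) of the standard deviation of the entire
spike-band-filtered trace, events are downward threshold crossings
aligned to the local minimum, and crossings within a dead time of the
previous spike are suppressed.  Sorting projects trough-aligned snippets
onto the top principal components (8-D by default) and partitions them
with k-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import SnippetArray, SpikeTrain

__all__ = [
    "DetectionParams",
    "detect_spikes",
    "extract_snippets",
    "peak_to_peak",
    "compute_snr",
    "pca_features",
    "kmeans_cluster",
    "suggest_k",
]


@dataclass(frozen=True)
class DetectionParams:
    """Spike-detection settings.

    ``threshold_multiplier`` is dimensionless and negative (−5 by
    default: threshold = −5 x SD of the filtered trace).  ``dead_time``
    suppresses re-triggering; ``pre_window``/``post_window`` set the
    snippet extent in seconds.
    """

    threshold_multiplier: float = -5.0
    dead_time: float = 0.001
    pre_window: float = 0.0008
    post_window: float = 0.0016
    robust_sd: bool = False  # median/0.6745 noise estimate instead of plain SD

    def __post_init__(self) -> None:
        if self.threshold_multiplier >= 0:
            raise ValueError("threshold_multiplier must be negative")
        if self.dead_time <= 0 or self.pre_window <= 0 or self.post_window <= 0:
            raise ValueError("dead_time and windows must be positive")


def detect_spikes(
    filtered_trace: np.ndarray,
    rate: float,
    params: DetectionParams = DetectionParams(),
    channel_id: str = "ch0",
) -> SpikeTrain:
    """Detect negative-going spikes in a spike-band-filtered trace.

    Threshold T = multiplier x SD(trace).  Each downward crossing of T is
    refined to the local minimum within ±0.5 ms, and crossings within
    ``dead_time`` of the previous accepted spike are suppressed.  A
    constant trace (SD = 0) yields an empty train.
    """
    x = np.asarray(filtered_trace, dtype=np.float64)
    if params.robust_sd:
        sd = np.median(np.abs(x)) / 0.6745
    else:
        sd = x.std()
    if sd == 0:
        return SpikeTrain(channel_id, np.empty(0))
    threshold = params.threshold_multiplier * sd
    below = x < threshold
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    half_ms = max(1, int(round(0.0005 * rate)))
    dead = params.dead_time * rate
    peaks: list[int] = []
    last = -np.inf
    for c in crossings:
        if c - last < dead:
            continue
        lo, hi = max(0, c - half_ms), min(len(x), c + half_ms + 1)
        peak = lo + int(np.argmin(x[lo:hi]))
        if peaks and peak == peaks[-1]:
            continue
        peaks.append(peak)
        last = c
    times = np.asarray(peaks, dtype=float) / rate
    return SpikeTrain(channel_id, times)


def extract_snippets(
    filtered_trace: np.ndarray,
    spike_times: np.ndarray,
    rate: float,
    params: DetectionParams = DetectionParams(),
    realign: bool = True,
) -> tuple[SnippetArray, int]:
    """Cut aligned waveform windows around spike times.

    Returns the snippet array and the number of spikes dropped for being
    too close to the trace edges.  With ``realign`` (the default) each
    window is re-centred on the local trough within ±2 samples so index
    ``pre_samples`` is the waveform minimum; pass ``realign=False`` when
    spike times are already trough-exact (e.g. ground truth), since
    picking a local minimum of noisy samples biases the trough estimate
    downward at low SNR.
    """
    x = np.asarray(filtered_trace, dtype=np.float64)
    pre = int(round(params.pre_window * rate))
    post = int(round(params.post_window * rate))
    idx = np.round(np.asarray(spike_times) * rate).astype(int)
    ok = (idx - pre >= 0) & (idx + post < len(x))
    dropped = int((~ok).sum())
    idx = idx[ok]
    kept_times = np.asarray(spike_times)[ok]
    waves = np.empty((len(idx), pre + post + 1))
    for row, i in enumerate(idx):
        w = x[i - pre : i + post + 1]
        if realign:
            # re-centre on the local trough near the nominal spike sample
            local = int(np.argmin(w[max(0, pre - 2) : pre + 3])) + max(0, pre - 2)
            shift = pre - local
            if shift and 0 <= i - shift - pre and i - shift + post < len(x):
                w = x[i - shift - pre : i - shift + post + 1]
        waves[row] = w
    return (
        SnippetArray(
            waveforms=waves,
            pre_samples=pre,
            post_samples=post,
            rate=rate,
            spike_times=kept_times,
        ),
        dropped,
    )


def peak_to_peak(
    snippets: SnippetArray, groups: np.ndarray | None = None
) -> tuple[np.ndarray, dict]:
    """Per-spike peak-to-peak amplitude (µV) and per-group mean/SD.

    ``groups`` is an optional per-spike label (e.g. cluster id); the
    returned dict maps group -> (mean, sd, n).  Empty input gives empty
    outputs.
    """
    if len(snippets) == 0:
        return np.empty(0), {}
    amps = snippets.waveforms.max(axis=1) - snippets.waveforms.min(axis=1)
    stats: dict = {}
    if groups is not None:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            a = amps[groups == g]
            stats[g] = (float(a.mean()), float(a.std()), int(a.size))
    else:
        stats["all"] = (float(amps.mean()), float(amps.std()), int(amps.size))
    return amps, stats


def compute_snr(
    filtered_trace: np.ndarray,
    spike_times: np.ndarray,
    rate: float,
    guard: float = 0.001,
) -> float:
    """Signal-to-noise ratio: rms over spike windows / rms elsewhere.

    Spike windows are ±``guard`` seconds around each spike time; all
    remaining samples count as noise.
    """
    spike_times = np.asarray(spike_times)
    if spike_times.size == 0:
        raise ValueError("SNR undefined without spikes")
    x = np.asarray(filtered_trace, dtype=np.float64)
    g = int(round(guard * rate))
    mask = np.zeros(len(x), dtype=bool)
    for i in np.round(spike_times * rate).astype(int):
        mask[max(0, i - g) : min(len(x), i + g + 1)] = True
    sig = np.sqrt(np.mean(x[mask] ** 2))
    noise = np.sqrt(np.mean(x[~mask] ** 2))
    return float(sig / noise)


def pca_features(snippets: SnippetArray, d: int = 8) -> np.ndarray:
    """Project snippets onto the top-``d`` principal axes (n_spikes x d).

    Deterministic: each axis's sign is fixed so its largest-magnitude
    loading is positive.
    """
    n = len(snippets)
    if n <= d:
        raise ValueError(f"need more than {d} spikes for {d}-D PCA, got {n}")
    pca = PCA(n_components=d, svd_solver="full")
    feats = pca.fit_transform(snippets.waveforms)
    for j in range(d):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            feats[:, j] *= -1
    return feats


def kmeans_cluster(
    features: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10
) -> np.ndarray:
    """k-means unit isolation; labels in 1..k, deterministic given seed.

    Runs ``n_restarts`` seeded initializations and keeps the partition
    with minimal within-cluster sum of squares.
    """
    features = np.asarray(features)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(features):
        raise ValueError(f"k={k} exceeds {len(features)} spikes")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(features) + 1


def suggest_k(features: np.ndarray, k_max: int = 5, seed: int = 0) -> int:
    """Silhouette-based suggestion for k (advisory only, never auto-applied)."""
    from sklearn.metrics import silhouette_score

    features = np.asarray(features)
    best_k, best_s = 1, -np.inf
    for k in range(2, min(k_max, len(features) - 1) + 1):
        labels = kmeans_cluster(features, k, seed=seed)
        s = silhouette_score(features, labels)
        if s > best_s:
            best_k, best_s = k, s
    return best_k
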