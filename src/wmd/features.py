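"""Wavelet-maxima-density (WMD) features.

The persistent-maxima stream of a flexion is cut into 300 ms windows
and the maxima magnitudes are clustered into four groups — one per
candidate muscle, since volume conduction gives each muscle's MUAPs a
characteristic magnitude.  Each window yields an 8-vector of cluster
centroids plus densities (counts); clustering is either per window or
against magnitude levels shared across the flexion, and window stats
can additionally be averaged rank-wise into one vector per flexion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WindowSpec",
    "WindowClusterStats",
    "FlexionFeatures",
    "segment",
    "cluster_window",
    "window_stats",
    "global_window_stats",
    "flexion_features",
    "FEATURE_COLUMNS",
]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["c1", "c2", "c3", "c4", "d1", "d2", "d3", "d4"]


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window: 300 ms default, the permissible real-time delay."""

    length_ms: float = 300.0
    overlap_fraction: float = 0.0

    def __post_init__(self):
        if self.length_ms <= 0:
            raise ValueError("window length must be positive")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")

    def length_samples(self, fs: float) -> int:
        return int(np.floor(self.length_ms * fs / 1000.0))

    def hop_samples(self, fs: float) -> int:
        n = self.length_samples(fs)
        return max(int(round(n * (1.0 - self.overlap_fraction))), 1)


@dataclass(frozen=True)
class WindowClusterStats:
    """Centroids (ascending) and occupancy counts of the k magnitude groups."""

    centroids: tuple[float, ...]
    densities: tuple[int, ...]
    window_index: int
    degenerate: bool = False

    def feature_vector(self) -> np.ndarray:
        return np.asarray(self.centroids + self.densities, dtype=float)


@dataclass(frozen=True)
class FlexionFeatures:
    """Rank-wise means of the window stats over one flexion (8 values)."""

    mean_centroids: tuple[float, ...]
    mean_densities: tuple[float, ...]
    label: str | None = None
    n_windows: int = 0

    def feature_vector(self) -> np.ndarray:
        return np.asarray(self.mean_centroids + self.mean_densities, dtype=float)


def segment(maxima, recording_length: int, spec: WindowSpec, fs: float
            ) -> list[np.ndarray]:
    """Assign maxima magnitudes to half-open sample windows.

    Windows are [start, start + L) with hop L·(1 − overlap); the trailing
    partial window is dropped.  A maximum on the exact boundary sample
    belongs to the later window.
    """
    length = spec.length_samples(fs)
    hop = spec.hop_samples(fs)
    if recording_length < length:
        return []
    starts = np.arange(0, recording_length - length + 1, hop)
    positions = np.asarray([p for p, _ in maxima], dtype=int)
    magnitudes = np.asarray([m for _, m in maxima], dtype=float)
    out = []
    for start in starts:
        mask = (positions >= start) & (positions < start + length)
        out.append(magnitudes[mask])
    return out


def _contiguous_kmeans(x_sorted: np.ndarray, k: int):
    """Globally optimal 1-D k-means by dynamic programming.

    One-dimensional k-means optima are contiguous partitions of the
    sorted values, so the within-cluster sum of squares can be minimized
    exactly in O(k·n²).  Ties pick the smallest start index (first
    argmin), making the result fully deterministic.
    """
    n = len(x_sorted)
    ps = np.concatenate([[0.0], np.cumsum(x_sorted)])
    ps2 = np.concatenate([[0.0], np.cumsum(x_sorted**2)])

    def seg_cost(i, j):
        # SSE of x[i..j] inclusive; i may be an array
        cnt = j - i + 1
        s = ps[j + 1] - ps[i]
        return np.maximum((ps2[j + 1] - ps2[i]) - s * s / cnt, 0.0)

    D = np.full((k, n), np.inf)
    B = np.zeros((k, n), dtype=int)
    D[0] = seg_cost(np.zeros(n, dtype=int), np.arange(n))
    for m in range(1, k):
        for j in range(m, n):
            t = np.arange(m, j + 1)
            vals = D[m - 1][t - 1] + seg_cost(t, j)
            a = int(np.argmin(vals))
            D[m][j] = vals[a]
            B[m][j] = m + a
    bounds = [n]
    j = n - 1
    for m in range(k - 1, 0, -1):
        start = B[m][j]
        bounds.append(start)
        j = start - 1
    bounds.append(0)
    bounds = bounds[::-1]
    centroids = []
    counts = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        centroids.append(float(x_sorted[a:b].mean()))
        counts.append(b - a)
    return centroids, counts, float(D[k - 1][n - 1])


def cluster_window(magnitudes, k: int = 4,
                   window_index: int = 0) -> WindowClusterStats:
    """Group one window's maxima magnitudes into k magnitude clusters.

    Solves 1-D k-means to global optimality (see ``_contiguous_kmeans``);
    centroids come out sorted ascending with densities in matching
    order.  Windows with fewer than k maxima cannot support k groups and
    raise; callers exclude them from flexion averaging.  A window whose
    magnitudes have fewer than k distinct values is returned but flagged
    degenerate (clusters collapse).
    """
    x = np.sort(np.asarray(magnitudes, dtype=float))
    if len(x) < k:
        raise ValueError(
            f"window has {len(x)} maxima, fewer than k={k}: cannot form clusters"
        )
    centroids, counts, _ = _contiguous_kmeans(x, k)
    degenerate = len(np.unique(x)) < k
    return WindowClusterStats(
        centroids=tuple(centroids), densities=tuple(counts),
        window_index=window_index, degenerate=degenerate,
    )


def global_window_stats(windows: list[np.ndarray], k: int = 4) -> list[WindowClusterStats]:
    """Cluster the whole flexion's magnitudes once; count per window.

    The k magnitude levels are estimated from every persistent maximum
    of the flexion (same optimal 1-D k-means), then each window's
    density vector counts its maxima against those shared levels
    (nearest-centroid assignment, boundaries at centroid midpoints).
    This keeps cluster ranks aligned across the windows of a flexion:
    a window in which the strongest muscle happened not to fire keeps a
    zero count in the top cluster instead of promoting a weaker one.
    Every window yields a row; an empty window is all-zero densities.
    Returns [] when the flexion has fewer than k maxima in total.
    """
    pooled = np.sort(np.concatenate([np.asarray(w, dtype=float) for w in windows])
                     if windows else np.empty(0))
    if len(pooled) < k:
        return []
    centroids, _, _ = _contiguous_kmeans(pooled, k)
    centroids = np.asarray(centroids)
    edges = np.concatenate([[-np.inf], (centroids[:-1] + centroids[1:]) / 2, [np.inf]])
    degenerate = len(np.unique(pooled)) < k
    stats = []
    for i, mags in enumerate(windows):
        counts, _ = np.histogram(np.asarray(mags, dtype=float), bins=edges)
        stats.append(WindowClusterStats(
            centroids=tuple(float(c) for c in centroids),
            densities=tuple(int(c) for c in counts),
            window_index=i, degenerate=degenerate,
        ))
    return stats


def window_stats(windows: list[np.ndarray], k: int = 4) -> list[WindowClusterStats]:
    """Cluster every window, silently skipping those with too few maxima."""
    stats = []
    skipped = 0
    for i, mags in enumerate(windows):
        if len(mags) < k:
            skipped += 1
            continue
        stats.append(cluster_window(mags, k=k, window_index=i))
    if skipped:
        logger.debug("excluded %d/%d windows with < %d maxima",
                     skipped, len(windows), k)
    return stats


def flexion_features(stats: list[WindowClusterStats], label: str | None = None,
                     normalize_density: bool = False,
                     window_len_s: float | None = None) -> FlexionFeatures:
    """Average window cluster stats rank-wise over one flexion.

    Cluster r of the flexion is the r-th smallest centroid of each
    window; densities are raw per-window counts unless
    ``normalize_density`` converts them to maxima per second.
    """
    if not stats:
        raise ValueError("flexion has no valid windows; excluded from the feature set")
    C = np.asarray([s.centroids for s in stats], dtype=float)
    D = np.asarray([s.densities for s in stats], dtype=float)
    if normalize_density:
        if not window_len_s:
            raise ValueError("window_len_s required to normalize densities")
        D = D / window_len_s
    return FlexionFeatures(
        mean_centroids=tuple(C.mean(axis=0)),
        mean_densities=tuple(D.mean(axis=0)),
        label=label, n_windows=len(stats),
    )
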