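"""Data-driven clustering-threshold calibration.

Pairwise scores from a repertoire are strongly bimodal: clonally related
pairs pile up near zero, unrelated pairs form a broad mode well above one.
The clustering threshold is read off the histogram as the trough — the
lowest-frequency bin strictly between the two dominant modes. Cross-family
sentinel scores are excluded from the histogram entirely; they carry no
information about the boundary and would distort the search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metric import ScoreParams, condensed_distances

__all__ = ["ScoreHistogram", "CalibrationError", "score_histogram", "find_trough"]


class CalibrationError(RuntimeError):
    """The score histogram has no usable two-mode structure; choose a
    threshold manually."""


@dataclass
class ScoreHistogram:
    bin_edges: np.ndarray  # len(counts) + 1, increasing
    counts: np.ndarray  # non-negative ints
    n_pairs: int  # number of binned (non-sentinel) scores

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts must have one fewer entry than bin_edges")
        if self.counts.sum() != self.n_pairs:
            raise ValueError("counts must sum to n_pairs")

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def score_histogram(
    records,
    n_sample: int = 1000,
    bin_width: float = 0.05,
    seed: int | None = None,
    params: ScoreParams | None = None,
) -> ScoreHistogram:
    """Histogram of all-vs-all pairwise scores over a random subsample.

    ``n_sample`` records are drawn uniformly without replacement (seeded),
    scored all-vs-all, and the non-sentinel scores are binned at fixed width
    over [0, max score].
    """
    if params is None:
        params = ScoreParams()
    if n_sample < 2:
        raise ValueError("n_sample must be at least 2")
    if n_sample > len(records):
        raise ValueError(f"n_sample={n_sample} exceeds {len(records)} records")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n_sample, replace=False)
    sample = [records[i] for i in sorted(idx)]
    scores = condensed_distances(sample, params)
    scores = scores[scores < params.sentinel_distance]
    if scores.size == 0:
        raise CalibrationError("no non-sentinel scores to histogram")
    n_bins = max(1, int(np.ceil(scores.max() / bin_width)))
    edges = np.arange(n_bins + 1, dtype=np.float64) * bin_width
    if edges[-1] <= scores.max():  # right edge must cover the max score
        edges = np.append(edges, edges[-1] + bin_width)
    counts, _ = np.histogram(scores, bins=edges)
    return ScoreHistogram(bin_edges=edges, counts=counts, n_pairs=int(scores.size))


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average, window clipped at the array edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    half = window // 2
    out = np.empty(len(counts), dtype=np.float64)
    for i in range(len(counts)):
        lo, hi = max(0, i - half), min(len(counts), i + half + 1)
        out[i] = counts[lo:hi].mean()
    return out


def _local_maxima(s: np.ndarray) -> list[int]:
    """Indices of local maxima; a plateau contributes its leftmost index.
    Array ends count as maxima when they dominate their inner neighbor."""
    maxima = []
    n = len(s)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        left_ok = i == 0 or s[i - 1] < s[i]
        right_ok = j == n - 1 or s[j + 1] < s[i]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            maxima.append(i)
        i = j + 1
    return maxima


def find_trough(histogram: ScoreHistogram, smoothing_window: int = 5) -> float:
    """Threshold at the trough between the two dominant score modes.

    Counts are smoothed with a centred moving average and local maxima are
    located. The related/unrelated modes are taken as the pair of maxima
    with the deepest valley between them — the pair maximizing
    ``min(height(m1), height(m2)) - min(counts between)`` — which keeps the
    search on the dominant bimodal divide even when the broad unrelated mode
    is ragged with several local bumps. The bin-center of the minimum
    smoothed count strictly between the two modes is returned (leftmost bin
    on ties). Raises :class:`CalibrationError` when fewer than two modes
    exist.
    """
    smoothed = _smooth(histogram.counts, smoothing_window)
    maxima = _local_maxima(smoothed)
    if len(maxima) < 2:
        raise CalibrationError(
            "score histogram is unimodal after smoothing; "
            "set the clustering threshold manually"
        )
    best = None  # (depth, lo, hi)
    for a in range(len(maxima)):
        for b in range(a + 1, len(maxima)):
            lo, hi = maxima[a], maxima[b]
            if hi - lo < 2:
                continue
            valley = smoothed[lo + 1 : hi].min()
            depth = min(smoothed[lo], smoothed[hi]) - valley
            if best is None or depth > best[0]:
                best = (depth, lo, hi)
    if best is None:
        raise CalibrationError("dominant modes are adjacent; no trough between them")
    _, lo, hi = best
    between = smoothed[lo + 1 : hi]
    trough_idx = lo + 1 + int(np.argmin(between))
    return float(histogram.bin_centers[trough_idx])
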