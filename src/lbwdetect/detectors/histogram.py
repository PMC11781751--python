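"""Histogram- and ECDF-based detectors (HBOS and ECOD).

Both assume feature independence and aggregate per-feature log tail
evidence, which makes them fast and well suited to the min-max scaled
matrices produced by the preprocessing pipeline.
"""

from __future__ import annotations

import math

import numpy as np

from .base import AnomalyScorer


class HBOS(AnomalyScorer):
    """Histogram-based outlier score.

    Each feature gets an equal-width histogram over its training range
    (default ceil(sqrt(n)) bins). A query's score is the sum over features
    of -log(normalized bin height), where heights are counts/n with a
    smoothing floor of 0.1/n, so empty bins and out-of-range values score
    high but stay finite.
    """

    def __init__(self, n_bins: int | None = None, smoothing: float = 0.1, seed: int = 0):
        super().__init__(seed=seed)
        if n_bins is not None and n_bins < 1:
            raise ValueError("n_bins must be positive")
        self.n_bins = n_bins
        self.smoothing = float(smoothing)

    def _fit(self, X: np.ndarray) -> None:
        n, d = X.shape
        b = self.n_bins if self.n_bins is not None else max(1, math.ceil(math.sqrt(n)))
        self._floor = self.smoothing / n
        self._edges: list[np.ndarray] = []
        self._heights: list[np.ndarray] = []
        for j in range(d):
            col = X[:, j]
            lo, hi = col.min(), col.max()
            if hi <= lo:  # constant feature: a single degenerate bin
                self._edges.append(np.array([lo, lo]))
                self._heights.append(np.array([1.0]))
                continue
            counts, edges = np.histogram(col, bins=b, range=(lo, hi))
            self._edges.append(edges)
            self._heights.append(counts / n)

    def _score(self, X: np.ndarray) -> np.ndarray:
        total = np.zeros(X.shape[0])
        for j, (edges, heights) in enumerate(zip(self._edges, self._heights)):
            col = X[:, j]
            lo, hi = edges[0], edges[-1]
            if len(heights) == 1:  # constant training feature
                h = np.where(col == lo, 1.0, self._floor)
            else:
                pos = np.clip(np.searchsorted(edges, col, side="right") - 1,
                              0, len(heights) - 1)
                inside = (col >= lo) & (col <= hi)
                h = np.where(inside, heights[pos], 0.0)
            total += -np.log(np.maximum(h, self._floor))
        return total


class ECOD(AnomalyScorer):
    """Empirical-CDF outlier detection, two-sided min-tail form.

    Per dimension the tail probability of a query value x is
    min(F(x), 1 - F(x-)) from the training ECDF, floored at 1/(n+1) so a
    value outside the observed range still gets finite evidence. The score
    sums -log(tail) over dimensions. (The published variant additionally
    selects sides by skewness; this implementation uses the symmetric
    min-tail rule throughout.)
    """

    def _fit(self, X: np.ndarray) -> None:
        self._sorted = [np.sort(X[:, j]) for j in range(X.shape[1])]
        self._n = X.shape[0]

    def _score(self, X: np.ndarray) -> np.ndarray:
        n = self._n
        floor = 1.0 / (n + 1)
        total = np.zeros(X.shape[0])
        for j, col_sorted in enumerate(self._sorted):
            x = X[:, j]
            f_left = np.searchsorted(col_sorted, x, side="right") / n   # P(X <= x)
            f_right = (n - np.searchsorted(col_sorted, x, side="left")) / n  # P(X >= x)
            tail = np.maximum(np.minimum(f_left, f_right), floor)
            total += -np.log(tail)
        return total
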