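"""Native isolation forest with per-tree path-length access.

Anomalies are points that are easy to isolate by random axis-aligned
splits: the expected root-to-leaf path length h(x, T) over a forest of
random trees is short for outliers. The score of a point is

    s(x) = 2 ** ( - E[h(x, T)] / c(psi) )

where psi is the subsample size used to grow each tree and c(n) is the
average path length of an unsuccessful BST search,

    c(1) = 0,   c(2) = 1,   c(n) = 2 H(n-1) - 2 (n-1)/n   (n > 2),

with H the harmonic number (evaluated exactly, not by the log
approximation). Scores lie in (0, 1); 0.5 corresponds to E[h] = c(psi).

The per-tree path lengths are exposed (:meth:`IsolationForest
.path_lengths`) because the depth-based local feature-importance method
needs h(x, T) for the original and the perturbed instance in every tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .base import AnomalyScorer

# exact harmonic numbers, grown on demand: _HARMONIC[k] = H(k), H(0) = 0
_HARMONIC = np.zeros(1)


def _harmonic(n: int) -> np.ndarray:
    global _HARMONIC
    if n >= len(_HARMONIC):
        extra = 1.0 / np.arange(len(_HARMONIC), n + 1)
        _HARMONIC = np.concatenate([_HARMONIC, _HARMONIC[-1] + np.cumsum(extra)])
    return _HARMONIC


def average_path_length(n) -> np.ndarray:
    """c(n): expected unsuccessful-search path length of a BST with n points."""
    n = np.asarray(n)
    scalar = n.ndim == 0
    n = np.atleast_1d(n).astype(int)
    H = _harmonic(int(n.max(initial=1)))
    out = np.zeros(n.shape, dtype=float)
    big = n >= 2
    nb = n[big]
    out[big] = 2.0 * H[nb - 1] - 2.0 * (nb - 1) / nb
    return out[0] if scalar else out


@dataclass
class IsolationTree:
    """Flat array representation of one isolation tree.

    ``feature[i] == -1`` marks a leaf; ``size[i]`` is the number of training
    rows that reached node i (used for the c(size) leaf adjustment).
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    size: np.ndarray

    def path_lengths(self, X: np.ndarray) -> np.ndarray:
        """h(x, T) per row: traversal depth plus c(leaf size)."""
        n = X.shape[0]
        node = np.zeros(n, dtype=np.intp)
        depth = np.zeros(n, dtype=float)
        active = self.feature[node] >= 0
        while active.any():
            rows = np.flatnonzero(active)
            nd = node[rows]
            f = self.feature[nd]
            go_left = X[rows, f] < self.threshold[nd]
            node[rows] = np.where(go_left, self.left[nd], self.right[nd])
            depth[rows] += 1.0
            active = self.feature[node] >= 0
        return depth + average_path_length(self.size[node])


def build_tree(X: np.ndarray, rng: np.random.Generator, height_limit: int) -> IsolationTree:
    """Grow one tree: uniform random non-constant feature, uniform split point."""
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    size: list[int] = []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        size.append(0)
        return len(feature) - 1

    stack: list[tuple[np.ndarray, int, int]] = [(np.arange(X.shape[0]), 0, new_node())]
    while stack:
        idx, depth, slot = stack.pop()
        size[slot] = len(idx)
        if depth >= height_limit or len(idx) <= 1:
            continue
        sub = X[idx]
        lo, hi = sub.min(axis=0), sub.max(axis=0)
        usable = np.flatnonzero(hi > lo)
        if usable.size == 0:
            continue
        f = int(usable[rng.integers(usable.size)])
        p = float(rng.uniform(lo[f], hi[f]))
        mask = sub[:, f] < p
        if not mask.any() or mask.all():  # degenerate draw at the boundary
            continue
        feature[slot] = f
        threshold[slot] = p
        ls, rs = new_node(), new_node()
        left[slot], right[slot] = ls, rs
        stack.append((idx[mask], depth + 1, ls))
        stack.append((idx[~mask], depth + 1, rs))

    return IsolationTree(
        feature=np.asarray(feature, dtype=np.intp),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.intp),
        right=np.asarray(right, dtype=np.intp),
        size=np.asarray(size, dtype=np.intp),
    )


class IsolationForest(AnomalyScorer):
    """Isolation forest (default 100 trees, subsample 256 capped at n)."""

    def __init__(self, n_trees: int = 100, subsample: int = 256, seed: int = 0):
        super().__init__(seed=seed)
        if n_trees < 1 or subsample < 2:
            raise ValueError("need at least one tree and a subsample of >= 2")
        self.n_trees = int(n_trees)
        self.subsample = int(subsample)
        self.trees_: list[IsolationTree] = []
        self.psi_: int | None = None

    def _fit(self, X: np.ndarray) -> None:
        n = X.shape[0]
        if n < 2:
            raise ValueError("isolation forest needs at least 2 training rows")
        self.psi_ = min(self.subsample, n)
        height_limit = math.ceil(math.log2(self.psi_))
        self.trees_ = []
        for child in np.random.SeedSequence(self.seed).spawn(self.n_trees):
            rng = np.random.default_rng(child)
            sample = rng.choice(n, size=self.psi_, replace=False)
            self.trees_.append(build_tree(X[sample], rng, height_limit))

    def path_lengths(self, X) -> np.ndarray:
        """Matrix of h(x, T), shape (n_trees, n_rows)."""
        if self.n_features_ is None:
            raise RuntimeError("scorer must be fitted before scoring")
        X = self._validate(X)
        if X.shape[1] != self.n_features_:
            raise ValueError("query column count does not match training")
        return np.vstack([t.path_lengths(X) for t in self.trees_])

    def _score(self, X: np.ndarray) -> np.ndarray:
        mean_h = np.vstack([t.path_lengths(X) for t in self.trees_]).mean(axis=0)
        return np.power(2.0, -mean_h / average_path_length(self.psi_))
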