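"""k-nearest-neighbor distance detector."""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .base import AnomalyScorer


class KNN(AnomalyScorer):
    """Euclidean distance to the k-th nearest training row (default k=5).

    A query far from every training (normal) point gets a large score.
    Training requires strictly more than k rows. When a training row is
    scored, it is its own 0-distance neighbor, as the contract counts all
    training rows. Distance ties do not affect the k-th distance value.
    """

    def __init__(self, k: int = 5, seed: int = 0):
        super().__init__(seed=seed)
        if k < 1:
            raise ValueError("k must be a positive integer")
        self.k = int(k)

    def _fit(self, X: np.ndarray) -> None:
        if X.shape[0] <= self.k:
            raise ValueError(
                f"knn needs more than k={self.k} training rows, got {X.shape[0]}"
            )
        self._nn = NearestNeighbors(n_neighbors=self.k).fit(X)

    def _score(self, X: np.ndarray) -> np.ndarray:
        dist, _ = self._nn.kneighbors(X, n_neighbors=self.k)
        return dist[:, -1]
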