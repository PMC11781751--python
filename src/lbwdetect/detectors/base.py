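"""Scorer contract shared by every anomaly detector.

A scorer is fitted on normal rows only and returns one scalar anomaly score
per query row, with the fixed orientation *higher = more anomalous*. All
randomness derives from a single integer seed via ``numpy.random
.SeedSequence`` spawning, so fits are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ScorerSpec:
    """Named detector with hyperparameter overrides and a seed."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0


class AnomalyScorer:
    """Base class: ``fit(X)`` on normal rows, ``score(X)`` higher = anomalous."""

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self.n_features_: int | None = None

    # -- subclass hooks --------------------------------------------------
    def _fit(self, X: np.ndarray) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def _score(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    # -- public contract -------------------------------------------------
    def fit(self, X) -> "AnomalyScorer":
        X = self._validate(X, fitting=True)
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty training matrix")
        self.n_features_ = X.shape[1]
        self._fit(X)
        return self

    def score(self, X) -> np.ndarray:
        if self.n_features_ is None:
            raise RuntimeError("scorer must be fitted before scoring")
        X = self._validate(X)
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"query has {X.shape[1]} columns, model was trained on {self.n_features_}"
            )
        out = np.asarray(self._score(X), dtype=float)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite anomaly score produced")
        return out

    @staticmethod
    def _validate(X, fitting: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2:
            raise ValueError("expected a 2-D feature matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite values")
        return X

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed))
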