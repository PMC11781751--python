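"""Anomaly-scorer registry.

Six detectors are implemented natively (isolation forest, HBOS, ECOD, kNN
distance, Gaussian mixture, PCA reconstruction). Any further detector —
one-class SVM, LOF, LODA, and friends — is plugged in through
:func:`adapt_external`, which wraps an arbitrary fit/score pair and
normalizes its orientation to the shared contract *higher = more
anomalous*.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .base import AnomalyScorer, ScorerSpec
from .histogram import ECOD, HBOS
from .iforest import IsolationForest, IsolationTree, average_path_length, build_tree
from .mixture import GMM
from .neighbors import KNN
from .pca_recon import PCAReconstruction

__all__ = [
    "AnomalyScorer", "ScorerSpec", "IsolationForest", "IsolationTree",
    "average_path_length", "build_tree", "HBOS", "ECOD", "KNN", "GMM",
    "PCAReconstruction", "NATIVE_DETECTORS", "make_scorer", "adapt_external",
    "list_detectors",
]

#: The native roster, addressable by name from config files and the CLI.
NATIVE_DETECTORS: dict[str, type] = {
    "iforest": IsolationForest,
    "hbos": HBOS,
    "ecod": ECOD,
    "knn": KNN,
    "gmm": GMM,
    "pca": PCAReconstruction,
}

_registry: dict[str, Callable[[ScorerSpec], AnomalyScorer]] = {
    name: (lambda spec, _cls=cls: _cls(seed=spec.seed, **spec.params))
    for name, cls in NATIVE_DETECTORS.items()
}

#: Orientation declarations accepted by :func:`adapt_external`.
ORIENTATIONS = ("higher_is_anomalous", "lower_is_anomalous")


class _AdapterScorer(AnomalyScorer):
    """Wrapper giving an external fit/score pair the native contract."""

    def __init__(self, fit_fn, score_fn, flip: bool, seed: int = 0):
        super().__init__(seed=seed)
        self._fit_fn = fit_fn
        self._score_fn = score_fn
        self._flip = flip
        self._state = None

    def _fit(self, X: np.ndarray) -> None:
        self._state = self._fit_fn(X)

    def _score(self, X: np.ndarray) -> np.ndarray:
        s = np.asarray(self._score_fn(self._state, X), dtype=float)
        return -s if self._flip else s


def adapt_external(name: str, fit_fn: Callable, score_fn: Callable,
                   orientation: str) -> ScorerSpec:
    """Register an external detector under ``adapter:<name>``.

    ``fit_fn(X) -> state`` trains on the normal rows; ``score_fn(state, X)``
    returns one score per row. ``orientation`` must be declared explicitly:
    scorers whose convention is *lower = more anomalous* (e.g. library
    ``score_samples`` log-densities) are negated so the registered scorer
    honors higher-is-anomalous. Returns a ready :class:`ScorerSpec`.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(
            f"orientation must be one of {ORIENTATIONS}, got {orientation!r}; "
            "refusing to register a scorer with undeclared orientation"
        )
    key = f"adapter:{name}"
    if key in _registry:
        raise ValueError(f"a scorer named {key!r} is already registered")
    flip = orientation == "lower_is_anomalous"
    _registry[key] = lambda spec: _AdapterScorer(
        fit_fn, score_fn, flip, seed=spec.seed, **spec.params
    )
    return ScorerSpec(name=key)


def unregister_adapter(name: str) -> None:
    """Remove an adapter registration (mainly for test isolation)."""
    _registry.pop(f"adapter:{name}", None)


def make_scorer(spec: ScorerSpec) -> AnomalyScorer:
    """Instantiate the detector named by ``spec`` with its params and seed."""
    if spec.name not in _registry:
        raise KeyError(
            f"unknown detector {spec.name!r}; known: {sorted(_registry)}"
        )
    return _registry[spec.name](spec)


def list_detectors() -> list[str]:
    return sorted(_registry)
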