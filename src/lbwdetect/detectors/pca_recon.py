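"""Principal-component reconstruction-error detector."""

from __future__ import annotations

import numpy as np

from .base import AnomalyScorer


class PCAReconstruction(AnomalyScorer):
    """Squared reconstruction error in a truncated principal subspace.

    The training (normal) data is centered and decomposed by SVD; the
    number of retained components q is the smallest count explaining at
    least ``var_explained`` of the training variance (default 0.9), unless
    ``n_components`` fixes it. Points poorly represented by the normal
    subspace get large scores. With q equal to the full rank the error is
    zero for any point in the training span.
    """

    def __init__(self, var_explained: float = 0.9, n_components: int | None = None,
                 seed: int = 0):
        super().__init__(seed=seed)
        if not 0 < var_explained <= 1:
            raise ValueError("var_explained must be in (0, 1]")
        if n_components is not None and n_components < 1:
            raise ValueError("n_components must be positive")
        self.var_explained = float(var_explained)
        self.n_components = n_components

    def _fit(self, X: np.ndarray) -> None:
        self.mean_ = X.mean(axis=0)
        _, s, Vt = np.linalg.svd(X - self.mean_, full_matrices=False)
        var = s ** 2
        total = var.sum()
        if self.n_components is not None:
            q = min(self.n_components, len(s))
        elif total <= 0:  # constant training matrix
            q = 1
        else:
            ratio = np.cumsum(var) / total
            q = int(np.searchsorted(ratio, self.var_explained - 1e-12) + 1)
            q = min(q, len(s))
        self.components_ = Vt[:q]
        self.q_ = q

    def _score(self, X: np.ndarray) -> np.ndarray:
        R = X - self.mean_
        recon = (R @ self.components_.T) @ self.components_
        return ((R - recon) ** 2).sum(axis=1)
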