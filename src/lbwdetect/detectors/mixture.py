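"""Gaussian mixture detector: negative log-likelihood as anomaly score."""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .base import AnomalyScorer

_LOG2PI = np.log(2.0 * np.pi)


class GMM(AnomalyScorer):
    """Diagonal-covariance Gaussian mixture fitted by EM.

    The anomaly score of x is the negative log-density under the fitted
    mixture, so the score is minimized near the bulk of the normal class.
    Defaults to a single component (a regularized Gaussian fit, no EM
    iterations needed); variances carry an additive ridge so degenerate
    (constant) features cannot produce infinite densities.
    """

    def __init__(self, components: int = 1, ridge: float = 1e-6,
                 max_iter: int = 200, tol: float = 1e-6, seed: int = 0):
        super().__init__(seed=seed)
        if components < 1:
            raise ValueError("components must be >= 1")
        self.components = int(components)
        self.ridge = float(ridge)
        self.max_iter = int(max_iter)
        self.tol = float(tol)

    def _log_gauss(self, X: np.ndarray) -> np.ndarray:
        """(n, k) log N(x | mu_c, diag(var_c)) matrix."""
        n, d = X.shape
        out = np.empty((n, self.components))
        for c in range(self.components):
            diff2 = (X - self.means_[c]) ** 2 / self.vars_[c]
            out[:, c] = -0.5 * (diff2.sum(axis=1) + np.log(self.vars_[c]).sum() + d * _LOG2PI)
        return out

    def _fit(self, X: np.ndarray) -> None:
        n, d = X.shape
        k = self.components
        if n < k:
            raise ValueError(f"need at least {k} rows to fit {k} components")
        base_var = X.var(axis=0) + self.ridge
        if k == 1:
            self.means_ = X.mean(axis=0)[None, :]
            self.vars_ = base_var[None, :]
            self.log_weights_ = np.zeros(1)
            return
        rng = self.rng()
        self.means_ = X[rng.choice(n, size=k, replace=False)].copy()
        self.vars_ = np.tile(base_var, (k, 1))
        self.log_weights_ = np.full(k, -np.log(k))
        prev_ll = -np.inf
        for _ in range(self.max_iter):
            log_joint = self._log_gauss(X) + self.log_weights_
            norm = logsumexp(log_joint, axis=1)
            ll = norm.mean()
            resp = np.exp(log_joint - norm[:, None])
            nk = resp.sum(axis=0) + 1e-12
            self.means_ = (resp.T @ X) / nk[:, None]
            for c in range(k):
                diff2 = (X - self.means_[c]) ** 2
                self.vars_[c] = (resp[:, c] @ diff2) / nk[c] + self.ridge
            self.log_weights_ = np.log(nk / n)
            if abs(ll - prev_ll) < self.tol:
                break
            prev_ll = ll

    def _score(self, X: np.ndarray) -> np.ndarray:
        return -logsumexp(self._log_gauss(X) + self.log_weights_, axis=1)
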