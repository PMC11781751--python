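"""Per-instance feature attribution for fitted anomaly scorers.

Two local attribution methods are provided, both based on replacing one
source feature of an instance with a baseline (mean) value and watching the
model react:

* **Score perturbation** (model-agnostic): for each source feature i build
  x_i' by substituting the baseline into every encoded column of i and
  record ``delta_S_i = S_o - S_{m,i}``, the original minus the perturbed
  anomaly score. With the higher-is-anomalous orientation, a positive
  delta means the feature's observed value pushed the score *up* (made the
  instance look more anomalous). Features are ranked by |delta_S_i|.

* **Local depth-based importance** (isolation forest only): for each tree T
  of a native isolation forest, ``I_i = mean_T |h(x, T) - h(x_i', T)|`` —
  the absolute path-length change under the same substitution, averaged
  over trees. Features whose values steer the instance into short
  (isolated) branches get large importances.

One-hot encoded categorical features are perturbed as a block: all their
indicator columns are replaced together by the (fractional) baseline means,
the literal mean-substitution rule. Ranks use average tie-handling so
aggregation over many outliers is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .detectors import AnomalyScorer, IsolationForest
from .preprocess import FeatureMatrix

BASELINE_PROVENANCES = ("training-normal-means", "test-set-means")


@dataclass
class Baseline:
    """Per-encoded-column substitution values mu with their provenance."""

    values: np.ndarray
    provenance: str = "training-normal-means"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("baseline values must be finite")
        if self.provenance not in BASELINE_PROVENANCES:
            raise ValueError(f"provenance must be one of {BASELINE_PROVENANCES}")


def compute_baseline(features: FeatureMatrix | np.ndarray,
                     rows: np.ndarray | None = None,
                     provenance: str = "training-normal-means") -> Baseline:
    """Column means over the given rows (default: all rows passed in)."""
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if rows is not None:
        X = X[np.asarray(rows)]
    if X.shape[0] == 0:
        raise ValueError("no rows to compute a baseline from")
    return Baseline(values=X.mean(axis=0), provenance=provenance)


@dataclass
class Attribution:
    """Per-feature importances for one instance, with derived ranks."""

    instance_id: object
    score_origin: float
    features: tuple[str, ...]
    values: np.ndarray          # delta_S_i (signed) or I_i (non-negative)
    ranks: np.ndarray           # 1 = most influential; average-rank ties
    method: str                 # 'perturb' or 'diffi'

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "instance": self.instance_id,
            "feature": self.features,
            "value": self.values,
            "abs_value": np.abs(self.values),
            "rank": self.ranks,
            "method": self.method,
        })


def _ranks_desc(magnitudes: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(-np.asarray(magnitudes, float), method="average")


def _check_columns(model: AnomalyScorer, x: np.ndarray, baseline: Baseline,
                   feature_groups: Mapping[str, np.ndarray]) -> None:
    d = model.n_features_
    if d is None:
        raise RuntimeError("model must be fitted")
    if x.shape != (d,):
        raise ValueError(f"instance has shape {x.shape}, model expects ({d},)")
    if baseline.values.shape != (d,):
        raise ValueError("baseline does not match model columns")
    all_cols = np.concatenate([np.asarray(v) for v in feature_groups.values()])
    if all_cols.size and (all_cols.max() >= d or all_cols.min() < 0):
        raise ValueError("feature group indices outside model columns")


def perturb_attribution(model: AnomalyScorer, x, baseline: Baseline,
                        feature_groups: Mapping[str, Sequence[int]],
                        instance_id: object = None) -> Attribution:
    """Mean-substitution score attribution, exact by construction.

    All perturbed variants are scored in one batch; each delta still equals
    ``score(x) - score(x_i')`` for the individually substituted instance.
    """
    x = np.asarray(x, dtype=float).ravel()
    _check_columns(model, x, baseline, feature_groups)
    names = tuple(feature_groups)
    batch = np.tile(x, (len(names) + 1, 1))
    for row, name in enumerate(names, start=1):
        cols = np.asarray(feature_groups[name], dtype=int)
        batch[row, cols] = baseline.values[cols]
    scores = model.score(batch)
    s_o = float(scores[0])
    deltas = s_o - scores[1:]
    return Attribution(
        instance_id=instance_id,
        score_origin=s_o,
        features=names,
        values=deltas,
        ranks=_ranks_desc(np.abs(deltas)),
        method="perturb",
    )


def local_diffi(model: AnomalyScorer, x, baseline: Baseline,
                feature_groups: Mapping[str, Sequence[int]],
                instance_id: object = None) -> Attribution:
    """Depth-based local importance; requires the native isolation forest."""
    if not isinstance(model, IsolationForest):
        raise TypeError(
            "local depth-based importance needs the native isolation forest "
            "(per-tree path lengths); use perturb_attribution for other models"
        )
    x = np.asarray(x, dtype=float).ravel()
    _check_columns(model, x, baseline, feature_groups)
    names = tuple(feature_groups)
    batch = np.tile(x, (len(names) + 1, 1))
    for row, name in enumerate(names, start=1):
        cols = np.asarray(feature_groups[name], dtype=int)
        batch[row, cols] = baseline.values[cols]
    h = model.path_lengths(batch)               # (n_trees, d + 1)
    imp = np.abs(h[:, 1:] - h[:, [0]]).mean(axis=0)
    return Attribution(
        instance_id=instance_id,
        score_origin=float(model.score(x[None])[0]),
        features=names,
        values=imp,
        ranks=_ranks_desc(imp),
        method="diffi",
    )


def select_outlier_points(labels=None, scores=None, mode: str = "label",
                          k: int | None = None) -> np.ndarray:
    """Row ids to aggregate attributions over.

    ``label`` mode (default) takes the labeled positives; ``top-k`` mode
    takes the k highest-scoring rows.
    """
    if mode == "label":
        if labels is None:
            raise ValueError("label mode needs labels")
        ids = np.flatnonzero(np.asarray(labels) == 1)
    elif mode == "top-k":
        if scores is None or k is None:
            raise ValueError("top-k mode needs scores and k")
        scores = np.asarray(scores, dtype=float)
        if k > scores.size:
            raise ValueError(f"k={k} exceeds {scores.size} rows")
        ids = np.sort(np.argsort(-scores, kind="stable")[:k])
    else:
        raise ValueError("mode must be 'label' or 'top-k'")
    if ids.size == 0:
        raise ValueError("empty outlier selection")
    return ids


def average_feature_ranks(attributions: Sequence[Attribution]) -> pd.Series:
    """Mean per-feature rank across outlier instances, sorted ascending.

    A lower mean rank means the feature was more influential more often.
    """
    if len(attributions) == 0:
        raise ValueError("no attributions to aggregate")
    names = attributions[0].features
    for a in attributions:
        if a.features != names:
            raise ValueError("attributions do not share a feature set")
    mat = np.vstack([a.ranks for a in attributions])
    out = pd.Series(mat.mean(axis=0), index=list(names), name="mean_rank")
    return out.sort_values(kind="stable")


def plot_mean_ranks(mean_ranks: pd.Series, path, title: str = "") -> None:
    """Optional horizontal bar chart of aggregated feature ranks."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.3 * len(mean_ranks) + 1.5))
    mean_ranks.iloc[::-1].plot.barh(ax=ax, color="steelblue")
    ax.set_xlabel("mean rank across outlier points (lower = more influential)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
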