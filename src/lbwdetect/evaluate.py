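"""Normal-only cross-validated evaluation: 2x5-fold CV, AUCROC/AUCPR, F-tests.

The evaluation protocol for one weight category is: stratify folds so every
test fold contains both classes, fit each detector on the *normal* rows of
the training folds only, score the full held-out fold, and record AUCROC
and AUCPR per fold. Detectors are then compared by a one-way ANOVA over
their fold-level AUCROC values.

AUCROC uses the Mann-Whitney formulation (probability that a random
positive outscores a random negative, ties credited 0.5). AUCPR is average
precision — the mean of precision evaluated at each positive's rank under a
descending, stable (row-order tie-break) sort — whose chance level equals
the positive prevalence, the natural baseline under extreme imbalance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.stats

from .detectors import ScorerSpec, make_scorer
from .preprocess import FeatureMatrix, Preprocessor, normal_only_split

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fold planning

@dataclass
class FoldPlan:
    """Stratified fold assignments, one vector per repeat."""

    repeats: int
    folds: int
    assignment: np.ndarray  # shape (repeats, n_rows), values in [0, folds)
    seed: int

    def __post_init__(self) -> None:
        if self.assignment.shape[0] != self.repeats:
            raise ValueError("assignment rows must equal repeats")


def make_folds(labels, repeats: int = 2, folds: int = 5, seed: int = 0,
               category: str = "") -> FoldPlan:
    """Stratified fold plan guaranteeing both classes in every test fold.

    Positives (and negatives) are shuffled independently per repeat and
    dealt round-robin across folds, so positive counts differ by at most
    one between folds. Requires at least ``folds`` rows of each class.
    """
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    tag = f" for category {category!r}" if category else ""
    if len(pos) < folds:
        raise ValueError(
            f"only {len(pos)} positive rows{tag} but {folds} folds requested; "
            "every test fold needs a positive — use fewer folds or more data"
        )
    if len(neg) < folds:
        raise ValueError(f"only {len(neg)} negative rows{tag} for {folds} folds")
    assignment = np.empty((repeats, labels.size), dtype=np.intp)
    for rep, child in enumerate(np.random.SeedSequence(seed).spawn(repeats)):
        rng = np.random.default_rng(child)
        for group in (pos, neg):
            order = rng.permutation(group)
            assignment[rep, order] = np.arange(order.size) % folds
    return FoldPlan(repeats=repeats, folds=folds, assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# metrics

def _check_two_class(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present to compute a ranking metric")
    return labels, pos


def auc_roc(scores, labels) -> float:
    """Mann-Whitney AUCROC: P(score_pos > score_neg) with 0.5 tie credit."""
    scores = np.asarray(scores, dtype=float)
    labels, pos = _check_two_class(labels)
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    ranks = scipy.stats.rankdata(scores)  # average ranks handle ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_pr(scores, labels) -> float:
    """Average precision under a descending stable sort.

    Equal scores keep their original row order, so the value is
    deterministic for any input.
    """
    scores = np.asarray(scores, dtype=float)
    labels, pos = _check_two_class(labels)
    order = np.argsort(-scores, kind="stable")
    hits = np.asarray(labels)[order] == 1
    cum_hits = np.cumsum(hits)
    ranks = np.arange(1, labels.size + 1)
    precision_at_pos = cum_hits[hits] / ranks[hits]
    return float(precision_at_pos.mean())


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class EvalReport:
    """Per-fold metric records plus convenience summaries.

    ``records`` columns: category, detector, repeat, fold, auc_roc, auc_pr,
    status ('ok' or the failure message; failed folds carry NaN metrics and
    are excluded from means).
    """

    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        ok = self.records[self.records["status"] == "ok"]
        return (
            ok.groupby(["category", "detector"], sort=False)[["auc_roc", "auc_pr"]]
            .mean()
            .reset_index()
        )

    def to_long(self) -> pd.DataFrame:
        return self.records.melt(
            id_vars=["category", "detector", "repeat", "fold", "status"],
            value_vars=["auc_roc", "auc_pr"],
            var_name="metric", value_name="value",
        )

    def fold_values(self, detector: str, metric: str = "auc_roc",
                    category: str | None = None) -> np.ndarray:
        df = self.records
        mask = (df["detector"] == detector) & (df["status"] == "ok")
        if category is not None:
            mask &= df["category"] == category
        return df.loc[mask, metric].to_numpy(dtype=float)

    @staticmethod
    def concat(reports: list["EvalReport"]) -> "EvalReport":
        return EvalReport(pd.concat([r.records for r in reports], ignore_index=True))


def _fold_seed(base_seed: int, repeat: int, fold: int) -> int:
    """Deterministic per-fold scorer seed derived from the spec seed."""
    ss = np.random.SeedSequence([int(base_seed), int(repeat), int(fold)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def cross_validate(features, labels, spec: ScorerSpec, plan: FoldPlan, *,
                   cohort: pd.DataFrame | None = None,
                   preprocessor: Preprocessor | None = None,
                   mode: str = "global",
                   category: str = "") -> EvalReport:
    """Run the normal-only CV protocol for one detector and one category.

    In the default ``global`` mode, ``features`` is the cohort-wide
    preprocessed matrix (transform statistics computed once on all rows, as
    the original pipeline does). In ``fold-safe`` mode, the raw ``cohort``
    frame and an unfitted ``preprocessor`` are required; the transform is
    refitted on each training fold's normal rows so no test information
    leaks into imputation or scaling.
    """
    labels = np.asarray(labels)
    if mode not in ("global", "fold-safe"):
        raise ValueError("mode must be 'global' or 'fold-safe'")
    if mode == "fold-safe":
        if cohort is None or preprocessor is None:
            raise ValueError("fold-safe mode needs the raw cohort and a preprocessor")
    else:
        if isinstance(features, FeatureMatrix):
            X_all = features.X
        else:
            X_all = np.asarray(features, dtype=float)

    rows = []
    for rep in range(plan.repeats):
        for fold in range(plan.folds):
            train_idx, test_idx = normal_only_split(labels, plan.assignment[rep], fold)
            scorer = make_scorer(replace(spec, seed=_fold_seed(spec.seed, rep, fold)))
            try:
                if mode == "fold-safe":
                    pp = Preprocessor(preprocessor.schema)
                    pp.fit(cohort.iloc[train_idx])
                    X_train = pp.transform(cohort.iloc[train_idx]).X
                    X_test = pp.transform(cohort.iloc[test_idx]).X
                else:
                    X_train, X_test = X_all[train_idx], X_all[test_idx]
                scorer.fit(X_train)
                s = scorer.score(X_test)
                roc = auc_roc(s, labels[test_idx])
                pr = auc_pr(s, labels[test_idx])
                status = "ok"
            except Exception as exc:  # recorded, excluded from means
                logger.error("detector %s failed on repeat %d fold %d: %s",
                             spec.name, rep, fold, exc)
                roc = pr = float("nan")
                status = f"failed: {exc}"
            rows.append({"category": category, "detector": spec.name,
                         "repeat": rep, "fold": fold,
                         "auc_roc": roc, "auc_pr": pr, "status": status})
    return EvalReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# cross-model comparison

@dataclass
class FTestResult:
    statistic: float
    p_value: float
    df_between: int
    df_within: int
    description: str

    def to_dict(self) -> dict:
        return {
            "F": self.statistic, "p": self.p_value,
            "df_between": self.df_between, "df_within": self.df_within,
            "description": self.description,
        }


def anova_f(groups, description: str = "one-way ANOVA over detector fold scores") -> FTestResult:
    """One-way ANOVA across groups of fold-level AUC values.

    The fully degenerate case (zero between- and within-group variance) is
    defined as F = 0, p = 1 rather than NaN.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two values")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    flat = np.concatenate(groups)
    if np.allclose(flat, flat[0]):
        return FTestResult(0.0, 1.0, k - 1, n_total - k, description)
    stat, p = scipy.stats.f_oneway(*groups)
    return FTestResult(float(stat), float(p), k - 1, n_total - k, description)


def compare_detectors(report: EvalReport, category: str,
                      metric: str = "auc_roc") -> FTestResult:
    """F-test across all detectors' fold-level metric values in a category."""
    detectors = report.records["detector"].unique()
    groups = [report.fold_values(d, metric=metric, category=category) for d in detectors]
    return anova_f(
        groups,
        description=f"{metric} across detectors ({', '.join(detectors)}), category {category}",
    )
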