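"""Metrics, fold planning, normal-only CV protocol, and the cross-model F-test."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from sklearn.metrics import average_precision_score, roc_auc_score

from lbwdetect.detectors import ScorerSpec, adapt_external, unregister_adapter
from lbwdetect.evaluate import (
    anova_f,
    auc_pr,
    auc_roc,
    compare_detectors,
    cross_validate,
    make_folds,
)
from lbwdetect.preprocess import Preprocessor
from lbwdetect.synth import SyntheticConfig, generate_cohort


class TestMakeFolds:
    def test_positives_spread_evenly(self):
        labels = np.array([1] * 19 + [0] * 300)
        plan = make_folds(labels, repeats=2, folds=5, seed=0)
        for rep in range(2):
            counts = [
                labels[plan.assignment[rep] == f].sum() for f in range(5)
            ]
            assert sorted(counts) == [3, 4, 4, 4, 4]  # 19 = 3 + 4*4
            for f in range(5):
                fold_labels = labels[plan.assignment[rep] == f]
                assert 0 < fold_labels.sum() < len(fold_labels)

    def test_each_repeat_partitions_rows(self):
        labels = np.array([1] * 10 + [0] * 90)
        plan = make_folds(labels, repeats=2, folds=5, seed=3)
        for rep in range(2):
            assert np.all(np.isin(plan.assignment[rep], np.arange(5)))
            assert plan.assignment[rep].size == 100

    def test_too_few_positives_is_hard_error(self):
        labels = np.array([1] * 4 + [0] * 96)
        with pytest.raises(ValueError, match="elbw"):
            make_folds(labels, folds=5, category="elbw")

    def test_deterministic_under_seed(self):
        labels = np.array([1] * 8 + [0] * 92)
        a = make_folds(labels, seed=5).assignment
        b = make_folds(labels, seed=5).assignment
        assert np.array_equal(a, b)


class TestAucRoc:
    def test_perfect_separation(self):
        assert auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_hand_enumerated_pairs(self):
        # pairs (pos, neg): (.7,.3)+, (.7,.6)+, (.5,.3)+, (.5,.6)- -> 3/4
        assert auc_roc([0.7, 0.3, 0.6, 0.5], [1, 0, 0, 1]) == 0.75

    def test_tie_credit(self):
        assert auc_roc([0.5, 0.5], [1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc([0.1, 0.2], [1, 1])

    def test_antisymmetry_and_monotone_invariance(self, rng):
        for _ in range(20):
            n = rng.integers(10, 60)
            scores = rng.normal(size=n).round(1)  # rounded to force ties
            labels = (rng.random(n) < 0.3).astype(int)
            if labels.sum() in (0, n):
                continue
            a = auc_roc(scores, labels)
            assert auc_roc(-scores, labels) == pytest.approx(1 - a)
            assert auc_roc(np.exp(scores), labels) == pytest.approx(a)
            assert auc_roc(3 * scores + 7, labels) == pytest.approx(a)

    def test_matches_sklearn_on_tie_free_scores(self, rng):
        scores = rng.normal(size=200)
        labels = (rng.random(200) < 0.2).astype(int)
        assert auc_roc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))


class TestAucPr:
    def test_perfect_ranking(self):
        assert auc_pr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_hand_tabulated(self):
        # positives at ranks 1 and 3: (1/1 + 2/3) / 2
        assert auc_pr([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(5 / 6)

    def test_random_scores_baseline_is_prevalence(self):
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            labels = (rng.random(10000) < 0.1).astype(int)
            vals.append(auc_pr(rng.random(10000), labels))
        assert abs(np.mean(vals) - 0.1) < 0.01

    def test_matches_sklearn_on_tie_free_scores(self, rng):
        scores = rng.normal(size=300)
        labels = (rng.random(300) < 0.15).astype(int)
        assert auc_pr(scores, labels) == pytest.approx(
            average_precision_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_pr([0.1, 0.2], [0, 0])


def _oracle_auc_roc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def _oracle_auc_pr(scores, labels):
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    tp, precisions = 0, []
    for rank, i in enumerate(order, start=1):
        if labels[i] == 1:
            tp += 1
            precisions.append(tp / rank)
    return sum(precisions) / len(precisions)


def test_metrics_match_exhaustive_oracles(rng):
    for _ in range(50):
        n = int(rng.integers(4, 51))
        scores = rng.normal(size=n).round(1)
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.sum() in (0, n):
            continue
        assert auc_roc(scores, labels) == pytest.approx(
            _oracle_auc_roc(scores.tolist(), labels.tolist()))
        assert auc_pr(scores, labels) == pytest.approx(
            _oracle_auc_pr(scores.tolist(), labels.tolist()))


# ---------------------------------------------------------------------------
# cross-validation protocol

def _signal_cohort(seed=0, severity=2.0, n=400):
    cfg = SyntheticConfig(n_samples=n, prevalence=(0.15, 0.05, 0.02),
                          severity=severity, missing_rate=0.0, seed=seed)
    df, truth = generate_cohort(cfg)
    fm = Preprocessor(cfg.schema()).fit(df).transform(df)
    return cfg, df, fm, truth


class TestCrossValidate:
    def test_oracle_scorer_reaches_perfect_auc(self):
        # an adapter that scores by the very feature defining the labels
        rng = np.random.default_rng(0)
        X = rng.random((200, 3))
        labels = (X[:, 0] > 0.8).astype(int)
        spec = adapt_external("truth-col", lambda data: None,
                              lambda s, data: data[:, 0],
                              orientation="higher_is_anomalous")
        try:
            plan = make_folds(labels, repeats=2, folds=5, seed=1)
            report = cross_validate(X, labels, spec, plan, category="lbw")
            assert (report.records["status"] == "ok").all()
            assert report.summary()["auc_roc"].iloc[0] == pytest.approx(1.0)
        finally:
            unregister_adapter("truth-col")

    def test_no_signal_cohort_scores_at_chance(self):
        rocs, prs, prev = [], [], []
        for seed in range(5):
            cfg, df, fm, truth = _signal_cohort(seed=seed, severity=0.0)
            lab = truth.labels["lbw"]
            plan = make_folds(lab, repeats=2, folds=5, seed=seed)
            rep = cross_validate(fm, lab, ScorerSpec("hbos", seed=seed), plan)
            rocs.append(rep.summary()["auc_roc"].iloc[0])
            prs.append(rep.summary()["auc_pr"].iloc[0])
            prev.append(lab.mean())
        assert abs(np.mean(rocs) - 0.5) < 0.06
        assert abs(np.mean(prs) - np.mean(prev)) < 0.06

    def test_mean_equals_hand_average_of_folds(self):
        _, _, fm, truth = _signal_cohort(seed=3)
        lab = truth.labels["lbw"]
        plan = make_folds(lab, repeats=2, folds=5, seed=3)
        rep = cross_validate(fm, lab, ScorerSpec("ecod"), plan, category="lbw")
        assert len(rep.records) == 10
        assert rep.summary()["auc_roc"].iloc[0] == pytest.approx(
            rep.records["auc_roc"].mean())

    def test_failing_detector_recorded_not_raised(self):
        rng = np.random.default_rng(0)
        X = rng.random((100, 2))
        labels = np.array([1] * 10 + [0] * 90)

        def bad_fit(data):
            raise RuntimeError("boom")

        spec = adapt_external("always-fails", bad_fit, lambda s, d: np.zeros(len(d)),
                              orientation="higher_is_anomalous")
        try:
            plan = make_folds(labels, repeats=1, folds=5, seed=0)
            rep = cross_validate(X, labels, spec, plan)
            assert (rep.records["status"] != "ok").all()
            assert rep.records["auc_roc"].isna().all()
            assert rep.summary().empty
        finally:
            unregister_adapter("always-fails")

    def test_fold_safe_mode_runs_clean(self):
        cfg, df, fm, truth = _signal_cohort(seed=4)
        lab = truth.labels["lbw"]
        plan = make_folds(lab, repeats=1, folds=5, seed=4)
        rep = cross_validate(None, lab, ScorerSpec("hbos"), plan,
                             cohort=df, preprocessor=Preprocessor(cfg.schema()),
                             mode="fold-safe")
        assert (rep.records["status"] == "ok").all()
        assert rep.records["auc_roc"].between(0, 1).all()


# ---------------------------------------------------------------------------
# cross-model F-test

class TestAnovaF:
    def test_identical_groups_give_zero(self):
        res = anova_f([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # SSB = 13.5 (df 1), SSW = 4 (df 4) -> F = 13.5 / 1 = 13.5
        res = anova_f([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert res.statistic == pytest.approx(13.5)
        assert res.df_between == 1 and res.df_within == 4
        assert res.p_value == pytest.approx(
            scipy.stats.f.sf(13.5, 1, 4))

    def test_fully_degenerate_defined_as_zero(self):
        res = anova_f([[2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            anova_f([[1.0, 2.0]])
        with pytest.raises(ValueError):
            anova_f([[1.0], [2.0]])

    def test_compare_detectors_across_report(self):
        _, _, fm, truth = _signal_cohort(seed=6)
        lab = truth.labels["lbw"]
        plan = make_folds(lab, repeats=1, folds=5, seed=6)
        reps = [cross_validate(fm, lab, ScorerSpec(n, seed=6), plan, category="lbw")
                for n in ("hbos", "knn")]
        from lbwdetect.evaluate import EvalReport
        res = compare_detectors(EvalReport.concat(reps), "lbw")
        assert res.statistic >= 0.0 and 0.0 <= res.p_value <= 1.0
        assert res.df_between == 1 and res.df_within == 8
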