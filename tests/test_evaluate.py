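"""Evaluation protocol: splits, metrics, ROC, grid search, bootstrap, Wilcoxon."""

import json
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon
from sklearn.metrics import roc_auc_score

from tofoutlier.errors import ValidationError
from tofoutlier.evaluate import (
    ExperimentConfig,
    SplitSpec,
    bootstrap_ci,
    compare_models,
    f1_metric,
    grid_search_cv,
    learning_curves,
    metrics,
    rank_auc,
    roc_curve,
    run_experiment,
    stratified_split,
    trapezoid_auc,
)


def label_table(n_normal, n_outlier, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array(["normal"] * n_normal + ["outlier"] * n_outlier)
    rng.shuffle(labels)
    return pd.DataFrame(
        {
            "label": labels,
            "measurement_id": [f"M{i}" for i in range(n_normal + n_outlier)],
        }
    )


class TestStratifiedSplit:
    def test_cohort_sized_split_matches_published_partition(self):
        table = label_table(503, 30)
        train, test = stratified_split(table, SplitSpec(test_fraction=0.40, seed=3))
        assert len(test) == 214 and len(train) == 319
        assert (test.label == "outlier").sum() == 12
        assert (train.label == "outlier").sum() == 18

    def test_split_is_disjoint_and_exhaustive(self):
        table = label_table(90, 10)
        train, test = stratified_split(table, SplitSpec(test_fraction=0.3, seed=1))
        ids = set(train.measurement_id) | set(test.measurement_id)
        assert len(ids) == 100
        assert not (set(train.measurement_id) & set(test.measurement_id))

    @pytest.mark.parametrize("n0,n1,frac,seed", [(57, 9, 0.25, 0), (200, 13, 0.4, 5), (33, 7, 0.5, 9)])
    def test_per_class_counts_proportional_within_one(self, n0, n1, frac, seed):
        table = label_table(n0, n1, seed=seed)
        _, test = stratified_split(table, SplitSpec(test_fraction=frac, seed=seed))
        import math

        assert len(test) == math.ceil((n0 + n1) * frac)
        for cls, n_cls in (("normal", n0), ("outlier", n1)):
            got = (test.label == cls).sum()
            assert abs(got - n_cls * frac) <= 1

    def test_tiny_class_rejected(self):
        table = label_table(20, 1)
        with pytest.raises(ValidationError):
            stratified_split(table, SplitSpec(test_fraction=0.4))


class TestMetrics:
    def test_perfect_precision_partial_recall(self):
        # 9 of 12 outliers detected, no false alarms, on 214 measurements
        y_true = np.r_[np.ones(12), np.zeros(202)]
        y_pred = np.r_[np.ones(9), np.zeros(3), np.zeros(202)]
        m = metrics(y_true, y_pred)
        assert m["precision"] == pytest.approx(1.0)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(18 / 21)
        assert round(m["f1"], 2) == 0.86

    def test_low_precision_low_recall(self):
        # one third of 12 outliers flagged plus 12 false alarms
        y_true = np.r_[np.ones(12), np.zeros(202)]
        y_pred = np.r_[np.ones(4), np.zeros(8), np.ones(12), np.zeros(190)]
        m = metrics(y_true, y_pred)
        assert m["precision"] == pytest.approx(0.25)
        assert m["recall"] == pytest.approx(1 / 3)
        assert m["f1"] == pytest.approx(8 / 28)
        assert round(m["f1"], 2) == 0.29

    def test_degenerate_auc_values(self):
        y = np.array([0, 0, 1, 1])
        assert rank_auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
        assert rank_auc(y, np.array([0.5, 0.5, 0.5, 0.5])) == 0.5

    def test_no_positives_rejected(self):
        with pytest.raises(ValidationError):
            rank_auc(np.zeros(5), np.arange(5.0))

    def test_rank_auc_matches_sklearn(self, rng):
        y = (rng.random(200) < 0.1).astype(int)
        y[:3] = 1
        s = np.round(rng.random(200), 2)  # ties on purpose
        assert rank_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestRocCurve:
    def test_matches_exhaustive_threshold_enumeration(self):
        y = np.array([1, 0, 1, 1, 0])
        s = np.array([0.9, 0.8, 0.8, 0.4, 0.2])
        fpr, tpr, thr = roc_curve(y, s)
        # enumerate distinct thresholds by hand: predict 1 iff score >= t
        pts = {(0.0, 0.0)}
        for t in sorted(set(s), reverse=True):
            pred = (s >= t).astype(int)
            tp = ((pred == 1) & (y == 1)).sum()
            fp = ((pred == 1) & (y == 0)).sum()
            pts.add((fp / 2, tp / 3))
        assert set(zip(fpr, tpr)) == pts

    def test_endpoints_and_monotonicity(self, rng):
        y = (rng.random(50) < 0.3).astype(int)
        y[0] = 1
        y[1] = 0
        s = rng.random(50)
        fpr, tpr, _ = roc_curve(y, s)
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_trapezoid_area_equals_rank_auc(self, rng):
        y = (rng.random(120) < 0.2).astype(int)
        y[0] = 1
        y[1] = 0
        s = np.round(rng.random(120), 2)
        fpr, tpr, _ = roc_curve(y, s)
        assert trapezoid_auc(fpr, tpr) == pytest.approx(rank_auc(y, s), abs=1e-12)

    def test_score_reversal_flips_auc(self, rng):
        y = (rng.random(60) < 0.25).astype(int)
        y[0] = 1
        y[1] = 0
        s = rng.random(60)
        assert rank_auc(y, -s) == pytest.approx(1.0 - rank_auc(y, s), abs=1e-12)

    def test_perfect_scores_pass_through_corner(self):
        y = np.array([0, 1, 0, 1])
        fpr, tpr, _ = roc_curve(y, y.astype(float))
        assert any(f == 0.0 and t == 1.0 for f, t in zip(fpr, tpr))


class TestGridSearch:
    def test_single_config_grid_is_selected(self, default_features):
        train, _ = stratified_split(default_features, SplitSpec(seed=0))
        gs = grid_search_cv(
            train, ["deltaT4_T1", "ratioT1"], grid=[(1.0, 5.0)], k=5, seed=0
        )
        assert gs.best_config.l2_lambda == 1.0
        assert gs.best_config.class_weights == (1.0, 5.0)

    def test_stratified_folds_balance_18_outliers_over_5_folds(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.r_[np.ones(18), np.zeros(301)]
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        counts = sorted(int(y[va].sum()) for _, va in skf.split(y.reshape(-1, 1), y))
        assert counts == [3, 3, 4, 4, 4]

    def test_selected_config_not_strictly_dominated(self, default_features):
        train, _ = stratified_split(default_features, SplitSpec(seed=0))
        from tofoutlier.features import ENGINEERED_FEATURES

        gs = grid_search_cv(train, ENGINEERED_FEATURES, k=5, seed=0)
        sel = gs.grid.index(
            (gs.best_config.l2_lambda, gs.best_config.class_weights[1])
        )
        for g in range(len(gs.grid)):
            if g == sel:
                continue
            dominated = np.all(gs.fold_scores[g] >= gs.fold_scores[sel]) and np.any(
                gs.fold_scores[g] > gs.fold_scores[sel]
            )
            assert not dominated

    def test_too_few_outliers_for_folds_rejected(self):
        table = label_table(50, 3)
        table["x"] = np.random.default_rng(0).random(53)
        with pytest.raises(ValidationError):
            grid_search_cv(table, ["x"], k=5)


class TestBootstrap:
    def test_perfect_predictions_give_degenerate_interval(self):
        y = np.r_[np.ones(10), np.zeros(90)]
        lo, hi = bootstrap_ci(y, y.astype(float), f1_metric, reps=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_interval_brackets_point_estimate(self):
        y = np.r_[np.ones(12), np.zeros(100)]
        pred = y.copy()
        pred[:3] = 0  # three misses
        pred[20:22] = 1  # two false alarms
        point = f1_metric(y, pred)
        lo, hi = bootstrap_ci(y, pred, f1_metric, reps=1000, seed=1)
        assert lo <= point <= hi

    def test_tiny_sample_interval_lies_in_achievable_support(self):
        """n=4: endpoints must be attainable F1 values of some resample."""
        y = np.array([1, 1, 0, 0])
        pred = np.array([1.0, 0.0, 0.0, 1.0])
        support = set()
        for pos in product([0, 1], repeat=2):
            for neg in product([2, 3], repeat=2):
                idx = np.array(list(pos) + list(neg))
                support.add(round(f1_metric(y[idx], pred[idx]), 12))
        lo, hi = bootstrap_ci(y, pred, f1_metric, reps=500, seed=2)
        assert round(lo, 12) in support and round(hi, 12) in support

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_ci(np.array([1, 0]), np.array([1.0, 0.0]), f1_metric, reps=10)


def exhaustive_signed_rank_p(d):
    """Two-sided exact p by enumerating all sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([0, 1], repeat=len(d))
    ]
    sums = np.array(sums)
    p = 2 * min((sums >= w_obs).mean(), (sums <= w_obs).mean())
    return w_obs, min(1.0, p)


class TestWilcoxon:
    def test_identical_scores_give_p_one(self):
        w, p = compare_models([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert (w, p) == (0.0, 1.0)

    def test_six_concordant_pairs_exact_p(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b = [0.9, 1.8, 2.7, 3.6, 4.5, 5.4]
        w, p = compare_models(a, b)
        assert w == 21.0
        assert p == pytest.approx(2.0 / 64.0)

    @pytest.mark.parametrize("n,seed", [(5, 0), (8, 1), (10, 2), (12, 3)])
    def test_exact_p_matches_sign_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=n)
        while len(np.unique(np.abs(d))) < n:
            d = rng.normal(size=n)
        a = np.arange(n, dtype=float)
        b = a - d
        w, p = compare_models(a, b)
        w_ref, p_ref = exhaustive_signed_rank_p(d)
        assert w == pytest.approx(w_ref)
        assert p == pytest.approx(p_ref)

    def test_swapping_arguments_preserves_p(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(size=9)
        _, p1 = compare_models(a, b)
        _, p2 = compare_models(b, a)
        assert p1 == pytest.approx(p2)

    def test_large_sample_matches_scipy_normal_approximation(self, rng):
        a = rng.normal(size=40)
        b = a + rng.normal(0.3, 1.0, size=40)
        _, p = compare_models(a, b)
        ref = scipy_wilcoxon(
            a, b, zero_method="wilcox", correction=False, mode="approx"
        )
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestLearningCurves:
    def test_one_row_per_feasible_size(self, default_features):
        from tofoutlier.model import CSLRConfig

        train, _ = stratified_split(default_features, SplitSpec(seed=0))
        lc = learning_curves(
            train,
            ["deltaT4_T1", "ratioT1"],
            CSLRConfig(class_weights=(1.0, 5.0)),
            train_sizes=(0.5, 1.0),
            k=5,
            seed=0,
        )
        assert len(lc) == 2
        assert set(lc.columns) >= {"val_f1_mean", "train_f1_mean", "val_auc_mean"}

    def test_infeasible_sizes_are_skipped(self, default_features):
        from tofoutlier.model import CSLRConfig

        train, _ = stratified_split(default_features, SplitSpec(seed=0))
        lc = learning_curves(
            train,
            ["deltaT4_T1"],
            CSLRConfig(),
            train_sizes=(0.02, 1.0),
            k=5,
            seed=0,
        )
        assert len(lc) == 1


@pytest.fixture(scope="module")
def small_features(small_dataset):
    from tofoutlier.features import build_feature_table

    return build_feature_table(small_dataset)


class TestRunExperiment:


    def _config(self):
        return ExperimentConfig(
            split=SplitSpec(test_fraction=0.4, seed=0),
            grid=[(0.1, 1.0), (1.0, 5.0)],
            k=3,
            bootstrap_reps=200,
            learning_curve_sizes=(1.0,),
            wilcoxon_repeats=2,
            seed=11,
        )

    def test_report_structure_and_shared_split(self, small_features):
        report = run_experiment(small_features, self._config())
        assert set(report["models"]) == {"basic", "engineered"}
        assert report["split"]["n_train"] + report["split"]["n_test"] == len(
            small_features
        )
        for tag in ("basic", "engineered"):
            assert "ci_95" in report["models"][tag]["test"]
        assert "wilcoxon" in report

    def test_rerun_is_byte_identical(self, small_features):
        def serialized(rep):
            return json.dumps(
                {k: v for k, v in rep.items() if not k.startswith("_")},
                sort_keys=True,
                default=str,
            )

        r1 = run_experiment(small_features, self._config())
        r2 = run_experiment(small_features, self._config())
        assert serialized(r1) == serialized(r2)
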