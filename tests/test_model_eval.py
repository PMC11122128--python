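"""Cross-validated attentional-state classifier evaluation."""

import numpy as np
import pandas as pd
import pytest

from eyesvd.model_eval import (
    CVConfig,
    _fold_metrics,
    compare_datasets,
    evaluate,
    fit_predict,
    stratified_folds,
    undersample_training,
)

from conftest import make_separable_table

FAST_XGB = {"n_estimators": 60}


class TestStratifiedFolds:
    def test_fifty_ten_split_gives_ten_two_per_fold(self):
        labels = np.array([1] * 50 + [0] * 10)
        folds = stratified_folds(labels, 5, seed=0)
        for test_idx in folds:
            assert np.sum(labels[test_idx] == 1) == 10
            assert np.sum(labels[test_idx] == 0) == 2

    def test_partition_property_and_determinism(self):
        labels = np.array([1] * 30 + [0] * 15)
        a = stratified_folds(labels, 5, seed=3)
        b = stratified_folds(labels, 5, seed=3)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)
        allidx = np.concatenate(a)
        assert sorted(allidx) == list(range(45))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.array([1] * 20 + [0] * 3), 5)


class TestUndersampleTraining:
    def test_majority_subsampled_to_minority(self):
        rows = np.arange(48).reshape(48, 1).astype(float)
        labels = np.array([1] * 40 + [0] * 8)
        sub_rows, sub_labels = undersample_training(rows, labels, seed=0)
        assert np.sum(sub_labels == 1) == 8 and np.sum(sub_labels == 0) == 8

    def test_balanced_input_identity(self):
        rows = np.arange(20).reshape(10, 2).astype(float)
        labels = np.array([0, 1] * 5)
        sub_rows, sub_labels = undersample_training(rows, labels, seed=0)
        np.testing.assert_array_equal(sub_rows, rows)

    def test_seeded_determinism(self):
        rows = np.arange(30).reshape(30, 1).astype(float)
        labels = np.array([1] * 24 + [0] * 6)
        a = undersample_training(rows, labels, seed=7)[0]
        b = undersample_training(rows, labels, seed=7)[0]
        np.testing.assert_array_equal(a, b)


class TestFitPredict:
    @pytest.mark.parametrize("kind,params", [("xgboost", FAST_XGB), ("mlp", {})])
    def test_separable_limit_perfect_auroc(self, kind, params):
        """On linearly separable data, scores rank the classes perfectly
        (decision thresholds hug the training data, so the limit is checked
        on in-distribution rows)."""
        from sklearn.metrics import roc_auc_score

        train = make_separable_table(n=60, seed=0)
        test = train.copy(deep=True)
        scores = fit_predict(train, test, kind, seed=0, model_params=params)
        assert roc_auc_score(test["label"], scores) == 1.0

    def test_permuted_labels_give_chance_auroc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        aucs = []
        for rep in range(20):
            train = make_separable_table(n=60, seed=rep)
            train["label"] = rng.permutation(train["label"].to_numpy())
            test = make_separable_table(n=40, seed=100 + rep)
            test["label"] = rng.permutation(test["label"].to_numpy())
            scores = fit_predict(train, test, "xgboost", seed=rep, model_params=FAST_XGB)
            aucs.append(roc_auc_score(test["label"], scores))
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_feature_mismatch_rejected(self):
        train = make_separable_table()
        test = train.rename(columns={"f2": "other"})
        with pytest.raises(ValueError):
            fit_predict(train, test, "xgboost")


class TestMetrics:
    def test_hand_built_confusion(self):
        # TP=8, FN=2, FP=3, TN=7 at threshold 0.5
        y = np.array([1] * 10 + [0] * 10)
        scores = np.array([0.9] * 8 + [0.1] * 2 + [0.8] * 3 + [0.2] * 7)
        m = _fold_metrics(y, scores)
        assert m["f1_focus"] == pytest.approx(2 * 8 / (2 * 8 + 2 + 3))
        assert m["accuracy_focus"] == pytest.approx(0.8)
        assert m["accuracy_notfocus"] == pytest.approx(0.7)

    def test_all_positive_predictor_on_imbalanced_data(self):
        y = np.array([1] * 50 + [0] * 10)
        scores = np.full(60, 0.9)
        m = _fold_metrics(y, scores)
        assert m["accuracy_focus"] == 1.0
        assert m["accuracy_notfocus"] == 0.0
        assert m["auroc"] == pytest.approx(0.5)

    def test_perfect_scores(self):
        y = np.array([1, 1, 0, 0])
        m = _fold_metrics(y, np.array([0.9, 0.8, 0.2, 0.1]))
        assert m["auroc"] == 1.0 and m["f1_focus"] == 1.0 and m["f1_notfocus"] == 1.0


class TestEvaluate:
    def _table(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([1] * (5 * n // 6) + [0] * (n - 5 * n // 6))
        return pd.DataFrame(
            {
                "good": y * 2.0 + rng.normal(0, 0.4, n),
                "noise": rng.normal(size=n),
                "label": y,
            }
        )

    def test_report_reproducible_and_leak_free(self):
        table = self._table()
        cv = CVConfig(seed=1, model_kind="xgboost", model_params=FAST_XGB)
        before = table.copy()
        rep1 = evaluate(table, cv)
        rep2 = evaluate(table, cv)
        pd.testing.assert_frame_equal(table, before)  # input untouched
        assert rep1.metrics == rep2.metrics
        assert rep1["auroc"][0] >= 0.9
        assert len(rep1.confusions) == 5

    def test_mlp_reproducible(self):
        table = self._table(seed=3)
        cv = CVConfig(seed=2, model_kind="mlp", model_params={"max_iter": 50})
        assert evaluate(table, cv).metrics == evaluate(table, cv).metrics

    def test_auroc_invariant_under_monotone_score_transform(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 50)
        s = rng.random(50)
        assert roc_auc_score(y, s) == pytest.approx(
            roc_auc_score(y, np.exp(3 * s) + 1)
        )


class TestCompareDatasets:
    def test_duplicated_dataset_identical_rows(self):
        table = make_separable_table(n=40, seed=0)
        cv = CVConfig(seed=0, model_params=FAST_XGB)
        grid = compare_datasets({"a": table, "b": table.copy()}, cv,
                                model_kinds=("xgboost",))
        a = grid[grid.dataset == "a"].drop(columns="dataset").reset_index(drop=True)
        b = grid[grid.dataset == "b"].drop(columns="dataset").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_single_dataset_single_row(self):
        grid = compare_datasets(
            {"only": make_separable_table()}, CVConfig(model_params=FAST_XGB),
            model_kinds=("xgboost",),
        )
        assert len(grid) == 1
        assert grid.loc[0, "auroc_mean"] >= 0.9
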