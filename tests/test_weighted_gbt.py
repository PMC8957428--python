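import numpy as np
import pytest

from hrvcdet import FeatureTable, GBTModel, GBTParams, cross_validate, fit, predict, predict_proba

FAST = GBTParams(n_trees=30, max_depth=3, learning_rate=0.3)


def make_table(X, labels):
    X = np.asarray(X, dtype=float)
    return FeatureTable(
        subject_ids=tuple(f"s{i}" for i in range(X.shape[0])),
        class_labels=tuple(labels),
        X=X,
        feature_names=tuple(f"f{m}" for m in range(X.shape[1])),
    )


def separable_table(rng, n_per=100, n_features=2, gap=5.0, n_classes=2):
    X, labels = [], []
    for y in range(n_classes):
        X.append(rng.normal(gap * y, 1.0, size=(n_per, n_features)))
        labels += [f"c{y}"] * n_per
    return make_table(np.vstack(X), labels)


class TestFit:
    def test_uniform_weights_identical_to_unweighted(self):
        rng = np.random.default_rng(0)
        table = separable_table(rng, n_per=40, gap=1.0, n_classes=3)
        m_uni = fit(table, np.ones(2), FAST)
        m_none = fit(table, None, FAST)
        s1 = m_uni.raw_scores(table.X)
        s2 = m_none.raw_scores(table.X)
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_zero_weight_feature_never_split(self):
        rng = np.random.default_rng(1)
        table = separable_table(rng, n_per=50, n_features=2, gap=3.0)
        model = fit(table, np.array([1.0, 0.0]), FAST)
        assert 1 not in model.used_features()

    def test_separable_data_training_accuracy_100(self):
        rng = np.random.default_rng(2)
        table = separable_table(rng, n_per=100, gap=5.0)
        model = fit(table, None, GBTParams(n_trees=50, max_depth=3))
        preds = predict(model, table.X)
        assert np.mean(preds == np.asarray(table.class_labels, dtype=object)) == 1.0

    def test_weight_length_mismatch_raises(self):
        rng = np.random.default_rng(3)
        table = separable_table(rng, n_per=10)
        with pytest.raises(ValueError, match="length"):
            fit(table, np.ones(5), FAST)

    def test_single_class_training_raises(self):
        table = make_table(np.random.default_rng(4).normal(size=(10, 2)), ["a"] * 10)
        with pytest.raises(ValueError):
            fit(table, None, FAST)

    def test_monotone_damping_of_feature_usage(self):
        rng = np.random.default_rng(5)
        # both features mildly informative
        X = np.vstack([rng.normal(0, 1, size=(60, 2)), rng.normal(1.5, 1, size=(60, 2))])
        table = make_table(X, ["a"] * 60 + ["b"] * 60)

        def split_count(w0):
            model = fit(table, np.array([w0, 1.0]), FAST)
            count = 0
            for rt in model.trees:
                for tree in rt:
                    stack = [tree]
                    while stack:
                        node = stack.pop()
                        if not node.is_leaf:
                            if node.feature == 0:
                                count += 1
                            stack += [node.left, node.right]
            return count

        counts = [split_count(w) for w in [1.0, 0.5, 0.2, 0.05, 0.0]]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0

    def test_downweighting_informative_feature_hurts_accuracy(self):
        rng = np.random.default_rng(6)
        # feature 0 informative, feature 1 pure noise
        X = np.vstack(
            [
                np.column_stack([rng.normal(0, 1, 60), rng.normal(0, 1, 60)]),
                np.column_stack([rng.normal(4, 1, 60), rng.normal(0, 1, 60)]),
            ]
        )
        table = make_table(X, ["a"] * 60 + ["b"] * 60)
        labels = np.asarray(table.class_labels, dtype=object)
        acc_good = np.mean(predict(fit(table, np.array([1.0, 1e-12]), FAST), table.X) == labels)
        acc_bad = np.mean(predict(fit(table, np.array([1e-12, 1.0]), FAST), table.X) == labels)
        assert acc_bad < acc_good


class TestPredict:
    def test_zero_tree_model_uniform_on_balanced_data(self):
        rng = np.random.default_rng(7)
        table = separable_table(rng, n_per=20, n_classes=3)
        model = fit(table, None, GBTParams(n_trees=0))
        proba = predict_proba(model, table.X[:5])
        np.testing.assert_allclose(proba, 1.0 / 3.0, atol=1e-9)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(8)
        table = separable_table(rng, n_per=30, n_classes=3, gap=1.0)
        model = fit(table, None, FAST)
        proba = predict_proba(model, rng.normal(size=(200, 2)))
        assert np.all(proba >= 0)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_predict_is_argmax_of_proba(self):
        rng = np.random.default_rng(9)
        table = separable_table(rng, n_per=30, n_classes=3, gap=1.0)
        model = fit(table, None, FAST)
        rows = rng.normal(size=(1000, 2))
        proba = predict_proba(model, rows)
        preds = predict(model, rows)
        expected = np.asarray(model.classes, dtype=object)[np.argmax(proba, axis=1)]
        assert np.all(preds == expected)

    def test_row_width_mismatch_raises(self):
        rng = np.random.default_rng(10)
        model = fit(separable_table(rng, n_per=10), None, FAST)
        with pytest.raises(ValueError):
            predict_proba(model, np.zeros((3, 5)))


class TestSerialization:
    def test_json_round_trip_preserves_scores(self):
        rng = np.random.default_rng(11)
        table = separable_table(rng, n_per=25, n_classes=3, gap=2.0)
        model = fit(table, np.array([1.0, 0.7]), FAST)
        back = GBTModel.from_json(model.to_json())
        np.testing.assert_array_equal(back.raw_scores(table.X), model.raw_scores(table.X))
        assert back.classes == model.classes


class TestCrossValidate:
    def test_separable_data_mean_accuracy_one(self):
        rng = np.random.default_rng(12)
        table = separable_table(rng, n_per=40, gap=8.0, n_classes=3)
        res = cross_validate(table, FAST, k=4, seed=0)
        assert res.mean_accuracy == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(13)
        accs = []
        for seed in range(20):
            r = np.random.default_rng(900 + seed)
            X = r.normal(size=(45, 4))
            labels = ["a", "b", "c"] * 15
            table = make_table(X, labels)
            res = cross_validate(
                table, GBTParams(n_trees=15, max_depth=2, learning_rate=0.3), k=3, seed=seed
            )
            accs.append(res.mean_accuracy)
        assert 0.18 <= np.mean(accs) <= 0.48

    def test_same_seed_reproduces_folds_and_accuracies(self):
        rng = np.random.default_rng(14)
        table = separable_table(rng, n_per=20, n_classes=3, gap=1.0)
        a = cross_validate(table, FAST, k=4, seed=5)
        b = cross_validate(table, FAST, k=4, seed=5)
        assert a.fold_assignment == b.fold_assignment
        assert a.fold_accuracies == b.fold_accuracies

    def test_class_smaller_than_k_raises(self):
        rng = np.random.default_rng(15)
        table = separable_table(rng, n_per=3)
        with pytest.raises(ValueError):
            cross_validate(table, FAST, k=5, seed=0)


def test_reference_library_agrees_on_separable_task():
    """Sanity cross-check against an established boosting library."""
    xgb = pytest.importorskip("xgboost")
    rng = np.random.default_rng(16)
    table = separable_table(rng, n_per=60, gap=4.0)
    y = (np.asarray(table.class_labels, dtype=object) == "c1").astype(int)
    ours = fit(table, None, GBTParams(n_trees=30, max_depth=3))
    acc_ours = np.mean(predict(ours, table.X) == np.asarray(table.class_labels, dtype=object))
    clf = xgb.XGBClassifier(n_estimators=30, max_depth=3, verbosity=0)
    clf.fit(table.X, y)
    acc_ref = np.mean(clf.predict(table.X) == y)
    assert acc_ours == acc_ref == 1.0
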