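import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ehgpred.classify import (
    ClassifierConfig,
    StratificationError,
    confusion_metrics,
    cross_validate,
    roc_auc,
    stratified_folds,
    train_classifier,
)
from ehgpred.features import FeatureMatrix


def mann_whitney_auc(scores, labels):
    """Pairwise-concordance oracle: P(score_pos > score_neg), ties half."""
    pos = scores[labels]
    neg = scores[~labels]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def _tpehg_labels():
    return np.array(["term"] * 262 + ["preterm"] * 38)


def _matrix(X, labels):
    return FeatureMatrix(channel="CH1", record_ids=[f"r{i}" for i in range(len(labels))],
                         X=X, labels=labels)


def _blobs(n_term, n_preterm, separation, rng):
    """Two Gaussian clusters in 6-D; separation controls difficulty."""
    X = np.vstack([
        rng.standard_normal((n_term, 6)),
        rng.standard_normal((n_preterm, 6)) + separation,
    ])
    labels = np.array(["term"] * n_term + ["preterm"] * n_preterm)
    return _matrix(X, labels)


class TestStratifiedFolds:
    def test_tpehg_ratio(self):
        folds = stratified_folds(_tpehg_labels(), k=10, seed=0)
        labels = _tpehg_labels()
        for fold in folds:
            n_pre = np.sum(labels[fold] == "preterm")
            n_term = np.sum(labels[fold] == "term")
            assert n_pre in (3, 4)
            assert n_term in (26, 27)

    def test_exact_division(self):
        labels = np.array(["term"] * 10 + ["preterm"] * 10)
        for fold in stratified_folds(labels, k=10, seed=3):
            assert np.sum(labels[fold] == "preterm") == 1
            assert np.sum(labels[fold] == "term") == 1

    @given(n_a=st.integers(5, 40), n_b=st.integers(5, 40), seed=st.integers(0, 999))
    @settings(max_examples=50, deadline=None)
    def test_partition_property(self, n_a, n_b, seed):
        labels = np.array(["a"] * n_a + ["b"] * n_b)
        rng = np.random.default_rng(seed)
        labels = rng.permutation(labels)
        k = 5
        folds = stratified_folds(labels, k=k, seed=seed)
        joined = np.concatenate(folds)
        assert len(joined) == len(labels)
        assert len(np.unique(joined)) == len(labels)
        counts = [np.sum(labels[f] == "a") for f in folds]
        assert max(counts) - min(counts) <= 1

    def test_deterministic(self):
        a = stratified_folds(_tpehg_labels(), k=10, seed=7)
        b = stratified_folds(_tpehg_labels(), k=10, seed=7)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_minority_smaller_than_k_raises(self):
        labels = np.array(["term"] * 50 + ["preterm"] * 5)
        with pytest.raises(StratificationError):
            stratified_folds(labels, k=10, seed=0)


class TestTrainClassifier:
    @pytest.fixture
    def separable(self, rng):
        X = np.vstack([rng.standard_normal((20, 6)), rng.standard_normal((20, 6)) + 8.0])
        y = np.array([False] * 20 + [True] * 20)
        return X, y

    @pytest.mark.parametrize("config", [
        ClassifierConfig(kind="knn", knn_k=4),
        ClassifierConfig(kind="svm", svm_kernel="linear"),
        ClassifierConfig(kind="svm", svm_kernel="rbf"),
        ClassifierConfig(kind="svm", svm_kernel="poly"),
        ClassifierConfig(kind="dt"),
    ])
    def test_separable_training_accuracy(self, separable, config):
        X, y = separable
        model = train_classifier(config, X, y)
        assert np.array_equal(model.predict(X), y)

    def test_knn_k1_reproduces_training_labels(self, rng):
        X = rng.standard_normal((30, 6))
        y = rng.random(30) < 0.4
        y[:2] = [True, False]  # both classes present
        model = train_classifier(ClassifierConfig(kind="knn", knn_k=1), X, y)
        assert np.array_equal(model.predict(X), y)

    def test_dt_split_budget(self, rng):
        X = rng.standard_normal((200, 6))
        y = X[:, 0] + 0.3 * rng.standard_normal(200) > 0
        model = train_classifier(
            ClassifierConfig(kind="dt", dt_max_splits=6, dt_min_leaf_size=1), X, y)
        tree = model._est.tree_
        internal = np.sum(tree.children_left != -1)
        assert internal <= 6

    def test_single_class_raises(self, rng):
        X = rng.standard_normal((10, 6))
        with pytest.raises(ValueError):
            train_classifier(ClassifierConfig(kind="svm"), X, np.ones(10, dtype=bool))

    def test_knn_even_k_tie_broken_by_nearest(self):
        # 2 nearest neighbors disagree: the closer one must win
        X = np.array([[0.0], [1.0]])
        y = np.array([True, False])
        model = train_classifier(ClassifierConfig(kind="knn", knn_k=2), X, y)
        assert model.predict(np.array([[0.1]]))[0] == True  # noqa: E712
        assert model.predict(np.array([[0.9]]))[0] == False  # noqa: E712


class TestConfusionMetrics:
    def test_symmetric_example(self):
        assert confusion_metrics(9, 1, 90, 10) == pytest.approx((90.0, 90.0, 90.0))

    def test_perfect(self):
        assert confusion_metrics(5, 0, 7, 0) == (100.0, 100.0, 100.0)

    def test_hand_arithmetic(self):
        se, sp, acc = confusion_metrics(3, 1, 25, 1)
        assert se == pytest.approx(75.0)
        assert sp == pytest.approx(2500.0 / 26.0)
        assert acc == pytest.approx(2800.0 / 30.0)

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 10, 2)


class TestRocAuc:
    def test_perfect_ranking(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([True, True, False, False])
        _, auc = roc_auc(scores, labels)
        assert auc == 1.0

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(99)
        scores = rng.standard_normal(10000)
        labels = rng.random(10000) < 0.5
        _, auc = roc_auc(scores, labels)
        assert abs(auc - 0.5) < 0.02

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            # coarse scores force plenty of ties
            scores = np.round(rng.standard_normal(n), 1)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_roc_points_monotone(self, rng):
        scores = rng.standard_normal(100)
        labels = rng.random(100) < 0.3
        points, _ = roc_auc(scores, labels)
        xs = [p[0] for p in points]
        ys = [p[1] for p in points]
        assert xs == sorted(xs) and ys == sorted(ys)
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([True, True]))


class TestCrossValidate:
    def test_separable_is_perfect(self, rng):
        matrix = _blobs(40, 20, 10.0, rng)
        result = cross_validate(ClassifierConfig(kind="svm", svm_kernel="linear"),
                                matrix, k=5, repetitions=3, base_seed=0)
        assert result.se_mean == 100.0
        assert result.sp_mean == 100.0
        assert result.acc_mean == 100.0

    def test_determinism(self, rng):
        matrix = _blobs(30, 15, 2.0, rng)
        config = ClassifierConfig(kind="knn", knn_k=4)
        a = cross_validate(config, matrix, k=5, repetitions=3, base_seed=11)
        b = cross_validate(config, matrix, k=5, repetitions=3, base_seed=11)
        assert a.per_repetition == b.per_repetition
        assert a.auc == b.auc
        assert a.roc_points == b.roc_points

    def test_class_totals_conserved(self, rng):
        X = rng.standard_normal((300, 6))
        matrix = _matrix(X, _tpehg_labels())
        result = cross_validate(ClassifierConfig(kind="knn", knn_k=4), matrix,
                                k=10, repetitions=2, base_seed=0)
        for rep in result.per_repetition:
            assert rep["TP"] + rep["FN"] == 38
            assert rep["TN"] + rep["FP"] == 262

    def test_label_permutation_sanity(self, rng):
        # features carry no signal: accuracy ~ majority rate, AUC ~ 0.5
        X = rng.standard_normal((300, 6))
        matrix = _matrix(X, _tpehg_labels())
        result = cross_validate(ClassifierConfig(kind="knn", knn_k=8), matrix,
                                k=10, repetitions=3, base_seed=4)
        assert 75.0 <= result.acc_mean <= 95.0
        assert abs(result.auc - 0.5) < 0.2

    def test_difficulty_monotone(self, rng):
        config = ClassifierConfig(kind="svm", svm_kernel="linear")
        accs = []
        for separation in (0.5, 2.0, 6.0):
            matrix = _blobs(60, 20, separation, np.random.default_rng(0))
            res = cross_validate(config, matrix, k=5, repetitions=3, base_seed=2)
            accs.append((res.acc_mean, res.acc_sd))
        tolerance0 = max(accs[0][1], 1e-9)
        tolerance1 = max(accs[1][1], 1e-9)
        assert accs[1][0] >= accs[0][0] - tolerance0
        assert accs[2][0] >= accs[1][0] - tolerance1

    def test_train_only_normalization_runs(self, rng):
        matrix = _blobs(30, 15, 4.0, rng)
        result = cross_validate(ClassifierConfig(kind="svm", svm_kernel="linear"),
                                matrix, k=5, repetitions=2, base_seed=0,
                                normalization="train_only")
        assert result.normalization == "train_only"
        assert result.acc_mean > 90.0

    def test_inner_search_tuning_runs(self, rng):
        matrix = _blobs(40, 20, 3.0, rng)
        config = ClassifierConfig(kind="svm", svm_kernel="rbf", tuning="inner_search")
        result = cross_validate(config, matrix, k=5, repetitions=1, base_seed=0)
        assert result.acc_mean > 90.0

    def test_json_round_trippable(self, rng, tmp_path):
        import json
        matrix = _blobs(20, 10, 4.0, rng)
        result = cross_validate(ClassifierConfig(kind="dt"), matrix, k=5,
                                repetitions=2, base_seed=0)
        path = tmp_path / "result.json"
        result.write_json(path)
        payload = json.loads(path.read_text())
        assert payload["config"]["kind"] == "dt"
        assert len(payload["per_repetition"]) == 2
        assert 0.0 <= payload["auc"] <= 1.0
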