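"""SVM classifier: kernel, splits, training, evaluation, CV, Pearson."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from viscoclass.classify import (
    ClassifierError,
    cross_validate,
    evaluate,
    gaussian_kernel,
    pearson_matrix,
    split_train_test,
    train_classifier,
)


def _blob_table(rng, centers, n, features=("x", "y"), spread=1.0):
    frames = []
    for status, center in centers.items():
        data = rng.normal(center, spread, size=(n, len(features)))
        df = pd.DataFrame(data, columns=list(features))
        df["status"] = status
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestGaussianKernel:
    def test_identical_points(self):
        assert gaussian_kernel(np.ones(5), np.ones(5), 2.0) == 1.0

    def test_closed_form_at_2sigma2(self):
        xi = np.zeros(2)
        xj = np.array([np.sqrt(2.0), 0.0])  # ||xi - xj||^2 = 2 = 2 sigma^2
        assert gaussian_kernel(xi, xj, 1.0) == pytest.approx(np.exp(-1.0))

    def test_dimension_mismatch(self):
        with pytest.raises(ClassifierError):
            gaussian_kernel(np.zeros(3), np.zeros(4), 1.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=9), rng.normal(size=9)
        assert gaussian_kernel(a, b, 1.7) == pytest.approx(gaussian_kernel(b, a, 1.7))

    def test_kernel_matrix_positive_semidefinite(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 6))
        k = np.array([[gaussian_kernel(a, b, 1.3) for b in x] for a in x])
        assert np.linalg.eigvalsh(k).min() > -1e-8


class TestSplit:
    def test_70_30_stratified_counts(self):
        rng = np.random.default_rng(0)
        table = _blob_table(rng, {0: 0.0, 2: 5.0}, 800)
        train, test = split_train_test(table, seed=1)
        assert train["status"].value_counts().to_dict() == {0: 560, 2: 560}
        assert test["status"].value_counts().to_dict() == {0: 240, 2: 240}

    def test_same_seed_same_partition(self):
        rng = np.random.default_rng(0)
        table = _blob_table(rng, {0: 0.0, 2: 5.0}, 50)
        a1, b1 = split_train_test(table, seed=3)
        a2, b2 = split_train_test(table, seed=3)
        assert list(a1.index) == list(a2.index)
        assert list(b1.index) == list(b2.index)

    def test_partition_is_exact(self):
        rng = np.random.default_rng(0)
        table = _blob_table(rng, {0: 0.0, 2: 5.0}, 40)
        train, test = split_train_test(table, seed=3)
        assert len(train) + len(test) == len(table)
        assert set(train.index).isdisjoint(test.index)


class TestTrainEvaluate:
    def test_separable_clouds_perfect_training(self):
        rng = np.random.default_rng(1)
        table = _blob_table(rng, {0: 0.0, 2: 50.0}, 100)
        clf = train_classifier(table, ["x", "y"], C=10, sigma=2)
        assert np.mean(clf.predict(table) == table["status"]) == 1.0

    def test_xor_pattern_solved_by_rbf(self):
        rng = np.random.default_rng(2)
        quads = [((0, 0), 0), ((4, 4), 0), ((0, 4), 2), ((4, 0), 2)]
        frames = []
        for (cx, cy), status in quads:
            df = pd.DataFrame(rng.normal((cx, cy), 0.5, size=(150, 2)), columns=["x", "y"])
            df["status"] = status
            frames.append(df)
        table = pd.concat(frames, ignore_index=True)
        train, test = split_train_test(table, seed=0)
        best = 0.0
        for C in (1.0, 10.0, 100.0):
            for sigma in (0.5, 1.0, 2.0):
                clf = train_classifier(train, ["x", "y"], C=C, sigma=sigma)
                best = max(best, evaluate(clf, test).accuracy)
        assert best >= 0.95

    def test_pure_noise_features_give_chance(self):
        accs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            table = _blob_table(rng, {0: 0.0, 2: 0.0}, 200)
            train, test = split_train_test(table, seed=seed)
            clf = train_classifier(train, ["x", "y"], C=1, sigma=1)
            accs.append(evaluate(clf, test).accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.08)

    def test_label_permutation_null(self):
        # informative features but shuffled labels: accuracy collapses to chance
        accs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            table = _blob_table(rng, {0: 0.0, 2: 5.0}, 300)
            table["status"] = rng.permutation(table["status"].to_numpy())
            train, test = split_train_test(table, seed=seed)
            clf = train_classifier(train, ["x", "y"], C=10, sigma=1)
            accs.append(evaluate(clf, test).accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.08)

    def test_perfect_and_inverted_scores(self):
        rng = np.random.default_rng(5)
        table = _blob_table(rng, {0: 0.0, 2: 50.0}, 100)
        train, test = split_train_test(table, seed=0)
        clf = train_classifier(train, ["x", "y"], C=10, sigma=2)
        metrics = evaluate(clf, test)
        assert metrics.accuracy == 1.0
        assert metrics.auc == pytest.approx(1.0)
        # invert scores by hand: AUC flips to 1 - AUC
        from sklearn.metrics import auc as sk_auc, roc_curve

        scores = -clf.decision_scores(test)
        fpr, tpr, _ = roc_curve(test["status"], scores, pos_label=2)
        assert sk_auc(fpr, tpr) == pytest.approx(1.0 - metrics.auc)

    def test_confusion_matrix_rows_sum_to_class_counts(self):
        rng = np.random.default_rng(6)
        table = _blob_table(rng, {0: 0.0, 1: 1.0, 2: 2.5}, 60)
        train, test = split_train_test(table, seed=0)
        clf = train_classifier(train, ["x", "y"], C=1, sigma=1)
        metrics = evaluate(clf, test)
        counts = test["status"].value_counts().sort_index().to_numpy()
        assert (metrics.confusion.sum(axis=1) == counts).all()

    def test_degenerate_feature_warns_not_fails(self):
        rng = np.random.default_rng(7)
        table = _blob_table(rng, {0: 0.0, 2: 5.0}, 30)
        table["const"] = 1.0
        with pytest.warns(UserWarning):
            clf = train_classifier(table, ["x", "const"], C=1, sigma=1)
        assert clf.scaler_sd[1] == 1.0

    def test_unseen_class_rejected(self):
        rng = np.random.default_rng(8)
        table = _blob_table(rng, {0: 0.0, 2: 5.0}, 30)
        clf = train_classifier(table, ["x", "y"], C=1, sigma=1)
        alien = _blob_table(rng, {1: 2.0}, 10)
        with pytest.raises(ClassifierError):
            evaluate(clf, alien)


class TestCrossValidate:
    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(9)
        table = _blob_table(rng, {0: 0.0, 2: 5.0}, 50)
        C, sigma, acc, results = cross_validate(
            table, ["x", "y"], k=5, c_grid=(3.0,), sigma_grid=(1.5,), seed=0
        )
        assert (C, sigma) == (3.0, 1.5)
        assert len(results) == 1
        assert 0.0 <= acc <= 1.0

    def test_fold_sizes(self):
        rng = np.random.default_rng(10)
        table = _blob_table(rng, {0: 0.0, 2: 5.0}, 800)
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        sizes = [len(val) for _, val in skf.split(np.zeros(len(table)), table["status"])]
        assert all(abs(s - 160) <= 1 for s in sizes)

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(11)
        table = _blob_table(rng, {0: 0.0, 2: 1.5}, 60)
        r1 = cross_validate(table, ["x", "y"], k=4, c_grid=(1.0, 10.0),
                            sigma_grid=(1.0,), seed=5)
        r2 = cross_validate(table, ["x", "y"], k=4, c_grid=(1.0, 10.0),
                            sigma_grid=(1.0,), seed=5)
        assert r1[:3] == r2[:3]

    def test_empty_grid_rejected(self):
        rng = np.random.default_rng(12)
        table = _blob_table(rng, {0: 0.0, 2: 5.0}, 40)
        with pytest.raises(ClassifierError):
            cross_validate(table, ["x", "y"], k=3, c_grid=(), sigma_grid=(1.0,))


class TestPearson:
    def test_self_correlation_and_affine_invariance(self):
        x = np.arange(30, dtype=float)
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"x": x, "ax": 2 * x + 3, "nx": -x, "z": rng.normal(size=30)})
        m = pearson_matrix(table, include_status=False)
        assert m.loc["x", "x"] == pytest.approx(1.0)
        assert m.loc["x", "ax"] == pytest.approx(1.0)
        assert m.loc["x", "nx"] == pytest.approx(-1.0)
        assert np.allclose(m.values, m.values.T)
        assert (m.abs().values <= 1.0 + 1e-12).all()

    def test_hand_evaluated_coefficient(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 5.0]})
        m = pearson_matrix(table, include_status=False)
        assert m.loc["x", "y"] == pytest.approx(3.0 / np.sqrt(2.0 * 14.0 / 3.0), rel=1e-4)
        assert m.loc["x", "y"] == pytest.approx(0.9820, abs=1e-4)

    def test_constant_column_reported_missing(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "c": [5.0] * 4})
        m = pearson_matrix(table, include_status=False)
        assert np.isnan(m.loc["x", "c"])
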