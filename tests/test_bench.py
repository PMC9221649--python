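"""Benchmarking protocol: winsorization, metrics, PCA, CV, grid search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from modelrank.bench import (ConfusionMatrix, ModelSpec, Winsorizer,
                             default_model_specs, evaluate_cv, grid_search,
                             make_pipeline, metrics_from_confusion,
                             pca_reduce, winsorize_outliers)
from modelrank.synthetic import SyntheticConfig, generate


class TestWinsorize:
    def test_no_outliers_pass_through(self):
        np.testing.assert_array_equal(
            winsorize_outliers([1, 2, 3, 4, 5]), [1, 2, 3, 4, 5])

    def test_upper_outlier_replaced_by_q3(self):
        # Q1=2, Q3=4, IQR=2 -> upper fence 7, so 100 becomes 4
        np.testing.assert_array_equal(
            winsorize_outliers([1, 2, 3, 4, 100]), [1, 2, 3, 4, 4])

    def test_lower_outlier_replaced_by_q1(self):
        out = winsorize_outliers([-100, 2, 3, 4, 5])
        assert out[0] == np.percentile([-100, 2, 3, 4, 5], 25)

    def test_constant_column_unchanged(self):
        np.testing.assert_array_equal(
            winsorize_outliers([5, 5, 5, 5]), [5, 5, 5, 5])

    def test_brute_force_fence_oracle(self):
        rng = np.random.default_rng(8)
        col = rng.normal(size=200)
        col[rng.integers(0, 200, 10)] *= 30
        q1, q3 = np.percentile(col, [25, 75])
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        expected = np.array([q1 if v < lo else q3 if v > hi else v
                             for v in col])
        np.testing.assert_allclose(winsorize_outliers(col), expected)

    def test_non_numeric_rejected_with_name(self):
        with pytest.raises(ValueError, match="'radius'"):
            winsorize_outliers(np.array(["a", "b", "c", "d"], dtype=object),
                               name="radius")

    def test_transformer_applies_training_fences_to_new_data(self):
        w = Winsorizer().fit(np.array([[1.0], [2.0], [3.0], [4.0]]))
        out = w.transform(np.array([[100.0], [2.5]]))
        assert out[0, 0] == pytest.approx(np.percentile([1, 2, 3, 4], 75))
        assert out[1, 0] == 2.5


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=50, tn=40, fp=0, fn=0))
        assert all(m[k] == 1.0 for k in m)

    def test_hand_computed_example(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=40, tn=30, fp=20, fn=10))
        assert m["accuracy"] == pytest.approx(0.70)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(0.80)
        assert m["specificity"] == pytest.approx(0.60)
        assert m["f1"] == pytest.approx(8 / 11)  # 0.7273

    def test_undefined_metric_is_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="precision"):
            m = metrics_from_confusion(ConfusionMatrix(tp=0, tn=5, fp=0, fn=3))
        assert np.isnan(m["precision"])
        assert m["specificity"] == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ConfusionMatrix(tp=-1, tn=1, fp=0, fn=0)

    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_metric_identities(self, counts):
        cm = ConfusionMatrix(*counts)
        m = metrics_from_confusion(cm)
        assert m["accuracy"] * cm.total == pytest.approx(cm.tp + cm.tn)
        fpr = cm.fp / (cm.fp + cm.tn)
        assert m["specificity"] + fpr == pytest.approx(1.0)
        harmonic = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
        assert m["f1"] == pytest.approx(harmonic, abs=1e-9)


class TestPCA:
    def test_full_variance_keeps_full_rank(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 6))
        reduced, pca = pca_reduce(X, 1.0)
        assert reduced.shape[1] == 6
        recon = pca.inverse_transform(reduced)
        np.testing.assert_allclose(recon, X, atol=1e-10)

    def test_planar_data_needs_two_components(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(2, 5))
        X = rng.normal(size=(100, 2)) @ basis
        reduced, _ = pca_reduce(X, 0.99)
        assert reduced.shape[1] == 2

    def test_isotropic_gaussian_component_count_matches_spectrum(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(1000, 30))  # large n keeps the spectrum near-flat
        reduced, pca = pca_reduce(X, 0.5)
        # independent eigendecomposition oracle on the centered covariance
        cov = np.cov(X - X.mean(0), rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = int(np.searchsorted(
            np.cumsum(eigvals) / eigvals.sum(), 0.5) + 1)
        assert reduced.shape[1] == expected
        assert 10 <= reduced.shape[1] <= 20  # ~15 for isotropic noise

    def test_invalid_variance_fraction(self):
        with pytest.raises(ValueError, match="variance_retained"):
            pca_reduce(np.eye(4), 0.0)


class TestEvaluateCV:
    def test_separable_classes_score_high(self, small_dataset):
        for family in ("svm", "logistic_regression", "naive_bayes"):
            report = evaluate_cv(small_dataset, family, folds=5, seed=0)
            assert report.accuracy >= 0.95
            assert report.neg_log_loss <= 0
            assert report.support == {0: 150, 1: 90}

    def test_f1_is_harmonic_mean_of_reported_precision_recall(self, small_dataset):
        r = evaluate_cv(small_dataset, "knn", {"n_neighbors": 5}, folds=5, seed=0)
        harmonic = 2 * r.precision * r.recall / (r.precision + r.recall)
        assert r.f1 == pytest.approx(harmonic, abs=1e-9)

    def test_determinism(self, small_dataset):
        a = evaluate_cv(small_dataset, "random_forest", {"n_estimators": 20},
                        folds=5, seed=3)
        b = evaluate_cv(small_dataset, "random_forest", {"n_estimators": 20},
                        folds=5, seed=3)
        assert a == b

    def test_permuted_labels_score_at_chance(self):
        data = generate(SyntheticConfig(n_class0=120, n_class1=80,
                                        n_features=8, n_informative=4,
                                        class_separation=5.0, seed=21))
        rng = np.random.default_rng(5)
        majority = 120 / 200
        accs, aucs = [], []
        for _ in range(5):
            shuffled = data.copy()
            shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
            r = evaluate_cv(shuffled, "logistic_regression", folds=5, seed=0)
            accs.append(r.accuracy)
            aucs.append(r.roc_auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)
        assert np.mean(accs) == pytest.approx(majority, abs=0.1)

    def test_single_class_rejected(self):
        data = pd.DataFrame({"x": np.arange(10.0), "label": np.zeros(10, int)})
        with pytest.raises(ValueError, match="both classes"):
            evaluate_cv(data, "svm")

    def test_too_many_folds_suggests_fewer(self):
        data = pd.DataFrame({"x": np.arange(12.0),
                             "label": [0] * 9 + [1] * 3})
        with pytest.raises(ValueError, match="fewer folds"):
            evaluate_cv(data, "svm", folds=5)

    def test_pooled_aggregate_available(self, small_dataset):
        r = evaluate_cv(small_dataset, "naive_bayes", folds=5, seed=0,
                        aggregate="pooled")
        assert 0.9 <= r.accuracy <= 1.0

    def test_leakage_free_differs_from_leaky_preprocessing(self):
        # fitting winsorizer/scaler/PCA on all data before CV leaks fold
        # statistics; the fold-wise pipeline must not reproduce that result
        from sklearn.model_selection import StratifiedKFold
        from sklearn.neighbors import KNeighborsClassifier

        data = generate(SyntheticConfig(n_class0=60, n_class1=40,
                                        n_features=10, n_informative=3,
                                        class_separation=1.5,
                                        outlier_fraction=0.05,
                                        outlier_scale=20.0, seed=13))
        X = data.drop(columns="label").to_numpy()
        y = data["label"].to_numpy()
        pipe = make_pipeline("knn", {"n_neighbors": 7}, seed=0)
        leaky_prep = pipe[:-1].fit(X)  # fit preprocessing on all rows
        Xt = leaky_prep.transform(X)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        leaky_acc = []
        for tr, te in skf.split(Xt, y):
            clf = KNeighborsClassifier(n_neighbors=7).fit(Xt[tr], y[tr])
            leaky_acc.append((clf.predict(Xt[te]) == y[te]).mean())
        clean = evaluate_cv(data, "knn", {"n_neighbors": 7}, folds=5, seed=0)
        assert clean.accuracy != pytest.approx(np.mean(leaky_acc), abs=1e-12)


class TestGridSearch:
    def test_grid_of_size_one(self, small_dataset):
        spec = ModelSpec("knn", {"n_neighbors": [3]})
        params, report = grid_search(small_dataset, spec, folds=5, seed=0)
        assert params == {"n_neighbors": 3}
        assert report == evaluate_cv(small_dataset, "knn", params, folds=5,
                                     seed=0)

    def test_duplicate_entries_equal_deduplicated(self, small_dataset):
        dup = ModelSpec("random_forest", {"n_estimators": [10, 10, 25]})
        dedup = ModelSpec("random_forest", {"n_estimators": [10, 25]})
        assert grid_search(small_dataset, dup, folds=5, seed=0) == \
            grid_search(small_dataset, dedup, folds=5, seed=0)

    def test_rbf_svm_beats_linear_logistic_on_spherical_boundary(self):
        # class = inside/outside a sphere: rotationally symmetric, so a
        # linear separator carries no signal while the RBF kernel does
        rng = np.random.default_rng(42)
        X = rng.normal(size=(300, 4))
        radius = np.linalg.norm(X, axis=1)
        y = (radius > np.median(radius)).astype(int)
        data = pd.DataFrame(X, columns=[f"f{i}" for i in range(4)])
        data["label"] = y
        _, svm_report = grid_search(
            data, ModelSpec("svm", {"C": [1, 10], "kernel": ["rbf"]}),
            folds=5, seed=0)
        logit = evaluate_cv(data, "logistic_regression", folds=5, seed=0)
        assert svm_report.accuracy > logit.accuracy + 0.1

    def test_default_specs_cover_all_families(self):
        specs = default_model_specs()
        assert set(specs) == {"svm", "random_forest", "logistic_regression",
                              "knn", "naive_bayes"}
        assert specs["knn"].grid["n_neighbors"] == list(range(1, 42))
        with pytest.raises(ValueError, match="unknown model family"):
            ModelSpec("perceptron")
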