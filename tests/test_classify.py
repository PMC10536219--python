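"""Classifier training contracts and confusion-matrix metrics."""

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import f1_score as sk_f1
from sklearn.svm import LinearSVC

from croplab.classify import (
    ClassifyError,
    ConfusionMatrix,
    LabeledDataset,
    confusion,
    evaluate,
    f1_per_class,
    grid_search,
    overall_accuracy,
    train_qda,
    train_rf,
    train_svm_linear,
)


def two_blob_dataset(rng, n=100, sep=6.0, dim=4):
    X = np.vstack([
        rng.normal(0.0, 1.0, size=(n, dim)),
        rng.normal(sep, 1.0, size=(n, dim)),
    ])
    y = np.array(["fallow"] * n + ["soybean"] * n)
    return LabeledDataset(X, y)


class TestTrainers:
    def test_rf_separable_and_deterministic(self, rng):
        ds = two_blob_dataset(rng)
        m1 = train_rf(ds, seed=0)
        m2 = train_rf(ds, seed=0)
        assert (m1.predict(ds.X) == ds.y).all()
        probe = rng.normal(3.0, 2.0, size=(50, 4))
        assert (m1.predict(probe) == m2.predict(probe)).all()

    def test_svm_separable(self, rng):
        ds = two_blob_dataset(rng)
        model = train_svm_linear(ds)
        assert (model.predict(ds.X) == ds.y).all()

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        with pytest.raises(ClassifyError):
            train_rf(LabeledDataset(X, np.array(["oat"] * 20)))

    def test_balanced_weights_lift_minority_recall(self, rng):
        """With 90/10 imbalance, balanced class weights raise minority recall."""
        n_maj, n_min = 450, 50
        X = np.vstack([
            rng.normal(0.0, 2.0, size=(n_maj, 2)),
            rng.normal(2.5, 2.0, size=(n_min, 2)),
        ])
        y = np.array(["fallow"] * n_maj + ["soybean"] * n_min)
        ds = LabeledDataset(X, y)
        balanced = train_svm_linear(ds)
        uniform = LinearSVC(C=1.0, max_iter=10000).fit(X, y)
        minority = y == "soybean"
        rec_bal = np.mean(balanced.predict(X[minority]) == "soybean")
        rec_uni = np.mean(uniform.predict(X[minority]) == "soybean")
        assert rec_bal > rec_uni

    def test_qda_two_spherical_gaussians(self, rng):
        ds = two_blob_dataset(rng, sep=8.0)
        model = train_qda(ds)
        held = two_blob_dataset(np.random.default_rng(99), sep=8.0)
        assert np.mean(model.predict(held.X) == held.y) > 0.999

    def test_qda_error_rate_near_bayes(self):
        """Equal spherical covariances: error within 2 points of the closed form."""
        rng = np.random.default_rng(11)
        delta, sigma, dim = 2.0, 1.0, 2
        # Bayes error for two equal-prior spherical Gaussians separated by
        # ||mu1 - mu2|| = delta*sqrt(dim): Phi(-d_Mahalanobis / 2)
        d_mah = delta * np.sqrt(dim) / sigma
        bayes = norm.cdf(-d_mah / 2)
        X = np.vstack([
            rng.normal(0.0, sigma, size=(4000, dim)),
            rng.normal(delta, sigma, size=(4000, dim)),
        ])
        y = np.array(["fallow"] * 4000 + ["soybean"] * 4000)
        model = train_qda(LabeledDataset(X, y))
        Xt = np.vstack([
            rng.normal(0.0, sigma, size=(4000, dim)),
            rng.normal(delta, sigma, size=(4000, dim)),
        ])
        err = np.mean(model.predict(Xt) != y)
        assert abs(err - bayes) < 0.02

    def test_qda_single_sample_class_rejected(self, rng):
        X = np.vstack([rng.normal(size=(10, 3)), rng.normal(5, 1, size=(1, 3))])
        y = np.array(["oat"] * 10 + ["soybean"])
        with pytest.raises(ClassifyError, match="fewer than"):
            train_qda(LabeledDataset(X, y))


class TestGridSearch:
    def test_single_point_grid(self, rng):
        ds = two_blob_dataset(rng, n=30)
        best, curve = grid_search(ds, "rf", [{"n_trees": 10}], k_folds=3)
        assert best == {"n_trees": 10}
        assert len(curve) == 1

    def test_tree_count_curve_plateaus(self, rng):
        X = np.vstack([
            rng.normal(0.0, 1.5, size=(60, 4)),
            rng.normal(1.5, 1.5, size=(60, 4)),
        ])
        y = np.array(["fallow"] * 60 + ["oat"] * 60)
        grid = [{"n_trees": k} for k in (1, 5, 20, 60, 120)]
        best, curve = grid_search(LabeledDataset(X, y), "rf", grid, k_folds=3, seed=0)
        accs = curve["cv_accuracy"].to_numpy()
        # small forests underperform; the curve levels off within noise
        assert accs[0] <= accs[2:].max()
        assert accs[2:].max() - accs[2:].min() < 0.1

    def test_degenerate_features_tie_to_first(self, rng):
        X = np.ones((40, 4))
        y = np.array(["fallow", "oat"] * 20)
        grid = [{"C": c} for c in (0.1, 1.0, 10.0)]
        best, curve = grid_search(LabeledDataset(X, y), "svm", grid, k_folds=2)
        assert best == {"C": 0.1}
        assert curve["cv_accuracy"].nunique() == 1

    def test_excessive_folds_rejected(self, rng):
        ds = two_blob_dataset(rng, n=3)
        with pytest.raises(ClassifyError):
            grid_search(ds, "rf", [{"n_trees": 5}], k_folds=10)

    def test_same_seed_identical(self, rng):
        ds = two_blob_dataset(rng, n=40, sep=1.0)
        grid = [{"n_trees": k} for k in (5, 15)]
        _, c1 = grid_search(ds, "rf", grid, k_folds=3, seed=7)
        _, c2 = grid_search(ds, "rf", grid, k_folds=3, seed=7)
        assert (c1["cv_accuracy"] == c2["cv_accuracy"]).all()


class TestMetrics:
    def test_perfect_prediction_is_diagonal(self):
        y = np.array(["fallow", "soybean", "oat", "oat"])
        cm = confusion(y, y)
        assert np.trace(cm.counts) == 4
        assert overall_accuracy(cm) == 100.0
        assert all(v == 1.0 for v in f1_per_class(cm).values())

    def test_hand_counted_three_class_example(self):
        y_true = ["fallow"] * 4 + ["soybean"] * 4 + ["oat"] * 4
        y_pred = ["fallow", "fallow", "soybean", "oat",
                  "soybean", "soybean", "soybean", "fallow",
                  "oat", "oat", "fallow", "fallow"]
        cm = confusion(y_true, y_pred)
        expected = np.array([[2, 1, 1], [1, 3, 0], [2, 0, 2]])
        assert (cm.counts == expected).all()
        assert overall_accuracy(cm) == pytest.approx(100 * 7 / 12)

    def test_field_level_arithmetic(self):
        cm = ConfusionMatrix(np.array([[9, 0, 0], [0, 4, 6], [0, 0, 10]]),
                             ("soybean", "oat", "fallow"))
        assert overall_accuracy(cm) == pytest.approx(100 * 23 / 29)
        assert round(overall_accuracy(cm)) == 79

    def test_f1_direct_formula(self):
        # TP=8, FP=2, FN=2 -> P = R = 0.8 -> F1 = 0.8
        cm = ConfusionMatrix(np.array([[8, 2, 0], [2, 8, 0], [0, 0, 1]]))
        assert f1_per_class(cm)[cm.classes[0]] == pytest.approx(0.8)

    def test_absent_class_f1_zero_with_warning(self):
        cm = ConfusionMatrix(np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]]))
        with pytest.warns(UserWarning, match="oat"):
            assert f1_per_class(cm)["oat"] == 0.0

    def test_empty_and_unknown_labels_rejected(self):
        with pytest.raises(ClassifyError):
            confusion([], [])
        with pytest.raises(ClassifyError):
            confusion(["wheat"], ["fallow"])

    def test_metrics_match_brute_force_and_sklearn(self, rng):
        """OA and F1 agree with independent recomputation on random matrices."""
        for _ in range(1000):
            n_cls = rng.integers(2, 6)
            classes = tuple(f"c{k}" for k in range(n_cls))
            counts = rng.integers(0, 100, size=(n_cls, n_cls))
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = ConfusionMatrix(counts, classes)
            # brute force: expand the matrix back to label pairs
            oa_bf = 100.0 * sum(counts[i, i] for i in range(n_cls)) / counts.sum()
            assert overall_accuracy(cm) == pytest.approx(oa_bf)
            f1 = f1_per_class(cm)
            for i, c in enumerate(classes):
                tp, fn, fp = counts[i, i], counts[i].sum() - counts[i, i], counts[:, i].sum() - counts[i, i]
                f1_bf = 2 * tp / (2 * tp + fn + fp) if (2 * tp + fn + fp) else 0.0
                assert f1[c] == pytest.approx(f1_bf)

    def test_confusion_matches_sklearn(self, rng):
        classes = ("fallow", "soybean", "oat")
        y_true = rng.choice(classes, size=200)
        y_pred = rng.choice(classes, size=200)
        cm = confusion(y_true, y_pred)
        ref = sk_confusion(y_true, y_pred, labels=list(classes))
        assert (cm.counts == ref).all()
        f1 = f1_per_class(cm)
        ref_f1 = sk_f1(y_true, y_pred, labels=list(classes), average=None, zero_division=0)
        for c, r in zip(classes, ref_f1):
            assert f1[c] == pytest.approx(r)

    def test_evaluate_report_roundtrip(self, rng):
        ds = two_blob_dataset(rng, n=50)
        model = train_rf(ds, n_trees=10, seed=0)
        report = evaluate(model, ds, classes=("fallow", "soybean", "oat"))
        payload = report.to_dict()
        assert payload["oa_percent"] == pytest.approx(100.0)
        assert set(payload["f1"]) == {"fallow", "soybean", "oat"}
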