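import numpy as np
import pandas as pd
import pytest

from scrkit.classify import (
    KernelNB,
    RUSBoostClassifier,
    _standardize_impute,
    binarize_sam,
    build_dataset,
    classifier_catalogue,
    format_benchmark,
    report_benchmark,
    run_benchmark,
)
from scrkit.features import FEATURE_NAMES


class TestBinarize:
    @pytest.mark.parametrize("score,expected", [(9, 1), (5, 1), (4, 0), (1, 0)])
    def test_threshold_five(self, score, expected):
        assert binarize_sam(score) == expected

    def test_threshold_one_everything_high(self):
        assert all(binarize_sam(s, threshold=1) == 1 for s in range(1, 10))

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError):
            binarize_sam(0)


class TestCatalogue:
    def test_twenty_configurations(self):
        assert len(classifier_catalogue()) == 20

    def test_families_complete(self):
        fams = {s.family for s in classifier_catalogue()}
        assert fams == {
            "logistic", "linear_discriminant", "naive_bayes", "tree",
            "ensemble", "knn", "svm",
        }

    def test_knn_fine_spec(self):
        spec = next(s for s in classifier_catalogue() if s.name == "knn/fine")
        assert spec.hyperparameters["n_neighbors"] == 2
        assert spec.hyperparameters["metric"] == "euclidean"

    def test_svm_iteration_cap(self):
        svms = [s for s in classifier_catalogue() if s.family == "svm"]
        assert len(svms) == 4
        assert all(s.hyperparameters["max_iterations"] == 100_000 for s in svms)

    def test_tree_split_budgets(self):
        splits = {
            s.variant: s.hyperparameters["max_splits"]
            for s in classifier_catalogue() if s.family == "tree"
        }
        assert splits == {"fine": 4, "medium": 20, "coarse": 100}


class TestDataset:
    def test_shape_two_rows_per_participant(self, small_sheet):
        sheet, sam = small_sheet
        X, y = build_dataset(sheet, sam, "flamenco")
        assert X.shape == (2 * sheet.participant_id.nunique(), 23)
        assert set(np.unique(y)) <= {0, 1}

    def test_deterministic(self, small_sheet):
        sheet, sam = small_sheet
        X1, y1 = build_dataset(sheet, sam, "cuban")
        X2, y2 = build_dataset(sheet, sam, "cuban")
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(y1, y2)

    def test_missing_sam_listed(self, small_sheet):
        sheet, sam = small_sheet
        partial = [r for r in sam if r.segment_label != "fandango"]
        with pytest.raises(ValueError, match="fandango"):
            build_dataset(sheet, partial, "flamenco")


class TestLeakage:
    def test_outlier_in_test_fold_cannot_leak_into_scaling(self, rng):
        X_train = rng.normal(size=(50, 23))
        X_test = rng.normal(size=(10, 23))
        X_test_out = X_test.copy()
        X_test_out[0] += 1e6
        tr_a, te_a = _standardize_impute(X_train, X_test)
        tr_b, te_b = _standardize_impute(X_train, X_test_out)
        np.testing.assert_array_equal(tr_a, tr_b)
        np.testing.assert_allclose(te_a[1:], te_b[1:])

    def test_imputation_uses_train_median(self, rng):
        X_train = rng.normal(size=(50, 3))
        X_test = rng.normal(size=(4, 3))
        X_test[2, 1] = np.nan
        _, te = _standardize_impute(X_train, X_test)
        mu, sd = X_train.mean(0), X_train.std(0)
        expected = (np.median(X_train[:, 1]) - mu[1]) / sd[1]
        assert te[2, 1] == pytest.approx(expected)


class TestInPackageEstimators:
    def test_kernel_nb_separates_gaussian_blobs(self, rng):
        X = np.vstack([rng.normal(-2, 1, (60, 4)), rng.normal(2, 1, (60, 4))])
        y = np.repeat([0, 1], 60)
        acc = (KernelNB().fit(X, y).predict(X) == y).mean()
        assert acc > 0.95

    def test_rusboost_handles_imbalance(self, rng):
        X = np.vstack([rng.normal(-1.5, 1, (80, 4)), rng.normal(1.5, 1, (20, 4))])
        y = np.repeat([0, 1], [80, 20])
        clf = RUSBoostClassifier(random_state=0).fit(X, y)
        pred = clf.predict(X)
        minority_recall = (pred[y == 1] == 1).mean()
        assert minority_recall > 0.8


class TestBenchmark:
    @pytest.fixture(scope="class")
    def separable(self):
        # labels are a threshold on the amplitude level; as in real EDA the
        # amplitude features co-move, so the signal spans several columns
        # (a single informative column among 22 standardized nuisance
        # columns would defeat any distance-based method)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 23))
        y = np.repeat([0, 1], 40)
        X[:, :8] += np.where(y == 1, 2.0, -2.0)[:, None]
        return X, y

    def test_separable_data_near_perfect(self, separable):
        X, y = separable
        res = run_benchmark(X, y, n_iterations=10, seed=0)
        rows = res.rows
        # KNN-coarse degenerates to majority vote once k reaches the fold size
        usable = rows[~((rows.family == "knn") & (rows.variant == "coarse"))]
        assert (usable.accuracy_mean >= 95.0).all()

    def test_deterministic_given_seed(self, separable):
        X, y = separable
        a = run_benchmark(X, y, n_iterations=5, seed=3)
        b = run_benchmark(X, y, n_iterations=5, seed=3)
        pd.testing.assert_frame_equal(a.rows, b.rows)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            run_benchmark(np.ones((10, 23)), np.zeros(10, dtype=int))

    def test_split_must_sum_to_one(self, separable):
        X, y = separable
        with pytest.raises(ValueError):
            run_benchmark(X, y, split=(0.8, 0.15, 0.15))

    def test_report_marks_best_per_family(self, separable):
        X, y = separable
        res = run_benchmark(X, y, n_iterations=5, seed=0)
        table = report_benchmark({"flamenco": res, "cuban": res})
        assert len(table) == 40
        for genre in ("flamenco", "cuban"):
            sub = table[table.genre == genre]
            assert sub.best_in_family.sum() == sub.family.nunique()
        text = format_benchmark(table)
        assert "flamenco" in text and "*" in text

    def test_accuracy_bounds(self, separable):
        X, y = separable
        res = run_benchmark(X, y, n_iterations=5, seed=0)
        assert ((res.rows.accuracy_mean >= 0) & (res.rows.accuracy_mean <= 100)).all()
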