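"""SVM training, evaluation reports, split arithmetic and PCA embedding."""

import numpy as np
import pandas as pd
import pytest

from tremorkit import pca_embedding, rebalance_dataset, train_svm, train_test_split
from tremorkit.model_eval import evaluate, evaluate_discarded, report_from_predictions

from test_rebalance import make_matrix


@pytest.fixture(scope="module")
def balanced_ds():
    fm = make_matrix([600, 400, 47], n_features=10, seed=0)
    return rebalance_dataset(fm, target=300, seed=0)


class TestSplit:
    def test_900_rows_split_675_225(self, balanced_ds):
        (X_tr, y_tr), (X_te, y_te) = train_test_split(balanced_ds, 0.75, seed=0)
        assert len(X_tr) == 675
        assert len(X_te) == 225

    def test_partition_disjoint_and_complete(self, balanced_ds):
        (X_tr, _), (X_te, _) = train_test_split(balanced_ds, 0.75, seed=1)
        idx = np.sort(np.concatenate([X_tr.index, X_te.index]))
        assert np.array_equal(idx, np.arange(len(balanced_ds.X)))


class TestTrainSvm:
    def test_separable_toy_perfect_training_accuracy(self):
        X = pd.DataFrame(
            [[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0]], columns=["a", "b"]
        )
        y = np.array([0, 0, 1, 1])
        model = train_svm((X, y))
        assert np.array_equal(model.predict(X), y)

    def test_deterministic_decision_function(self, balanced_ds):
        train, _ = train_test_split(balanced_ds, seed=0)
        m1 = train_svm(train, seed=0)
        m2 = train_svm(train, seed=0)
        probe = balanced_ds.X.iloc[:20]
        assert np.allclose(m1.decision_function(probe), m2.decision_function(probe))

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]})
        with pytest.raises(ValueError):
            train_svm((X, np.zeros(2, int)))

    def test_schema_mismatch_rejected(self, balanced_ds):
        train, _ = train_test_split(balanced_ds, seed=0)
        model = train_svm(train)
        bad = balanced_ds.X.iloc[:5].rename(columns={"f00": "zz"})
        with pytest.raises(ValueError, match="schema"):
            model.predict(bad)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = report_from_predictions(y, y)
        assert rep.accuracy == 1.0
        assert np.trace(rep.confusion) == 6

    def test_printed_toy_confusion(self):
        # true: 10x class0 -> 0, 5x class1 -> 2, 5x class2 -> 2
        y = np.array([0] * 10 + [1] * 5 + [2] * 5)
        pred = np.array([0] * 10 + [2] * 5 + [2] * 5)
        rep = report_from_predictions(y, pred)
        assert np.array_equal(rep.confusion, [[10, 0, 0], [0, 0, 5], [0, 0, 5]])
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.sensitivity == 1.0

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 3, 60)
        pred = rng.integers(0, 3, 60)
        perm = rng.permutation(60)
        r1 = report_from_predictions(y, pred)
        r2 = report_from_predictions(y[perm], pred[perm])
        assert np.array_equal(r1.confusion, r2.confusion)
        assert r1.accuracy == r2.accuracy

    def test_confusion_conservation(self, balanced_ds):
        train, test = train_test_split(balanced_ds, seed=0)
        model = train_svm(train)
        rep = evaluate(model, *test)
        assert rep.confusion.sum() == rep.n
        assert np.trace(rep.confusion) / rep.n == pytest.approx(rep.accuracy, abs=1e-12)
        row_sums = rep.confusion.sum(axis=1)
        for c in range(3):
            assert row_sums[c] == np.sum(np.asarray(test[1]) == c)
        norm_rows = rep.confusion_normalized.sum(axis=1)
        assert np.all((np.abs(norm_rows - 1.0) < 1e-12) | (norm_rows == 0.0))

    def test_adjacent_vs_nonadjacent_rates(self):
        y = np.array([0, 0, 1, 2])
        pred = np.array([1, 2, 1, 2])
        rep = report_from_predictions(y, pred)
        assert rep.adjacent_misclass_rate == pytest.approx(0.25)
        assert rep.nonadjacent_misclass_rate == pytest.approx(0.25)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            report_from_predictions(np.array([]), np.array([]))


class TestEvaluateDiscarded:
    def test_pool_composition_and_absent_class(self, balanced_ds):
        train, _ = train_test_split(balanced_ds, seed=0)
        model = train_svm(train)
        rep = evaluate_discarded(model, balanced_ds)
        # pool = (600-300) + (400-300) real rows, no class 2
        assert rep.n == 400
        assert rep.absent_classes == [2]

    def test_empty_pool_rejected(self):
        fm = make_matrix([30, 30, 5], n_features=4, seed=1)
        ds = rebalance_dataset(fm, target=30, seed=0)
        train, _ = train_test_split(ds, seed=0)
        model = train_svm(train)
        with pytest.raises(ValueError, match="empty"):
            evaluate_discarded(model, ds)


@pytest.fixture(scope="module")
def data():
    return np.random.default_rng(3).standard_normal((200, 10)) * np.arange(1, 11)


class TestPcaEmbedding:
    def test_components_uncorrelated(self, data):
        coords = pca_embedding(data)
        assert abs(np.corrcoef(coords[:, 0], coords[:, 1])[0, 1]) < 1e-8

    def test_variance_bounded_by_input(self, data):
        coords = pca_embedding(data)
        scaled_var = 10.0  # z-scored input has unit variance per feature
        assert coords.var(axis=0, ddof=1).sum() <= scaled_var + 1e-9

    def test_transform_deterministic(self, data):
        assert np.allclose(pca_embedding(data), pca_embedding(data))

    def test_same_loadings_applied_to_other_matrix(self, data):
        other = data[:50] + 0.1
        c_direct = pca_embedding(data)
        c_other = pca_embedding(other, fit_on=data)
        # applying the fit transformation to the fit data reproduces it
        assert np.allclose(pca_embedding(data, fit_on=data), c_direct)
        assert c_other.shape == (50, 2)

    def test_too_many_components_rejected(self, data):
        with pytest.raises(ValueError):
            pca_embedding(data, n_components=11)
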