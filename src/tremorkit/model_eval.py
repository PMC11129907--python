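"""SVM-RBF training and the dual in-sample / discarded-pool evaluation.

The balanced dataset is split 75/25 into train and test portions; an RBF
support vector machine (one-vs-one multiclass, features z-scored with
training statistics) predicts the severity class. Evaluation reports the
absolute and row-normalized confusion matrices, overall accuracy,
per-class accuracy, tremor sensitivity (any true label >= 1 predicted as
>= 1) and adjacent / non-adjacent misclassification rates, both on the
held-out test split and on the real rows discarded by undersampling —
the latter probes whether the classifier merely memorized the resampled
(partly synthetic) training distribution.

A 2-D PCA embedding fitted on the initial (pre-resampling) selected
features provides the standard visual check of class geometry; the same
loadings are applied to the resampled dataset so real and synthetic rows
are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split as _sk_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .rebalance import ResampledDataset

CLASSES = (0, 1, 2)


@dataclass
class TrainedModel:
    """A fitted scaler + SVM-RBF pair with its feature schema."""

    scaler: StandardScaler
    svm: SVC
    feature_names: list[str]
    C: float
    gamma: float | str
    seed: int

    @property
    def n_support(self) -> np.ndarray:
        return self.svm.n_support_

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.feature_names:
                raise ValueError(
                    "feature names/order mismatch the training schema"
                )
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.shape[1] != len(self.feature_names):
                raise ValueError("feature count mismatches the training schema")
        return X

    def predict(self, X) -> np.ndarray:
        return self.svm.predict(self.scaler.transform(self._check(X)))

    def decision_function(self, X) -> np.ndarray:
        return self.svm.decision_function(self.scaler.transform(self._check(X)))


@dataclass
class EvalReport:
    """Confusion matrices and summary metrics for one evaluation set."""

    dataset_id: str
    confusion: np.ndarray  # 3x3 absolute counts, rows = true class
    confusion_normalized: np.ndarray  # rows sum to 1 (or 0 for absent classes)
    accuracy: float
    sensitivity: float  # true >= 1 predicted >= 1
    per_class_accuracy: dict[int, float]
    adjacent_misclass_rate: float  # |true - pred| == 1, over all samples
    nonadjacent_misclass_rate: float  # |true - pred| == 2, over all samples
    n: int
    absent_classes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "confusion": self.confusion.tolist(),
            "confusion_normalized": self.confusion_normalized.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "per_class_accuracy": {int(k): v for k, v in self.per_class_accuracy.items()},
            "adjacent_misclass_rate": self.adjacent_misclass_rate,
            "nonadjacent_misclass_rate": self.nonadjacent_misclass_rate,
            "n": self.n,
            "absent_classes": self.absent_classes,
        }


def train_test_split(
    ds: ResampledDataset, train_frac: float = 0.75, seed: int = 0
) -> tuple[tuple[pd.DataFrame, np.ndarray], tuple[pd.DataFrame, np.ndarray]]:
    """Disjoint random 75/25 partition of the balanced rows (not stratified)."""
    X_tr, X_te, y_tr, y_te = _sk_split(
        ds.X, ds.y, train_size=train_frac, random_state=seed, shuffle=True
    )
    return (X_tr, y_tr), (X_te, y_te)


def train_svm(
    train: tuple[pd.DataFrame, np.ndarray],
    C: float = 1.0,
    gamma: float | str = "scale",
    seed: int = 0,
) -> TrainedModel:
    """Fit the z-scored RBF-kernel SVM (one-vs-one multiclass).

    ``gamma='scale'`` is 1 / (d * Var(features)) on the scaled matrix.
    """
    X, y = train
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"f{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    scaler = StandardScaler().fit(Xa)
    svm = SVC(C=C, kernel="rbf", gamma=gamma, random_state=seed)
    svm.fit(scaler.transform(Xa), y)
    return TrainedModel(scaler=scaler, svm=svm, feature_names=names, C=C, gamma=gamma, seed=seed)


def evaluate(model: TrainedModel, X, y, dataset_id: str = "test") -> EvalReport:
    """Full evaluation report on one labelled set."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("cannot evaluate on an empty set")
    return report_from_predictions(y, model.predict(X), dataset_id)


def report_from_predictions(y, pred, dataset_id: str = "test") -> EvalReport:
    """Build the evaluation report from true labels and predictions."""
    y = np.asarray(y)
    pred = np.asarray(pred)
    if len(y) == 0:
        raise ValueError("cannot evaluate on an empty set")
    conf = np.zeros((3, 3), dtype=int)
    for t, p in zip(y, pred):
        conf[int(t), int(p)] += 1
    row_sums = conf.sum(axis=1)
    norm = np.divide(
        conf, row_sums[:, None], out=np.zeros((3, 3)), where=row_sums[:, None] > 0
    )
    n = len(y)
    accuracy = float(np.trace(conf) / n)
    tremor_true = y >= 1
    sensitivity = (
        float(np.mean(pred[tremor_true] >= 1)) if tremor_true.any() else float("nan")
    )
    per_class = {
        c: (float(conf[c, c] / row_sums[c]) if row_sums[c] else float("nan"))
        for c in CLASSES
    }
    diff = np.abs(y - pred)
    return EvalReport(
        dataset_id=dataset_id,
        confusion=conf,
        confusion_normalized=norm,
        accuracy=accuracy,
        sensitivity=sensitivity,
        per_class_accuracy=per_class,
        adjacent_misclass_rate=float(np.mean(diff == 1)),
        nonadjacent_misclass_rate=float(np.mean(diff == 2)),
        n=n,
        absent_classes=[c for c in CLASSES if row_sums[c] == 0],
    )


def evaluate_discarded(model: TrainedModel, ds: ResampledDataset) -> EvalReport:
    """Evaluate on the real rows removed by undersampling (out-of-sample pool)."""
    if len(ds.discarded_X) == 0:
        raise ValueError("discarded pool is empty")
    return evaluate(model, ds.discarded_X, ds.discarded_y, dataset_id="discarded_pool")


def pca_embedding(
    X: pd.DataFrame | np.ndarray,
    n_components: int = 2,
    fit_on: pd.DataFrame | np.ndarray | None = None,
) -> np.ndarray:
    """2-D PCA coordinates of ``X``, with loadings fitted on ``fit_on``.

    When ``fit_on`` is None the loadings are fitted on ``X`` itself. The
    matrix used for fitting also defines the standardization, so the same
    transformation can be applied to a resampled dataset for side-by-side
    visualisation.
    """
    Xa = np.asarray(X, dtype=float)
    fit = Xa if fit_on is None else np.asarray(fit_on, dtype=float)
    if n_components > fit.shape[1]:
        raise ValueError(f"n_components={n_components} exceeds feature count {fit.shape[1]}")
    scaler = StandardScaler().fit(fit)
    pca = PCA(n_components=n_components, svd_solver="full").fit(scaler.transform(fit))
    return pca.transform(scaler.transform(Xa))
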