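"""Soft-margin Gaussian-kernel SVM classification of tissue state.

The classifier solves the standard soft-margin problem
``min 1/2 ||w||^2 + C sum_i xi_i`` in the feature space induced by the
Gaussian kernel ``kappa(xi, xj) = exp(-||xi - xj||^2 / (2 sigma^2))``.
Multi-class tasks use one-vs-one voting; multi-class ROC curves are macro
one-vs-rest on continuous decision scores.  Features are z-scored with
statistics of the training split only, so a single shared kernel width is
meaningful across markers of very different units.

scikit-learn's SVC provides the quadratic-program solver behind
:func:`train_classifier`; the decision-function contract
``f(x) = sum_i a_i y_i kappa(x_i, x) + b`` per binary subproblem is exposed
through the stored support vectors and dual coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

__all__ = [
    "DEFAULT_C_GRID",
    "DEFAULT_SIGMA_GRID",
    "gaussian_kernel",
    "split_train_test",
    "TrainedClassifier",
    "EvalMetrics",
    "train_classifier",
    "evaluate",
    "cross_validate",
    "pearson_matrix",
]

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_SIGMA_GRID = (0.5, 1.0, 2.0, 5.0)


class ClassifierError(ValueError):
    pass


def gaussian_kernel(xi: np.ndarray, xj: np.ndarray, sigma: float) -> float:
    """Gaussian (RBF) kernel value in (0, 1]."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if sigma <= 0:
        raise ClassifierError("sigma must be positive")
    if xi.shape != xj.shape:
        raise ClassifierError(f"dimension mismatch: {xi.shape} vs {xj.shape}")
    return float(np.exp(-np.sum((xi - xj) ** 2) / (2.0 * sigma**2)))


def _sigma_to_gamma(sigma: float) -> float:
    return 1.0 / (2.0 * sigma**2)


def split_train_test(
    table: pd.DataFrame, train_frac: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split on the ``status`` column (default 70/30)."""
    if not (0.0 < train_frac < 1.0):
        raise ClassifierError("train_frac must lie in (0, 1)")
    counts = table["status"].value_counts()
    if (counts < 2).any():
        raise ClassifierError("every class needs at least 2 rows to stratify")
    train, test = train_test_split(
        table, train_size=train_frac, stratify=table["status"], random_state=seed
    )
    return train, test


@dataclass
class TrainedClassifier:
    """Trained RBF-SVM plus the state needed to reproduce its decisions."""

    features: list[str]
    classes: np.ndarray
    C: float
    sigma: float
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    _svc: SVC = field(repr=False)

    @property
    def support_vectors(self) -> np.ndarray:
        return self._svc.support_vectors_

    @property
    def dual_coef(self) -> np.ndarray:
        return self._svc.dual_coef_

    @property
    def intercept(self) -> np.ndarray:
        return self._svc.intercept_

    def _design(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.features].to_numpy(dtype=float)
        return (x - self.scaler_mean) / self.scaler_sd

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self._svc.predict(self._design(table))

    def decision_scores(self, table: pd.DataFrame) -> np.ndarray:
        """Continuous decision values (one-vs-rest shape for multi-class)."""
        return self._svc.decision_function(self._design(table))

    def to_json(self, path: str | Path) -> None:
        state = {
            "features": self.features,
            "classes": self.classes.tolist(),
            "C": self.C,
            "sigma": self.sigma,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept.tolist(),
        }
        Path(path).write_text(json.dumps(state))


@dataclass(frozen=True)
class EvalMetrics:
    accuracy: float
    confusion: np.ndarray  # rows: true class, cols: predicted
    roc_points: dict[int, np.ndarray]  # class -> (fpr, tpr) array, shape (n, 2)
    auc: float  # binary AUC, or macro one-vs-rest average


def train_classifier(
    train: pd.DataFrame,
    features: list[str],
    C: float = 10.0,
    sigma: float = 2.0,
) -> TrainedClassifier:
    """Fit the soft-margin Gaussian-kernel SVM on z-scored features."""
    if not features:
        raise ClassifierError("feature list must be non-empty")
    y = train["status"].to_numpy()
    if np.unique(y).size < 2:
        raise ClassifierError("training data must contain at least 2 classes")
    x = train[list(features)].to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        import warnings

        warnings.warn(
            f"degenerate (zero-variance) features {np.array(features)[degenerate]}; "
            "their scale is set to 1",
            stacklevel=2,
        )
        sd = np.where(degenerate, 1.0, sd)
    svc = SVC(
        C=C,
        kernel="rbf",
        gamma=_sigma_to_gamma(sigma),
        decision_function_shape="ovr",
    )
    svc.fit((x - mean) / sd, y)
    return TrainedClassifier(
        features=list(features),
        classes=svc.classes_,
        C=C,
        sigma=sigma,
        scaler_mean=mean,
        scaler_sd=sd,
        _svc=svc,
    )


def evaluate(clf: TrainedClassifier, test: pd.DataFrame) -> EvalMetrics:
    """Accuracy, confusion matrix and ROC/AUC on a held-out split."""
    y = test["status"].to_numpy()
    unseen = np.setdiff1d(np.unique(y), clf.classes)
    if unseen.size:
        raise ClassifierError(f"test set contains unseen class codes {unseen}")
    pred = clf.predict(test)
    acc = float(np.mean(pred == y))
    conf = confusion_matrix(y, pred, labels=clf.classes)
    scores = clf.decision_scores(test)
    roc_points: dict[int, np.ndarray] = {}
    aucs = []
    if clf.classes.size == 2:
        fpr, tpr, _ = roc_curve(y, np.atleast_1d(scores), pos_label=clf.classes[1])
        roc_points[int(clf.classes[1])] = np.column_stack([fpr, tpr])
        aucs.append(_auc(fpr, tpr))
    else:
        for idx, cls in enumerate(clf.classes):
            fpr, tpr, _ = roc_curve((y == cls).astype(int), scores[:, idx])
            roc_points[int(cls)] = np.column_stack([fpr, tpr])
            aucs.append(_auc(fpr, tpr))
    return EvalMetrics(accuracy=acc, confusion=conf, roc_points=roc_points,
                       auc=float(np.mean(aucs)))


def cross_validate(
    table: pd.DataFrame,
    features: list[str],
    k: int = 10,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID,
    seed: int = 0,
) -> tuple[float, float, float, pd.DataFrame]:
    """Stratified k-fold grid search over (C, sigma).

    Returns ``(best_C, best_sigma, best_mean_accuracy, results)``; ties in
    mean accuracy break toward smaller C, then smaller sigma.
    """
    if k < 2:
        raise ClassifierError("k must be >= 2")
    if not c_grid or not sigma_grid:
        raise ClassifierError("hyperparameter grid must be non-empty")
    y = table["status"].to_numpy()
    if (pd.Series(y).value_counts() < k).any():
        raise ClassifierError("every class needs at least k rows for k-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(table)), y))
    records = []
    for C, sigma in product(sorted(c_grid), sorted(sigma_grid)):
        accs = []
        for train_idx, val_idx in folds:
            clf = train_classifier(table.iloc[train_idx], features, C=C, sigma=sigma)
            accs.append(float(np.mean(clf.predict(table.iloc[val_idx]) == y[val_idx])))
        records.append({"C": C, "sigma": sigma, "mean_accuracy": float(np.mean(accs))})
    results = pd.DataFrame(records)
    best = results.sort_values(
        ["mean_accuracy", "C", "sigma"], ascending=[False, True, True]
    ).iloc[0]
    return float(best["C"]), float(best["sigma"]), float(best["mean_accuracy"]), results


def pearson_matrix(table: pd.DataFrame, include_status: bool = True) -> pd.DataFrame:
    """Pearson correlation matrix of the markers (optionally with status).

    ``r = sum (x - xbar)(y - ybar) / sqrt(sum (x - xbar)^2 sum (y - ybar)^2)``.
    Constant columns yield missing (NaN) entries rather than zeros; the
    status code participates as the ordinal 0/1/2 variable.
    """
    cols = [c for c in table.columns if c not in ("measurement_id",)]
    if not include_status:
        cols = [c for c in cols if c != "status"]
    sub = table[cols].astype(float)
    if len(sub) < 3:
        raise ClassifierError("need at least 3 rows for a correlation matrix")
    return sub.corr(method="pearson")
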