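"""Leave-one-out benchmarking of four classifiers on feature subsets.

Classifiers: Mahalanobis-distance (per-class mean and covariance, nearest
class in Mahalanobis distance, ridge-regularized when singular), LDA and
QDA with equal priors (closed-form Gaussian discriminants, vectorized for
the thousands of leave-one-out fits the derivative-order grid requires),
and a linear SVM (C = 1) with per-fold standardization computed on the
training fold only.

Cross-validation is leave-one-RECORDING-out: fold k trains on all
recordings except k and predicts k. Performance metrics per classifier:

    SE = 100 TP / (TP + FN)          sensitivity
    PP = 100 TP / (TP + FP)          positive predictivity (precision)
    F1 = 2 SE PP / (SE + PP)
    OA = mean F1 across classifiers  (overall accuracy)

where "positive" is the post-exercise (heat-stressed) class. Ties in
distance or score predict the negative (rest) class, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIER_NAMES", "POSITIVE", "NEGATIVE",
    "loocv_predict", "confusion_metrics", "overall_accuracy",
    "evaluate_feature", "ClassifierReport",
]

CLASSIFIER_NAMES = ("mahalanobis", "lda", "qda", "svm_linear")
POSITIVE = "after"
NEGATIVE = "before"

_RIDGE = 1e-6  # trace-scaled ridge for singular class covariances


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    return X


def _reg_cov(Xc: np.ndarray) -> np.ndarray:
    """Class covariance, trace-scaled-ridge-regularized only if singular."""
    d = Xc.shape[1]
    cov = np.cov(Xc, rowvar=False).reshape(d, d)
    scale = np.trace(cov) / d
    if scale <= 0:
        scale = 1.0
    ridge = 0.0
    while True:
        try:
            np.linalg.cholesky(cov + ridge * np.eye(d))
            return cov + ridge * np.eye(d)
        except np.linalg.LinAlgError:
            ridge = _RIDGE * scale if ridge == 0 else ridge * 10
            if ridge > 1e6 * scale:  # pathological; fall back to identity
                return scale * np.eye(d)


def _gaussian_predict(name: str, X_train, y_train, X_test) -> np.ndarray:
    """Closed-form Gaussian classifiers (equal priors, tie -> negative).

    ``mahalanobis``: nearest class in Mahalanobis distance with per-class
    covariance. ``qda``: the same plus the 0.5 log|Sigma_c| term (the
    Gaussian Bayes rule). ``lda``: pooled within-class covariance, linear
    boundary. All use unbiased class covariances and the trace-scaled ridge
    of :func:`_reg_cov` when singular.
    """
    # drop columns constant across the whole training set: they carry no
    # class information and their ridge would distort the log-determinant
    col_sd = X_train.std(axis=0)
    keep = col_sd > 0
    if not keep.any():
        out = np.empty(len(X_test), dtype=object)
        out[:] = NEGATIVE  # no information: tie, negative class
        return out
    # per-column standardization for conditioning; the Gaussian rules are
    # affine-equivariant, so predictions are unchanged in exact arithmetic
    X_train = X_train[:, keep] / col_sd[keep]
    X_test = X_test[:, keep] / col_sd[keep]
    mu = {}
    covs, ns = {}, {}
    for label in (NEGATIVE, POSITIVE):
        Xc = X_train[y_train == label]
        ns[label] = len(Xc)
        mu[label] = Xc.mean(axis=0)
        covs[label] = _reg_cov(Xc)
    if name == "lda":
        pooled = ((ns[NEGATIVE] - 1) * covs[NEGATIVE]
                  + (ns[POSITIVE] - 1) * covs[POSITIVE]) / (sum(ns.values()) - 2)
        covs = {label: pooled for label in covs}
    score = {}
    for label in (NEGATIVE, POSITIVE):
        sign, ld = np.linalg.slogdet(covs[label])
        diff = X_test - mu[label]
        d2 = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(covs[label]), diff)
        score[label] = d2 + (ld if name == "qda" else 0.0)
    preds = np.empty(len(X_test), dtype=object)
    preds[:] = NEGATIVE
    preds[score[POSITIVE] < score[NEGATIVE]] = POSITIVE
    return preds


def _svm_predict(X_train, y_train, X_test) -> np.ndarray:
    # per-fold standardization from training statistics only (no leakage)
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    clf = SVC(kernel="linear", C=1.0)
    clf.fit((X_train - mu) / sd, y_train)
    return clf.predict((X_test - mu) / sd)


def loocv_predict(X, y, classifier: str) -> np.ndarray:
    """One held-out prediction per recording under leave-one-out CV."""
    X = _as_2d(X)
    y = np.asarray(y, dtype=object)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    labels = set(y)
    if not labels <= {NEGATIVE, POSITIVE}:
        raise ValueError(f"labels must be {{'{NEGATIVE}', '{POSITIVE}'}}, got {labels}")
    for label in (NEGATIVE, POSITIVE):
        if np.sum(y == label) < 3:
            raise ValueError(f"need >= 3 recordings per class, class {label!r} too small")
    n = len(X)
    preds = np.empty(n, dtype=object)
    mask = np.ones(n, dtype=bool)
    if classifier not in CLASSIFIER_NAMES:
        raise ValueError(f"unknown classifier {classifier!r}")
    for k in range(n):
        mask[k] = False
        if classifier == "svm_linear":
            preds[k] = _svm_predict(X[mask], y[mask], X[k:k + 1])[0]
        else:
            preds[k] = _gaussian_predict(classifier, X[mask], y[mask], X[k:k + 1])[0]
        mask[k] = True
    return preds


def confusion_metrics(pred, truth, positive: str = POSITIVE) -> dict:
    """Confusion counts and SE / PP / F1 (percent) for one classifier."""
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(pred) != len(truth):
        raise ValueError("pred and truth length mismatch")
    known = {NEGATIVE, POSITIVE}
    if not (set(pred) | set(truth)) <= known:
        raise ValueError(f"unknown label among {set(pred) | set(truth)}")
    tp = int(np.sum((pred == positive) & (truth == positive)))
    fn = int(np.sum((pred != positive) & (truth == positive)))
    fp = int(np.sum((pred == positive) & (truth != positive)))
    tn = int(np.sum((pred != positive) & (truth != positive)))
    se = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    pp = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    undefined = (se + pp) == 0
    f1 = 0.0 if undefined else 2.0 * se * pp / (se + pp)
    return {"TP": tp, "FN": fn, "FP": fp, "TN": tn,
            "SE": se, "PP": pp, "F1": f1, "f1_undefined": undefined}


def overall_accuracy(f1_scores: Sequence[float]) -> float:
    """Overall accuracy: arithmetic mean of the classifiers' F1 scores."""
    f1_scores = list(f1_scores)
    if not f1_scores:
        raise ValueError("need at least one F1 score")
    return float(np.mean(f1_scores))


@dataclass
class ClassifierReport:
    """Per-classifier confusion counts and metrics for one feature subset.

    ``table`` is indexed by classifier name with columns TP/FN/FP/TN/SE/PP/F1.
    """

    table: pd.DataFrame

    @property
    def oa(self) -> float:
        """Overall accuracy: mean F1 across the classifiers evaluated."""
        return overall_accuracy(self.table["F1"].tolist())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ClassifierReport OA={self.oa:.1f}%\n{self.table}>"


def evaluate_feature(X, y, classifiers: Sequence[str] = CLASSIFIER_NAMES,
                     ) -> ClassifierReport:
    """LOOCV-evaluate a feature subset under each classifier."""
    rows = {}
    for name in classifiers:
        pred = loocv_predict(X, y, name)
        m = confusion_metrics(pred, y)
        m.pop("f1_undefined")
        rows[name] = m
    table = pd.DataFrame(rows).T[["TP", "FN", "FP", "TN", "SE", "PP", "F1"]]
    table.index.name = "classifier"
    return ClassifierReport(table=table)
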