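"""Penalized classification of clinical characteristics and gene signatures.

Clinical labels (T, N, ER, PR, HER2) are predicted from image-level
radiomic features with an L1-penalized logistic regression evaluated along
a 100-value lambda path: the objective is the average logistic
log-likelihood plus ``lambda * sum(|beta_j|)``.  Per-lambda performance is
the 5-fold cross-validated AUC on a 70% training split; the selected lambda
maximizes mean CV AUC and is then scored on the 30% held-out split.

Binarized gene-signature / TIL targets are classified with two pluggable
backends (a small neural network and gradient-boosted trees) under a common
fit/score contract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupShuffleSplit, StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

__all__ = [
    "auc",
    "LassoPathResult",
    "LassoPathClassifier",
    "lasso_path_fit",
    "classify_clinical",
    "classify_signatures",
    "BACKENDS",
]

logger = logging.getLogger(__name__)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann–Whitney U statistic.

    Equals the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class LassoPathResult:
    lambda_grid: np.ndarray
    n_nonzero: np.ndarray
    cv_auc: np.ndarray
    best_lambda: float
    test_auc: float
    label: str = ""
    coefficients: np.ndarray | None = None


class LassoPathClassifier:
    """L1-penalized logistic regression fitted along a descending lambda path.

    The grid holds ``n_lambda`` log-spaced values from lambda_max (the
    smallest penalty at which every slope is zero, computed from the data)
    down to ``lambda_max * lambda_min_ratio``.  Features are standardized on
    the training data; the per-lambda sklearn fit uses C = 1 / (N * lambda).
    """

    def __init__(self, n_lambda: int = 100, lambda_min_ratio: float = 1e-3,
                 cv_folds: int = 5, seed: int = 0, max_iter: int = 2000):
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.cv_folds = cv_folds
        self.seed = seed
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"n_lambda": self.n_lambda,
                "lambda_min_ratio": self.lambda_min_ratio,
                "cv_folds": self.cv_folds, "seed": self.seed,
                "max_iter": self.max_iter}

    def set_params(self, **params) -> "LassoPathClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _fit_at(self, X: np.ndarray, y: np.ndarray, lam: float,
                ) -> LogisticRegression:
        C = 1.0 / (len(y) * lam)
        clf = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=C,
                                 max_iter=self.max_iter,
                                 random_state=self.seed)
        return clf.fit(X, y)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LassoPathClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels are degenerate (one class)")
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        # smallest lambda at which all slopes are zero (KKT at beta = 0)
        resid = y - y.mean()
        self.lambda_max_ = float(np.abs(Xs.T @ resid).max() / len(y))
        self.lambda_grid_ = np.logspace(
            np.log10(self.lambda_max_),
            np.log10(self.lambda_max_ * self.lambda_min_ratio), self.n_lambda)

        cv = StratifiedKFold(n_splits=self.cv_folds, shuffle=True,
                             random_state=self.seed)
        folds = list(cv.split(Xs, y))
        cv_auc = np.empty(self.n_lambda)
        n_nonzero = np.empty(self.n_lambda, dtype=int)
        self.path_coefs_ = np.empty((self.n_lambda, X.shape[1]))
        for i, lam in enumerate(self.lambda_grid_):
            fold_auc = []
            for tr, va in folds:
                if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                    continue
                clf = self._fit_at(Xs[tr], y[tr], lam)
                fold_auc.append(auc(clf.decision_function(Xs[va]), y[va]))
            cv_auc[i] = float(np.mean(fold_auc)) if fold_auc else 0.5
            full = self._fit_at(Xs, y, lam)
            self.path_coefs_[i] = full.coef_[0]
            n_nonzero[i] = int(np.sum(np.abs(full.coef_[0]) > 1e-10))
        self.cv_auc_ = cv_auc
        self.n_nonzero_ = n_nonzero
        # maximize CV AUC; ties resolved toward the sparser (larger) lambda
        self.best_index_ = int(np.argmax(cv_auc))
        self.best_lambda_ = float(self.lambda_grid_[self.best_index_])
        self.model_ = self._fit_at(Xs, y, self.best_lambda_)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.model_.decision_function(self.scaler_.transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict(self.scaler_.transform(X))


def lasso_path_fit(features: np.ndarray, labels: Sequence[float],
                   n_lambda: int = 100, cv_folds: int = 5,
                   split_ratio: float = 0.7, seed: int = 0,
                   groups: Sequence[str] | None = None,
                   label_name: str = "") -> LassoPathResult:
    """Train/evaluate the lasso path on a random split; returns the path result.

    Samples with missing labels are excluded before splitting.  When
    ``groups`` is given the split keeps each group (patient) entirely on
    one side.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    keep = ~np.isnan(y)
    X, y = X[keep], y[keep].astype(int)
    groups_arr = np.asarray(groups)[keep] if groups is not None else None
    if X.shape[0] < 20:
        raise ValueError("need at least 20 samples for the lasso path")
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate after exclusion")

    if groups_arr is not None:
        gss = GroupShuffleSplit(n_splits=1, train_size=split_ratio,
                                random_state=seed)
        tr, te = next(gss.split(X, y, groups_arr))
    else:
        tr, te = train_test_split(np.arange(len(y)), train_size=split_ratio,
                                  random_state=seed, stratify=y)
    if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
        raise ValueError("a split side lost one of the classes")

    path = LassoPathClassifier(n_lambda=n_lambda, cv_folds=cv_folds, seed=seed)
    path.fit(X[tr], y[tr])
    test_auc = auc(path.decision_function(X[te]), y[te])
    return LassoPathResult(lambda_grid=path.lambda_grid_,
                           n_nonzero=path.n_nonzero_, cv_auc=path.cv_auc_,
                           best_lambda=path.best_lambda_,
                           test_auc=float(test_auc), label=label_name,
                           coefficients=path.path_coefs_[path.best_index_])


def classify_clinical(features: pd.DataFrame, clinical: pd.DataFrame,
                      level: str = "image", n_lambda: int = 100,
                      cv_folds: int = 5, split_ratio: float = 0.7,
                      seed: int = 0, group_by_patient: bool = False,
                      ) -> dict[str, LassoPathResult]:
    """One lasso-path result per clinical label.

    ``features`` is the image-level frame (with ``patient_id`` column) or a
    patient-level matrix indexed by patient.  At image level each image
    inherits its patient's label; labels that are missing everywhere (or
    one-class) are skipped with a warning.
    """
    if level not in ("image", "patient"):
        raise ValueError("level must be 'image' or 'patient'")
    if level == "image":
        if "patient_id" not in features.columns:
            raise ValueError("image-level features need a patient_id column")
        pids = features["patient_id"].to_numpy()
        feat_cols = [c for c in features.columns
                     if c not in ("patient_id", "image_id")]
        X = features[feat_cols].to_numpy(dtype=float)
    else:
        pids = np.asarray(features.index)
        X = features.to_numpy(dtype=float)

    results: dict[str, LassoPathResult] = {}
    for label in clinical.columns:
        y = clinical[label].reindex(pids).to_numpy(dtype=float)
        observed = y[~np.isnan(y)]
        if observed.size == 0 or len(np.unique(observed)) < 2:
            warnings.warn(f"label {label!r} skipped: missing or one-class",
                          stacklevel=2)
            continue
        results[label] = lasso_path_fit(
            X, y, n_lambda=n_lambda, cv_folds=cv_folds,
            split_ratio=split_ratio, seed=seed,
            groups=pids if group_by_patient else None, label_name=label)
    return results


def _make_backend(name: str, seed: int):
    if name == "neural-net":
        from sklearn.neural_network import MLPClassifier
        return MLPClassifier(hidden_layer_sizes=(32,), max_iter=2000,
                             random_state=seed)
    if name == "gradient-boosted-trees":
        from xgboost import XGBClassifier
        return XGBClassifier(n_estimators=100, max_depth=3, learning_rate=0.1,
                             random_state=seed, verbosity=0,
                             eval_metric="logloss")
    raise ValueError(f"unknown backend {name!r}; available: {sorted(BACKENDS)}")


BACKENDS = ("neural-net", "gradient-boosted-trees")


def classify_signatures(features: np.ndarray | pd.DataFrame,
                        targets: pd.DataFrame,
                        backend: str = "gradient-boosted-trees",
                        split_ratio: float = 0.7,
                        seed: int = 0) -> pd.DataFrame:
    """Train/test AUC for each binarized signature/TIL target with one backend.

    ``targets`` holds one binary (0/1) column per signature or TIL score;
    rows must align with ``features`` rows.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] != len(targets):
        raise ValueError(f"features ({X.shape[0]} rows) and targets "
                         f"({len(targets)} rows) are misaligned")
    rows = []
    for col in targets.columns:
        y = targets[col].to_numpy(dtype=float)
        keep = ~np.isnan(y)
        Xk, yk = X[keep], y[keep].astype(int)
        tr, te = train_test_split(np.arange(len(yk)), train_size=split_ratio,
                                  random_state=seed, stratify=yk)
        clf = _make_backend(backend, seed)
        clf.fit(Xk[tr], yk[tr])
        score = clf.predict_proba(Xk[te])[:, 1]
        rows.append((col, backend, auc(score, yk[te])))
    return pd.DataFrame(rows, columns=["target", "backend", "auc"])
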