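"""Multi-parametric prediction of non-response with cross-validated search.

Two classifiers are supported, one supervised and one unsupervised:

* **logistic** — maximum-likelihood logistic regression of P(NR | x)
  with intercept; prediction is NR when the fitted probability is
  >= 0.5.  Perfect separation makes the MLE diverge, in which case the
  fit falls back to a mildly ridge-penalized solution with a warning.
* **kmeans** — 2-means clustering of the training features with the L1
  (city-block) distance: each of ``n_replicates`` restarts initializes
  the two centroids at two distinct training observations, Lloyd
  iterations assign points to the L1-nearest centroid and update
  centroids as coordinate-wise medians, and the restart with the least
  within-cluster L1 dispersion wins.  Each cluster takes the majority
  outcome of its training members (ties break toward NR, the class the
  model exists to catch); test points get the label of the L1-nearest
  centroid.

Model performance is estimated by leave-one-out cross-validation: each
patient is predicted by a model trained — including feature
standardization and any log transform — on the other n−1 only.
Sensitivity is the percentage of NR patients classified correctly,
specificity the percentage of PR+CR patients, accuracy the raw
percentage correct.

The subset search evaluates every feature combination in a size range by
LOOCV and ranks by accuracy, ties toward sensitivity, then smaller
subsets.  The full 2-to-26-parameter enumeration is ~2^26 subsets; the
search refuses ranges whose combination count exceeds a cap unless
explicitly overridden, reporting the count.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

__all__ = [
    "KMeansClassifierSpec",
    "ModelEvaluation",
    "FeatureTable",
    "fit_logistic",
    "fit_kmeans_classifier",
    "loocv",
    "subset_search",
    "count_subsets",
]


@dataclass(frozen=True)
class KMeansClassifierSpec:
    """2-means / L1 nearest-cluster classifier parameters."""

    n_replicates: int = 30
    max_iter: int = 100
    seed: int = 0
    k: int = 2

    def __post_init__(self) -> None:
        if self.k != 2:
            raise ValueError("the classifier is defined for exactly 2 clusters")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class ModelEvaluation:
    """LOOCV performance of one feature subset under one classifier."""

    feature_subset: tuple[str, ...]
    classifier: str
    se: float  # % NR classified correctly
    sp: float  # % PR+CR classified correctly
    accuracy: float  # % correct overall
    predictions: np.ndarray  # per-patient LOOCV predictions (bool, True = NR)
    tp: int
    fn: int
    tn: int
    fp: int


@dataclass(frozen=True)
class FeatureTable:
    """Per-patient features plus the binary outcome (True = NR)."""

    features: pd.DataFrame
    outcome: np.ndarray
    log_transform: tuple[str, ...] = ()  # feature names to log-transform

    def __post_init__(self) -> None:
        y = np.asarray(self.outcome, dtype=bool)
        if len(self.features) != y.size:
            raise ValueError("outcome length does not match the feature table")
        if y.all() or not y.any():
            raise ValueError("outcome must contain both classes")
        object.__setattr__(self, "outcome", y)
        missing = [c for c in self.log_transform if c not in self.features.columns]
        if missing:
            raise ValueError(f"log_transform names not in table: {missing}")

    def select(self, subset: Sequence[str]) -> np.ndarray:
        missing = [c for c in subset if c not in self.features.columns]
        if missing:
            raise ValueError(f"unknown features: {missing}")
        x = self.features.loc[:, list(subset)].to_numpy(dtype=float)
        if not np.isfinite(x).all():
            bad = [
                (self.features.index[i], subset[j])
                for i, j in zip(*np.nonzero(~np.isfinite(x)))
            ]
            raise ValueError(f"missing/non-finite values in selected features: {bad}")
        return x


class _LogisticModel:
    def __init__(self, clf: LogisticRegression, keep: np.ndarray):
        self._clf = clf
        self._keep = keep

    @property
    def coef_(self) -> np.ndarray:
        return self._clf.coef_[0]

    @property
    def intercept_(self) -> float:
        return float(self._clf.intercept_[0])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self._clf.predict_proba(np.asarray(x, dtype=float)[:, self._keep])[:, 1]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x) >= 0.5


def fit_logistic(x, y) -> _LogisticModel:
    """Maximum-likelihood logistic regression with a ridge fallback.

    Constant features carry no information and are dropped with a
    warning.  Separation (diverging MLE) triggers a refit with a mild L2
    penalty, also flagged by a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=bool)
    if x.ndim != 2:
        raise ValueError("x must be 2D")
    for cls in (True, False):
        if (y == cls).sum() < 2:
            raise ValueError("need at least 2 patients per class")
    keep = x.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature(s)", stacklevel=2)
    if not keep.any():
        raise ValueError("all features are constant")
    xk = x[:, keep]
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-10,
                                     max_iter=1000).fit(xk, y)
            prob = clf.predict_proba(xk)[:, 1]
            # saturated fitted probabilities mean the MLE is off at infinity
            diverged = bool(np.abs(clf.coef_).max() > 1e4
                            or np.all((prob < 1e-8) | (prob > 1 - 1e-8)))
        except ConvergenceWarning:
            diverged = True
            clf = None
    if diverged or clf is None:
        warnings.warn("logistic MLE did not converge (separation?); "
                      "falling back to ridge-penalized fit", stacklevel=2)
        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000).fit(xk, y)
    return _LogisticModel(clf, keep)


class _KMeansClassifier:
    def __init__(self, centroids: np.ndarray, cluster_labels: np.ndarray,
                 inertia: float, flags: tuple[str, ...]):
        self.centroids = centroids  # (2, d)
        self.cluster_labels = cluster_labels  # (2,) bool, True = NR
        self.inertia = inertia
        self.flags = flags

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        d = np.abs(x[:, None, :] - self.centroids[None, :, :]).sum(axis=2)
        return self.cluster_labels[d.argmin(axis=1)]


def _l1_kmeans_once(x: np.ndarray, init_idx: np.ndarray, max_iter: int):
    centroids = x[init_idx].copy()
    assign = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        d = np.abs(x[:, None, :] - centroids[None, :, :]).sum(axis=2)
        new_assign = d.argmin(axis=1)
        for c in range(2):
            members = x[new_assign == c]
            if len(members):
                centroids[c] = np.median(members, axis=0)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    d = np.abs(x[:, None, :] - centroids[None, :, :]).sum(axis=2)
    assign = d.argmin(axis=1)
    inertia = float(d[np.arange(len(x)), assign].sum())
    return centroids, assign, inertia


def fit_kmeans_classifier(x, y, spec: KMeansClassifierSpec | None = None) -> _KMeansClassifier:
    """Fit the 2-means / L1 nearest-cluster classifier (best of replicates)."""
    spec = spec or KMeansClassifierSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=bool)
    if len(x) < 2:
        raise ValueError("need at least 2 training points")
    rng = np.random.default_rng(spec.seed)
    best = None
    for _ in range(spec.n_replicates):
        init_idx = rng.choice(len(x), size=2, replace=False)
        centroids, assign, inertia = _l1_kmeans_once(x, init_idx, spec.max_iter)
        if best is None or inertia < best[2]:
            best = (centroids, assign, inertia)
    centroids, assign, inertia = best
    labels = np.zeros(2, dtype=bool)
    flags: list[str] = []
    for c in range(2):
        members = y[assign == c]
        if members.size == 0:
            # empty cluster: label by the overall minority-catching default
            labels[c] = True
            flags.append(f"empty_cluster:{c}")
        else:
            n_pos, n_neg = int(members.sum()), int((~members).sum())
            if n_pos == n_neg:
                labels[c] = True  # tie → NR, sensitivity priority
                flags.append(f"majority_tie:{c}")
            else:
                labels[c] = n_pos > n_neg
    return _KMeansClassifier(centroids, labels, inertia, tuple(flags))


def _prepare_fold(train_x: np.ndarray, test_x: np.ndarray,
                  log_cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Training-fold-only log transform and z-scoring (no leakage)."""
    train_x = train_x.copy()
    test_x = test_x.copy()
    for j in np.flatnonzero(log_cols):
        col = train_x[:, j]
        # data-driven positivity: shift so the training minimum maps to 1
        offset = 1.0 - col.min() if col.min() <= 0 else 0.0
        train_x[:, j] = np.log(col + offset)
        test_x[:, j] = np.log(np.maximum(test_x[:, j] + offset, 1e-12))
    mu = train_x.mean(axis=0)
    sd = train_x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train_x - mu) / sd, (test_x - mu) / sd


def loocv(table: FeatureTable, subset: Sequence[str], classifier: str = "kmeans",
          spec: KMeansClassifierSpec | None = None) -> ModelEvaluation:
    """Leave-one-out cross-validated evaluation of one feature subset.

    Every per-fold model — including the z-scoring parameters and any
    log transform — is fitted on the n−1 training patients only.
    """
    if classifier not in ("logistic", "kmeans"):
        raise ValueError("classifier must be 'logistic' or 'kmeans'")
    subset = tuple(subset)
    if not subset:
        raise ValueError("feature subset must be nonempty")
    x = table.select(subset)
    y = table.outcome
    log_cols = np.array([name in table.log_transform for name in subset])
    n = len(y)
    preds = np.zeros(n, dtype=bool)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        ytr = y[tr]
        if ytr.all() or not ytr.any():
            raise ValueError(f"fold {i}: training set contains a single class")
        xtr, xte = _prepare_fold(x[tr], x[i: i + 1], log_cols)
        if classifier == "logistic":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_logistic(xtr, ytr)
        else:
            fold_spec = spec or KMeansClassifierSpec()
            model = fit_kmeans_classifier(xtr, ytr, fold_spec)
        preds[i] = bool(model.predict(xte)[0])
    tp = int((preds & y).sum())
    fn = int((~preds & y).sum())
    tn = int((~preds & ~y).sum())
    fp = int((preds & ~y).sum())
    return ModelEvaluation(
        feature_subset=subset,
        classifier=classifier,
        se=100.0 * tp / (tp + fn),
        sp=100.0 * tn / (tn + fp),
        accuracy=100.0 * (tp + tn) / n,
        predictions=preds,
        tp=tp, fn=fn, tn=tn, fp=fp,
    )


def count_subsets(n_features: int, sizes: Sequence[int]) -> int:
    return sum(math.comb(n_features, k) for k in sizes)


def subset_search(table: FeatureTable, classifier: str = "kmeans",
                  size_range: tuple[int, int] = (2, 4),
                  spec: KMeansClassifierSpec | None = None,
                  max_evaluations: int = 10**6,
                  force: bool = False) -> list[ModelEvaluation]:
    """Exhaustively evaluate all feature subsets in a size range by LOOCV.

    Subsets are ranked by accuracy, ties by sensitivity, then by smaller
    size, then lexicographically (fully reproducible ordering).  A range
    whose combination count exceeds ``max_evaluations`` is refused with
    the count reported, unless ``force`` is set.
    """
    names = list(table.features.columns)
    lo, hi = size_range
    if not 2 <= lo <= hi <= len(names):
        raise ValueError(f"size_range must lie within [2, {len(names)}]")
    sizes = range(lo, hi + 1)
    n_comb = count_subsets(len(names), sizes)
    if n_comb > max_evaluations and not force:
        raise ValueError(
            f"{n_comb} subset evaluations requested, exceeding the cap of "
            f"{max_evaluations}; narrow the size range or pass force=True"
        )
    results = []
    for k in sizes:
        for combo in combinations(names, k):
            results.append(loocv(table, combo, classifier, spec))
    results.sort(key=lambda ev: (-ev.accuracy, -ev.se, len(ev.feature_subset),
                                 ev.feature_subset))
    return results
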