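"""Repeated stratified cross-validation with rank-based AUC scoring.

AUC is computed as the probability that a random positive outranks a random
negative, ties counting one half — the Mann-Whitney form — so it is exact
for any score vector, including the piecewise-constant scores produced by
tree ensembles on binary rule encodings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.impute import SimpleImputer
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)


@dataclass
class CVSpec:
    """Stratified k-fold repeated-CV specification (default 10-fold x 100,
    matching the framework's evaluation protocol; reduce ``n_repeats`` for
    desk-scale runs)."""

    n_folds: int = 10
    n_repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Probability a positive outranks a negative (ties count 1/2).

    Equivalent to the area under the ROC curve; computed from mid-ranks:
    AUC = (sum of positive ranks - n_pos(n_pos+1)/2) / (n_pos * n_neg).
    """
    y = np.asarray(y_true, dtype=float)
    s = np.asarray(scores, dtype=float)
    pos = y == 1.0
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def predict_scores(estimator, X: np.ndarray) -> np.ndarray:
    """Positive-class score from an estimator (probability if available,
    else decision function)."""
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    return estimator.decision_function(X)


def make_pipeline(estimator, scale: bool = True) -> Pipeline:
    """Median imputation (fit on the training side only) + optional
    standardization + classifier; keeps CV leakage-safe."""
    steps = [("impute", SimpleImputer(strategy="median"))]
    if scale:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", estimator))
    return Pipeline(steps)


def repeated_cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    estimator_factory,
    spec: CVSpec,
    scale: bool = True,
) -> tuple[float, float]:
    """Mean and sd of out-of-fold AUC over all folds x repeats.

    ``estimator_factory`` is a zero-argument callable returning a fresh
    (seeded) classifier.  Fold assignment is stratified and seeded from
    ``spec.seed``.  A degenerate fold with a single class is skipped with
    a warning (stratification prevents this unless a class has fewer
    members than folds).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_min = int(min(np.sum(y == 1.0), np.sum(y == 0.0)))
    n_folds = min(spec.n_folds, n_min)
    if n_folds < spec.n_folds:
        logger.warning("reducing folds %d -> %d (smallest class has %d members)",
                       spec.n_folds, n_folds, n_min)
    if n_folds < 2:
        raise ValueError("need at least 2 members in each class")
    cv = RepeatedStratifiedKFold(
        n_splits=n_folds, n_repeats=spec.n_repeats, random_state=spec.seed
    )
    aucs: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for train_idx, test_idx in cv.split(X, y):
            if len(np.unique(y[test_idx])) < 2:
                logger.warning("single-class fold skipped")
                continue
            model = make_pipeline(estimator_factory(), scale=scale)
            model.fit(X[train_idx], y[train_idx])
            scores = predict_scores(model, X[test_idx])
            aucs.append(auc_score(y[test_idx], scores))
    arr = np.asarray(aucs)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0
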