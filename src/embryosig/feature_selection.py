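"""Stage 1: feature ranking and selection by repeated-CV AUC.

Three rankers — a univariate rank-statistic filter, an L1-regularized linear
model and a tree-ensemble importance (the two embedded methods) — are
aggregated by mean rank.  Nested top-k feature sets are then scored by
repeated stratified cross-validation with every roster classifier; per set
size the best mean AUC over the roster is recorded, and the chosen size is
the smallest whose best AUC is within one standard error of the global
maximum (the parsimony, "one-SE", reading of a balanced cut-off between set
size and association strength).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .classifiers import ClassifierRoster
from .crossval import CVSpec, repeated_cv_auc
from .schema import CohortTable

logger = logging.getLogger(__name__)


@dataclass
class FeatureSelectionResult:
    selected: list[str]
    rank_tables: pd.DataFrame  # per-method ranks, one row per feature
    aggregated_rank: pd.Series  # mean rank, ascending = better
    curve: pd.DataFrame  # columns: k, auc_mean, auc_sd, classifier
    chosen_k: int
    best_classifier: str

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "chosen_k": int(self.chosen_k),
            "best_classifier": self.best_classifier,
            "curve": self.curve.to_dict(orient="records"),
            "aggregated_rank": {k: float(v) for k, v in self.aggregated_rank.items()},
        }


def _ranks(scores: pd.Series, ascending: bool = False) -> pd.Series:
    """Average ranks, 1 = best; NaN scores rank last."""
    filled = scores.fillna(-np.inf if not ascending else np.inf)
    return filled.rank(ascending=ascending, method="average")


def rank_features_filter(
    train: CohortTable, labels: np.ndarray | None = None, method: str = "rank_statistic"
) -> pd.DataFrame:
    """Univariate filter ranking.

    ``rank_statistic`` (default): absolute standardized Mann-Whitney
    statistic per feature (two-sided, tie-corrected) — deterministic and
    monotone-transform invariant.  ``auc``: |univariate AUC - 0.5|.
    A constant feature gets score 0 (ranked last) with a warning.
    """
    y = train.labels if labels is None else np.asarray(labels, dtype=float)
    X = train.features()
    scores = {}
    for col in train.feature_names:
        x = X[col].to_numpy()
        ok = ~np.isnan(x) & ~np.isnan(y)
        x0, x1 = x[ok & (y == 0.0)], x[ok & (y == 1.0)]
        if x0.size == 0 or x1.size == 0 or np.unique(x[ok]).size < 2:
            logger.warning("feature %s constant or single-group; ranked last", col)
            scores[col] = np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u, _ = stats.mannwhitneyu(x1, x0, alternative="two-sided")
        auc = u / (x0.size * x1.size)
        if method == "auc":
            scores[col] = abs(auc - 0.5)
        else:
            # standardized distance of U from its null mean, tie-agnostic scale
            mu = x0.size * x1.size / 2.0
            sd = np.sqrt(x0.size * x1.size * (x0.size + x1.size + 1) / 12.0)
            scores[col] = abs(u - mu) / sd
    s = pd.Series(scores, name="score")
    return pd.DataFrame({"score": s, "rank": _ranks(s)})


def rank_features_embedded(
    train: CohortTable,
    labels: np.ndarray | None = None,
    seed: int = 0,
    l1_C: float = 10.0,
    n_trees: int = 200,
) -> pd.DataFrame:
    """Embedded rankings: |coefficients| of an L1 logistic regression and
    impurity importances of a random forest, each converted to ranks.

    The default penalty is mild (C=10): under the strong collinearity of
    cytokinesis timings a hard lasso zeroes all but one member of a
    correlated group, which makes coefficient ranks degenerate.

    Missing values are median-imputed with the imputer fit on this training
    table only; features are standardized for the linear model so
    coefficient magnitudes are comparable.
    """
    y = train.labels if labels is None else np.asarray(labels, dtype=float)
    if np.unique(y[~np.isnan(y)]).size < 2:
        raise ValueError("embedded ranking needs both classes")
    X = train.features().to_numpy()
    X = SimpleImputer(strategy="median").fit_transform(X)
    Xs = StandardScaler().fit_transform(X)

    lasso = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", C=l1_C, random_state=seed, max_iter=1000
    ).fit(Xs, y)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed).fit(X, y)

    idx = list(train.feature_names)
    l1 = pd.Series(np.abs(lasso.coef_[0]), index=idx, name="l1_coef")
    imp = pd.Series(forest.feature_importances_, index=idx, name="tree_importance")
    return pd.DataFrame(
        {
            "l1_coef": l1,
            "l1_rank": _ranks(l1),
            "tree_importance": imp,
            "tree_rank": _ranks(imp),
        }
    )


def aggregate_ranks(
    filter_table: pd.DataFrame,
    embedded_table: pd.DataFrame,
    method: str = "median",
) -> pd.Series:
    """Aggregate the filter and both embedded rankings (1 = best).

    The default is the median rank: it is robust to the known failure mode
    of any single ranker (an L1 model drops all but one member of a group
    of collinear features, so its coefficient ranks can be degenerate for
    exactly the features the other two methods agree are informative).
    ``method='mean'`` gives plain mean-rank aggregation.  Ties are broken
    by canonical feature order downstream.
    """
    mat = pd.concat(
        [filter_table["rank"], embedded_table["l1_rank"], embedded_table["tree_rank"]],
        axis=1,
    )
    if method == "median":
        return mat.median(axis=1).rename("agg_rank")
    if method == "mean":
        return mat.mean(axis=1).rename("agg_rank")
    raise ValueError("method must be 'median' or 'mean'")


def select_feature_set(
    train: CohortTable,
    labels: np.ndarray | None = None,
    roster: ClassifierRoster | None = None,
    spec: CVSpec | None = None,
    min_k: int = 3,
    max_k: int | None = None,
    aggregation: str = "median",
    seed: int = 0,
) -> FeatureSelectionResult:
    """Full stage-1 selection: rank, sweep nested top-k sets, apply the
    one-standard-error rule to the max-over-roster AUC curve."""
    y = train.labels if labels is None else np.asarray(labels, dtype=float)
    roster = roster or ClassifierRoster(seed=seed)
    spec = spec or CVSpec(seed=seed)

    filt = rank_features_filter(train, y)
    emb = rank_features_embedded(train, y, seed=seed)
    agg = aggregate_ranks(filt, emb, method=aggregation)
    # deterministic order: mean rank, then canonical name order
    order = sorted(train.feature_names, key=lambda f: (agg[f], train.feature_names.index(f)))

    p = len(order)
    max_k = min(max_k or p, p)
    min_k = min(min_k, max_k)
    sizes = list(range(min_k, max_k + 1))

    Xfull = train.features(order).to_numpy()
    rows = []
    for k in sizes:
        best_auc, best_sd, best_clf = -np.inf, np.nan, None
        for name, factory in roster.factories().items():
            mean_auc, sd_auc = repeated_cv_auc(Xfull[:, :k], y, factory, spec)
            if mean_auc > best_auc:
                best_auc, best_sd, best_clf = mean_auc, sd_auc, name
        rows.append({"k": k, "auc_mean": best_auc, "auc_sd": best_sd,
                     "classifier": best_clf})
        logger.info("feature sweep k=%d: max AUC %.3f (%s)", k, best_auc, best_clf)
    curve = pd.DataFrame(rows)

    n_evals = spec.n_folds * spec.n_repeats
    i_best = int(curve["auc_mean"].idxmax())
    se_best = curve.loc[i_best, "auc_sd"] / np.sqrt(max(n_evals, 1))
    threshold = curve.loc[i_best, "auc_mean"] - se_best
    within = curve[curve["auc_mean"] >= threshold]
    chosen = within.iloc[0]

    rank_tables = pd.concat([filt, emb], axis=1)
    return FeatureSelectionResult(
        selected=order[: int(chosen["k"])],
        rank_tables=rank_tables,
        aggregated_rank=agg,
        curve=curve,
        chosen_k=int(chosen["k"]),
        best_classifier=str(curve.loc[i_best, "classifier"]),
    )
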