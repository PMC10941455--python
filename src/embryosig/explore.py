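"""Exploratory stage: PCA embedding, Pearson correlation matrix and
per-feature Kruskal-Wallis tests between the BL and nBL groups.

These are descriptive views of the cohort (no multiple-testing correction
is applied); mean imputation is used only inside the PCA embedding, never
for any modelling stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .schema import CohortTable

SIGNIFICANCE_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_code(p: float) -> str:
    for threshold, code in SIGNIFICANCE_LEVELS:
        if p < threshold:
            return code
    return "ns"


def pca_embed(
    table: CohortTable, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores and explained-variance fractions on the (z-scored) table.

    Missing values are mean-imputed for the embedding only.  Explained
    variance fractions are nonincreasing and sum to at most 1.
    """
    X = table.features().to_numpy()
    if n_components > X.shape[1]:
        raise ValueError(
            f"n_components={n_components} exceeds feature count {X.shape[1]}"
        )
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    X = np.where(np.isnan(X), col_mean, X)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


def pearson_matrix(table: CohortTable, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations, features grouped by category.

    An entry with fewer than ``min_pairs`` complete pairs is left missing.
    """
    order = (
        table.category_features("woman")
        + table.category_features("cos")
        + table.category_features("embryo")
    )
    corr = table.features(order).corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


@dataclass
class FeatureTestResult:
    feature: str
    statistic: float
    p_value: float
    code: str
    testable: bool = True


def kruskal_tests(
    table: CohortTable, labels: np.ndarray | None = None
) -> list[FeatureTestResult]:
    """Tie-corrected Kruskal-Wallis rank test of each feature between the
    two outcome groups (chi-square reference, 1 df).

    A feature entirely missing in one group (or with all values tied) is
    flagged untestable rather than assigned a statistic.
    """
    y = table.labels if labels is None else np.asarray(labels, dtype=float)
    X = table.features()
    results: list[FeatureTestResult] = []
    for col in table.feature_names:
        x = X[col].to_numpy()
        ok = ~np.isnan(x) & ~np.isnan(y)
        g0, g1 = x[ok & (y == 0.0)], x[ok & (y == 1.0)]
        if g0.size == 0 or g1.size == 0:
            results.append(FeatureTestResult(col, np.nan, np.nan, "untestable", False))
            continue
        if np.unique(np.concatenate([g0, g1])).size < 2:
            # all values tied: no rank separation, H = 0 by definition
            results.append(FeatureTestResult(col, 0.0, 1.0, "ns"))
            continue
        h, p = stats.kruskal(g1, g0)
        results.append(FeatureTestResult(col, float(h), float(p), significance_code(p)))
    return results


def group_quantiles(
    table: CohortTable, labels: np.ndarray | None = None,
    quantiles=(0.25, 0.5, 0.75),
) -> pd.DataFrame:
    """Per-feature group quantiles (the numerical surface behind the
    split-violin view of the two outcome groups)."""
    y = table.labels if labels is None else np.asarray(labels, dtype=float)
    X = table.features()
    rows = []
    for col in table.feature_names:
        for group, name in ((1.0, "BL"), (0.0, "nBL")):
            vals = X[col].to_numpy()[y == group]
            vals = vals[~np.isnan(vals)]
            row = {"feature": col, "group": name, "n": vals.size}
            for q in quantiles:
                row[f"q{int(q * 100)}"] = float(np.quantile(vals, q)) if vals.size else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def tests_to_frame(results: list[FeatureTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "H": r.statistic,
                "p_value": r.p_value,
                "code": r.code,
                "testable": r.testable,
            }
            for r in results
        ]
    )


# --------------------------------------------------------------- plotting


def plot_pca(scores: np.ndarray, labels: np.ndarray, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for value, name, color in ((1.0, "BL", "tab:blue"), (0.0, "nBL", "tab:orange")):
        m = labels == value
        ax.scatter(scores[m, 0], scores[m, 1], s=8, alpha=0.6, label=name, c=color)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_correlation_heatmap(corr: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.columns)), corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr.index)), corr.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
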