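"""One-way ANOVA feature ranking and selection.

Each feature is scored by the classical one-way ANOVA F statistic across the
class groups, F = MS_between / MS_within with (k-1, N-k) degrees of freedom.
The F values are used purely as a ranking filter (no multiple-testing
correction: selection, not inference). Ties in F are broken by feature name
so the ranking is reproducible.

The default selection keeps k=24 features: the four feature types the
ranking is expected to favor (approximate entropy, correlation dimension,
spectral peak amplitude, tremor-band power) times the six channels.
"""

from __future__ import annotations

import warnings
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

__all__ = ["anova_rank", "select_features", "AnovaFeatureSelector", "anova_f"]

_META_COLS = ("subject_id", "class_label")


def anova_f(groups: Sequence[np.ndarray]) -> Tuple[float, float]:
    """One-way ANOVA F statistic and p-value from group sums of squares.

    Edge contracts: all values equal -> F = 0; zero within-group variance
    with unequal group means -> F = +inf with p = 0 (and a warning).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    n_total = sum(len(g) for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        warnings.warn("zero within-group variance with unequal means; F = +inf")
        return float("inf"), 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p


def _split_groups(table: pd.DataFrame, feature: str) -> List[np.ndarray]:
    return [
        grp[feature].to_numpy(dtype=float)
        for _, grp in table.groupby("class_label", sort=True)
    ]


def anova_rank(table: pd.DataFrame) -> pd.DataFrame:
    """Rank every feature column of a feature table by its ANOVA F.

    Returns a DataFrame with columns feature, F, p_value, normalized_score
    (F / max F) and rank (1 = largest F; ties broken lexicographically by
    feature name).
    """
    features = [c for c in table.columns if c not in _META_COLS]
    if not features:
        raise ValueError("feature table has no feature columns")
    counts = table["class_label"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 classes with >= 2 samples each")
    records = []
    for feat in features:
        f, p = anova_f(_split_groups(table, feat))
        records.append((feat, f, p))
    out = pd.DataFrame(records, columns=["feature", "F", "p_value"])
    finite = out["F"].replace(np.inf, np.nan)
    max_f = finite.max()
    if np.isinf(out["F"]).any():
        out["normalized_score"] = np.where(np.isinf(out["F"]), 1.0, out["F"] / max_f)
    else:
        out["normalized_score"] = out["F"] / max_f if max_f > 0 else 0.0
    order = out.sort_values(["F", "feature"], ascending=[False, True], kind="mergesort")
    out.loc[order.index, "rank"] = np.arange(1, len(out) + 1)
    out["rank"] = out["rank"].astype(int)
    return out.sort_values("rank").reset_index(drop=True)


def select_features(ranking: pd.DataFrame, table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep the k top-ranked features; row order and labels preserved.

    Columns of the reduced table are ordered by rank.
    """
    n_features = len(ranking)
    if not (1 <= k <= n_features):
        raise ValueError(f"k must be in [1, {n_features}], got {k}")
    top = ranking.sort_values("rank")["feature"].head(k).tolist()
    missing = [f for f in top if f not in table.columns]
    if missing:
        raise ValueError(f"ranked features missing from table: {missing}")
    return table[list(_META_COLS) + top].copy()


class AnovaFeatureSelector(SelectorMixin, BaseEstimator):
    """sklearn-style selector keeping the k features with the largest F.

    Accepts plain arrays (fit(X, y)) for pipeline use; the functional
    wrappers :func:`anova_rank` / :func:`select_features` cover the
    feature-table workflow.
    """

    def __init__(self, k: int = 24):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not (1 <= self.k <= X.shape[1]):
            raise ValueError(f"k must be in [1, {X.shape[1]}], got {self.k}")
        classes = np.unique(y)
        f_vals = np.empty(X.shape[1])
        p_vals = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            f_vals[j], p_vals[j] = anova_f([X[y == c, j] for c in classes])
        self.f_statistic_ = f_vals
        self.p_values_ = p_vals
        finite_max = np.nanmax(np.where(np.isinf(f_vals), np.nan, f_vals))
        self.normalized_scores_ = np.where(
            np.isinf(f_vals), 1.0, f_vals / finite_max if finite_max > 0 else 0.0
        )
        # stable ranking: descending F, index order breaks ties
        order = np.lexsort((np.arange(len(f_vals)), -f_vals))
        ranks = np.empty(len(f_vals), dtype=int)
        ranks[order] = np.arange(1, len(f_vals) + 1)
        self.ranks_ = ranks
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.ranks_ <= self.k
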