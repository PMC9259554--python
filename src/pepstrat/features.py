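"""Binarization of the peak matrix and discriminant feature ranking.

The binary discriminant analysis (BDA) path converts peak intensities
to presence/absence against a per-peak threshold and ranks peaks by
standardized deviations of the class presence frequencies from the
pooled frequency (t-scores).  A random-forest importance ranking is
provided as the alternative criterion.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .peaks import PeakMatrix

SIGNIFICANCE_T = 2.5  # |t| at the 95% significance convention


@dataclass
class BinaryMatrix:
    """Samples x peaks in {0,1} plus the per-bin thresholds that
    produced it (a cell is 1 iff intensity >= threshold)."""

    values: pd.DataFrame  # int 0/1, columns are bin reference masses
    thresholds: pd.Series
    rows: pd.DataFrame  # sample_id / replicate metadata, aligned

    def __post_init__(self) -> None:
        v = self.values.values
        if not np.isin(v, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")
        if not np.isfinite(self.thresholds.values).all():
            raise ValueError("thresholds must be finite")

    @property
    def bin_refs(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    def subset(self, bins) -> "BinaryMatrix":
        return BinaryMatrix(values=self.values.loc[:, list(bins)].copy(),
                            thresholds=self.thresholds.loc[list(bins)].copy(),
                            rows=self.rows.copy())

    def restrict_rows(self, row_ids) -> "BinaryMatrix":
        return BinaryMatrix(values=self.values.loc[list(row_ids)].copy(),
                            thresholds=self.thresholds.copy(),
                            rows=self.rows.loc[list(row_ids)].copy())


@dataclass
class FeatureRanking:
    """Per-peak discriminant scores.

    ``table`` is indexed by bin reference mass with one signed t-score
    column per class (``t_<group>``), an ``aggregate_score``, ``rank``
    (1 = best) and a ``significant`` flag (any class |t| >= 2.5; always
    False for importance-based rankings, which carry no t-scores).
    ``row_ids`` records the rows the ranking was computed on — the
    leakage guard for supervised evaluation.
    """

    table: pd.DataFrame
    method: str  # "bda" or "rf"
    row_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ranks = np.sort(self.table["rank"].values)
        if not np.array_equal(ranks, np.arange(1, len(self.table) + 1)):
            raise ValueError("ranks must be a permutation of 1..n_bins")

    def top_k(self, k: int) -> list[float]:
        return select_top_k(self, k)

    def save(self, path) -> None:
        self.table.to_csv(path, index_label="bin_ref")

    @classmethod
    def load(cls, path, method: str = "bda") -> "FeatureRanking":
        table = pd.read_csv(path, index_col="bin_ref")
        return cls(table=table, method=method)


# ---------------------------------------------------------------------------

def dichotomize(m: PeakMatrix, labels: pd.Series,
                mode: str = "pooled") -> BinaryMatrix:
    """Binarize each peak against its per-peak average intensity.

    ``mode='pooled'`` (default): threshold = mean over all rows.
    ``mode='class_mean_mixture'``: threshold = unweighted mean of the
    class means.  The cell is 1 when the intensity is equal or higher
    than the threshold.
    """
    labels = pd.Series(labels).reindex(m.values.index)
    if labels.isna().any():
        raise ValueError("every row needs a group label")
    if labels.nunique() < 2:
        raise ValueError("dichotomization needs >= 2 groups (a single group "
                         "degenerates the threshold to the class mean)")
    if mode == "pooled":
        thresholds = m.values.mean(axis=0)
    elif mode == "class_mean_mixture":
        thresholds = m.values.groupby(labels).mean().mean(axis=0)
    else:
        raise ValueError(f"unknown dichotomization mode: {mode!r}")
    values = (m.values >= thresholds).astype(int)
    return BinaryMatrix(values=values, thresholds=thresholds, rows=m.rows.copy())


def bda_tscores(b: BinaryMatrix, labels: pd.Series,
                significance: float = SIGNIFICANCE_T) -> FeatureRanking:
    """Binary discriminant t-scores: class presence frequency vs the
    pooled frequency.

    For bin j and group g with n_g of n rows, group frequency p_gj and
    pooled frequency p_j (shrunk into [eps, 1-eps], eps = 1/(2n)):

        t_gj = (p_gj - p_j) / sqrt( p_j (1 - p_j) (1/n_g - 1/n) )

    Positive t means the peak is over-present in that group.  Peaks are
    ranked by the aggregate score sum_g t_gj^2 (descending); a peak is
    significant when any class reaches |t| >= ``significance``.
    """
    labels = pd.Series(labels).reindex(b.values.index)
    if labels.isna().any():
        raise ValueError("every row needs a group label")
    counts = labels.value_counts()
    n = len(labels)
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"every group needs >= 2 samples; too small: {small}")
    if (counts == n).any():
        raise ValueError("need more than one group")

    eps = 1.0 / (2 * n)
    pooled = b.values.mean(axis=0).clip(eps, 1 - eps)
    groups = sorted(counts.index)
    t_cols = {}
    for g in groups:
        rows_g = b.values[labels == g]
        n_g = len(rows_g)
        p_g = rows_g.mean(axis=0)
        se = np.sqrt(pooled * (1 - pooled) * (1.0 / n_g - 1.0 / n))
        t_cols[f"t_{g}"] = (p_g - pooled) / se
    table = pd.DataFrame(t_cols, index=b.values.columns)
    table["aggregate_score"] = (table ** 2).sum(axis=1)
    # stable tie-break: equal aggregates rank in bin (mass) order
    order = np.argsort(-table["aggregate_score"].values, kind="stable")
    rank = np.empty(len(table), dtype=int)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    table["significant"] = (table[[f"t_{g}" for g in groups]].abs().max(axis=1)
                            >= significance)
    return FeatureRanking(table=table, method="bda",
                          row_ids=tuple(b.values.index))


def select_top_k(r: FeatureRanking, k: int) -> list[float]:
    """The k best-ranked bins, best first."""
    n = len(r.table)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    ordered = r.table.sort_values("rank").index[:k]
    return list(ordered)


def rf_importance_ranking(b: BinaryMatrix, labels: pd.Series, n_trees: int = 500,
                          seed: int = 0) -> FeatureRanking:
    """Rank peaks by impurity-decrease importance of a random forest
    trained on all given rows; deterministic given the seed."""
    labels = pd.Series(labels).reindex(b.values.index)
    if labels.isna().any():
        raise ValueError("every row needs a group label")
    if labels.nunique() < 2:
        raise ValueError("random-forest ranking needs >= 2 classes")
    forest = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                    random_state=seed)
    forest.fit(b.values.values, labels.values)
    table = pd.DataFrame({"aggregate_score": forest.feature_importances_},
                         index=b.values.columns)
    order = np.argsort(-table["aggregate_score"].values, kind="stable")
    rank = np.empty(len(table), dtype=int)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    table["significant"] = False
    return FeatureRanking(table=table, method="rf",
                          row_ids=tuple(b.values.index))
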