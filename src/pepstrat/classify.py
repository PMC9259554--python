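"""Supervised classification and cross-validated performance tables.

Implements the evaluation design of the study protocol: a stratified
60/40 sample-level split, feature ranking on the training rows only
(structurally enforced), repeated stratified k-fold cross-validation
inside the training set, a single held-out test pass, and five
performance metrics (accuracy, sensitivity, specificity, PPV, NPV)
computed on the confusion table collapsed to positive-vs-negative
classes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .features import (BinaryMatrix, FeatureRanking, bda_tscores,
                       rf_importance_ranking, select_top_k)
from .io import SampleManifest

logger = logging.getLogger("pepstrat")

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


# ---------------------------------------------------------------------------
# Train / test split
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Disjoint train/test sample-id sets produced by a stratified
    random split (both replicates of a sample stay on one side)."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int
    stratified: bool = True

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sample sets overlap")


def split_train_test(manifest: SampleManifest, train_frac: float,
                     seed: int) -> SplitSpec:
    """Stratified random sample-level split; deterministic given seed.
    Per-group train counts are the rounded group-size fraction, kept
    off 0 and n_g so neither side loses a class."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    groups = manifest.sample_groups()
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for g in sorted(groups.unique()):
        ids = sorted(groups.index[groups == g])
        if len(ids) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples to split")
        n_train = int(round(train_frac * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return SplitSpec(train_ids=tuple(sorted(train)),
                     test_ids=tuple(sorted(test)), seed=seed)


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

class BdaClassifier:
    """Bernoulli discriminant on binary peak features.

    Per class g and peak j the model stores the Laplace-smoothed
    presence frequency q_gj = (count_gj + 1) / (n_g + 2); a sample x is
    scored by

        score(g | x) = log pi_g + sum_j [ x_j log q_gj
                                          + (1 - x_j) log(1 - q_gj) ]

    with empirical priors pi_g, and classified to the argmax (ties go
    to the lexicographically first class label, logged).  The model is
    bound to the peak subset it was trained on.
    """

    def __init__(self) -> None:
        self.classes_: list[str] = []
        self.feature_names_: list = []
        self.log_prior_: np.ndarray | None = None
        self.freq_: np.ndarray | None = None  # classes x peaks

    def fit(self, X: pd.DataFrame, y) -> "BdaClassifier":
        y = pd.Series(np.asarray(y), index=X.index)
        self.classes_ = sorted(y.unique())
        if len(self.classes_) < 2:
            raise ValueError("training rows contain a single class")
        self.feature_names_ = list(X.columns)
        n = len(y)
        prior = np.array([(y == g).sum() / n for g in self.classes_])
        self.log_prior_ = np.log(prior)
        freq = np.vstack([
            (X[y == g].sum(axis=0).values + 1.0) / ((y == g).sum() + 2.0)
            for g in self.classes_])
        self.freq_ = freq
        return self

    def _scores(self, X: pd.DataFrame) -> np.ndarray:
        if self.freq_ is None:
            raise ValueError("classifier is not fitted")
        if list(X.columns) != self.feature_names_:
            raise ValueError("prediction input peak set differs from the "
                             "training peak set; the model is bound to its "
                             "peaks and thresholds")
        x = X.values.astype(float)
        log_q = np.log(self.freq_)
        log_1mq = np.log(1.0 - self.freq_)
        return self.log_prior_ + x @ log_q.T + (1.0 - x) @ log_1mq.T

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scores = self._scores(X)
        best = np.argmax(scores, axis=1)  # argmax takes the first maximum:
        ties = (scores == scores.max(axis=1, keepdims=True)).sum(axis=1) > 1
        if ties.any():  # lexicographically first class since classes_ sorted
            logger.debug("%d tied predictions resolved to the first class",
                         int(ties.sum()))
        return np.array([self.classes_[i] for i in best])


class RfClassifier:
    """Seeded random-forest wrapper (bagged trees, majority vote) on
    binary features; the ensemble itself is scikit-learn's."""

    def __init__(self, n_trees: int = 500, seed: int = 0) -> None:
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = n_trees
        self.seed = seed
        self.feature_names_: list = []
        self._forest: RandomForestClassifier | None = None

    def fit(self, X: pd.DataFrame, y) -> "RfClassifier":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training rows contain a single class")
        self.feature_names_ = list(X.columns)
        self._forest = RandomForestClassifier(
            n_estimators=self.n_trees, max_features="sqrt",
            random_state=self.seed)
        self._forest.fit(X.values, y)
        return self

    @property
    def feature_importances_(self) -> np.ndarray:
        if self._forest is None:
            raise ValueError("classifier is not fitted")
        return self._forest.feature_importances_

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self._forest is None:
            raise ValueError("classifier is not fitted")
        if list(X.columns) != self.feature_names_:
            raise ValueError("prediction input peak set differs from the "
                             "training peak set")
        return self._forest.predict(X.values)


def train_bda_classifier(b: BinaryMatrix, labels: pd.Series) -> BdaClassifier:
    labels = pd.Series(labels).reindex(b.values.index)
    return BdaClassifier().fit(b.values, labels)


def train_rf_classifier(b: BinaryMatrix, labels: pd.Series, n_trees: int = 500,
                        seed: int = 0) -> RfClassifier:
    labels = pd.Series(labels).reindex(b.values.index)
    return RfClassifier(n_trees=n_trees, seed=seed).fit(b.values, labels)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_table(y_true, y_pred, classes=None) -> pd.DataFrame:
    """Counts with truth on rows and prediction on columns."""
    y_true = pd.Series(np.asarray(y_true))
    y_pred = pd.Series(np.asarray(y_pred))
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    table = pd.crosstab(y_true, y_pred).reindex(index=classes, columns=classes,
                                                fill_value=0)
    table.index.name = "truth"
    table.columns.name = "predicted"
    return table


def _binary_counts(c: pd.DataFrame, positive_classes) -> tuple[int, int, int, int]:
    positive = [g for g in c.index if g in set(positive_classes)]
    negative = [g for g in c.index if g not in set(positive_classes)]
    tp = int(c.loc[positive, positive].values.sum())
    fn = int(c.loc[positive, negative].values.sum())
    fp = int(c.loc[negative, positive].values.sum())
    tn = int(c.loc[negative, negative].values.sum())
    return tp, fn, fp, tn


def _safe_pct(num: float, den: float) -> float:
    return round(100.0 * num / den, 1) if den > 0 else float("nan")


def compute_metrics(c: pd.DataFrame, positive_classes,
                    average: str = "collapse") -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV and NPV in percent
    (1-decimal rounding) from a confusion table.

    ``average='collapse'`` (default): the multi-class table is
    collapsed to positive (union of ``positive_classes``) vs negative
    before computing the ratios.  ``average='macro'``: one-vs-rest
    metrics per class, unweighted mean.  Undefined ratios (zero
    denominator) are reported as NaN, never as 0.
    """
    total = c.values.sum()
    if total <= 0:
        raise ValueError("empty confusion table")
    pos = set(positive_classes)
    if average == "collapse":
        if not pos or not pos & set(c.index) or pos >= set(c.index):
            raise ValueError("positive_classes must be a proper nonempty "
                             "subset of the observed classes")
        tp, fn, fp, tn = _binary_counts(c, pos)
        return {
            "accuracy": _safe_pct(tp + tn, total),
            "sensitivity": _safe_pct(tp, tp + fn),
            "specificity": _safe_pct(tn, tn + fp),
            "ppv": _safe_pct(tp, tp + fp),
            "npv": _safe_pct(tn, tn + fn),
        }
    if average == "macro":
        per_class = [compute_metrics(c, {g}, average="collapse")
                     for g in c.index]
        return {name: round(float(np.nanmean([m[name] for m in per_class])), 1)
                for name in METRIC_NAMES}
    raise ValueError(f"unknown averaging mode: {average!r}")


# ---------------------------------------------------------------------------
# Grid evaluation
# ---------------------------------------------------------------------------

def _check_no_leakage(ranking: FeatureRanking, test_ids) -> None:
    overlap = set(ranking.row_ids) & set(test_ids)
    if overlap:
        raise ValueError(
            f"feature ranking was computed on rows that overlap the test set "
            f"({sorted(overlap)[:5]}...); refusing to evaluate (leakage)")


def _rank(algorithm: str, b: BinaryMatrix, labels: pd.Series, n_trees: int,
          seed: int) -> FeatureRanking:
    if algorithm == "BDA":
        return bda_tscores(b, labels)
    if algorithm == "RF":
        return rf_importance_ranking(b, labels, n_trees=n_trees, seed=seed)
    raise ValueError(f"unknown algorithm: {algorithm!r}")


def _make_model(algorithm: str, n_trees: int, seed: int):
    return (BdaClassifier() if algorithm == "BDA"
            else RfClassifier(n_trees=n_trees, seed=seed))


def _cv_metrics(algorithm: str, X: pd.DataFrame, y: pd.Series, folds: int,
                repeats: int, positive_classes, n_trees: int,
                seed: int) -> dict[str, float]:
    """Repetition-pooled out-of-fold confusion -> metrics, averaged
    over repetitions.  Fold seeds derive from the master seed by fixed
    increments."""
    classes = sorted(y.unique())
    per_rep = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed + 1000 * rep)
        oof = pd.Series(index=y.index, dtype=object)
        for fold, (tr, te) in enumerate(skf.split(X.values, y.values)):
            model = _make_model(algorithm, n_trees, seed + 1000 * rep + fold)
            model.fit(X.iloc[tr], y.iloc[tr])
            oof.iloc[te] = model.predict(X.iloc[te])
        c = confusion_table(y.values, oof.values, classes=classes)
        per_rep.append(compute_metrics(c, positive_classes))
    return {name: round(float(np.nanmean([m[name] for m in per_rep])), 1)
            for name in METRIC_NAMES}


def evaluate_grid(b: BinaryMatrix, labels: pd.Series, split: SplitSpec,
                  algorithms=("BDA", "RF"), k_values=(5, 10, 15, 20),
                  cv_folds: int = 5, cv_repeats: int = 20, seed: int = 0,
                  n_trees: int = 500, positive_classes=("IS", "LPS"),
                  rankings: dict[str, FeatureRanking] | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate every (algorithm, top-k) combination.

    For each cell: rank peaks on the training rows with the
    algorithm's own ranker (or use the supplied ranking, refused if it
    saw any test row), select the top-k peaks, estimate CV-mean metrics
    by ``cv_folds`` x ``cv_repeats`` stratified CV inside the training
    set, refit on the full training set and score once on the held-out
    test set.  Returns (test_table, cv_table), one row per cell.
    """
    labels = pd.Series(labels).reindex(b.values.index)
    train_ids = [i for i in b.values.index if i in set(split.train_ids)]
    test_ids = [i for i in b.values.index if i in set(split.test_ids)]
    if not train_ids or not test_ids:
        raise ValueError("split does not match the matrix rows")
    b_train = b.restrict_rows(train_ids)
    y_train = labels.loc[train_ids]
    y_test = labels.loc[test_ids]
    classes = sorted(labels.unique())

    test_rows = []
    cv_rows = []
    for alg in algorithms:
        if rankings is not None and alg in rankings:
            ranking = rankings[alg]
            _check_no_leakage(ranking, split.test_ids)
        else:
            ranking = _rank(alg, b_train, y_train, n_trees, seed)
            _check_no_leakage(ranking, split.test_ids)
        for k in k_values:
            bins = select_top_k(ranking, k)
            X_train = b_train.values.loc[:, bins]
            X_test = b.values.loc[test_ids, bins]
            cv = _cv_metrics(alg, X_train, y_train, cv_folds, cv_repeats,
                             positive_classes, n_trees, seed)
            cv_rows.append({"algorithm": alg, "top_k": k, **cv})
            model = _make_model(alg, n_trees, seed)
            model.fit(X_train, y_train)
            pred = model.predict(X_test)
            c = confusion_table(y_test.values, pred, classes=classes)
            test = compute_metrics(c, positive_classes)
            test_rows.append({"algorithm": alg, "top_k": k, **test})
    return pd.DataFrame(test_rows), pd.DataFrame(cv_rows)
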