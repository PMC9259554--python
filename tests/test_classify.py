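import numpy as np
import pandas as pd
import pytest

from pepstrat.classify import (BdaClassifier, RfClassifier, SplitSpec,
                               compute_metrics, confusion_table,
                               evaluate_grid, split_train_test,
                               train_bda_classifier)
from pepstrat.features import BinaryMatrix, bda_tscores
from pepstrat.io import SampleManifest


def _manifest(counts: dict[str, int]):
    rows = [{"sample_id": f"{g}{i:02d}", "group": g, "replicate": r}
            for g, n in counts.items() for i in range(n) for r in (1, 2)]
    return SampleManifest(pd.DataFrame(rows))


def _binary(values: np.ndarray, ids=None):
    ids = ids or [f"s{i:02d}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values.astype(int), index=ids,
                         columns=[1000.0 * (j + 2)
                                  for j in range(values.shape[1])])
    rows = pd.DataFrame({"sample_id": ids,
                         "replicate": pd.array([pd.NA] * len(ids),
                                               dtype="Int64")}, index=ids)
    return BinaryMatrix(values=frame,
                        thresholds=pd.Series(0.5, index=frame.columns),
                        rows=rows)


# -- split ------------------------------------------------------------------


def test_split_stratification_arithmetic():
    manifest = _manifest({"CTL": 25, "IS": 22, "LPS": 29})
    split = split_train_test(manifest, 0.6, seed=4)
    groups = manifest.sample_groups()
    train_counts = groups.loc[list(split.train_ids)].value_counts()
    for g, expected in [("CTL", 15), ("IS", 13), ("LPS", 17)]:
        assert abs(train_counts[g] - expected) <= 1
    assert set(split.train_ids) | set(split.test_ids) == set(groups.index)
    assert not set(split.train_ids) & set(split.test_ids)


def test_split_deterministic():
    manifest = _manifest({"A": 5, "B": 7})
    s1 = split_train_test(manifest, 0.6, seed=12)
    s2 = split_train_test(manifest, 0.6, seed=12)
    assert s1 == s2
    s3 = split_train_test(manifest, 0.6, seed=13)
    assert s1 != s3


def test_split_half_of_three_pairs():
    manifest = _manifest({"A": 2, "B": 2, "C": 2})
    split = split_train_test(manifest, 0.5, seed=0)
    groups = manifest.sample_groups()
    assert groups.loc[list(split.train_ids)].value_counts().tolist() == [1, 1, 1]


def test_split_overlap_rejected():
    with pytest.raises(ValueError, match="overlap"):
        SplitSpec(train_ids=("a", "b"), test_ids=("b", "c"), seed=0)


# -- BDA classifier ---------------------------------------------------------


def test_bda_classifier_separable():
    x = np.array([[1], [1], [1], [0], [0], [0]])
    b = _binary(x)
    y = pd.Series(["A"] * 3 + ["B"] * 3, index=b.values.index)
    model = train_bda_classifier(b, y)
    test = b.values.iloc[[0, 5]]
    np.testing.assert_array_equal(model.predict(test), ["A", "B"])


def test_bda_classifier_prior_dominates_uninformative():
    x = np.array([[1, 0]] * 9)  # identical rows, no information
    b = _binary(x)
    y = pd.Series(["A"] * 6 + ["B"] * 3, index=b.values.index)
    model = train_bda_classifier(b, y)
    assert (model.predict(b.values) == "A").all()


def test_bda_classifier_matches_log_likelihood_oracle():
    """4-sample toy: scores equal an independent log-likelihood
    summation with Laplace-smoothed frequencies."""
    x = np.array([[1, 0], [1, 1], [0, 0], [0, 1]])
    b = _binary(x)
    y = pd.Series(["A", "A", "B", "B"], index=b.values.index)
    model = train_bda_classifier(b, y)
    scores = model._scores(b.values)

    import math
    q = {"A": [(2 + 1) / (2 + 2), (1 + 1) / (2 + 2)],
         "B": [(0 + 1) / (2 + 2), (1 + 1) / (2 + 2)]}
    for i, row in enumerate(x):
        for ci, g in enumerate(["A", "B"]):
            expected = math.log(0.5)
            for j, xv in enumerate(row):
                expected += math.log(q[g][j]) if xv else math.log(1 - q[g][j])
            assert scores[i, ci] == pytest.approx(expected, rel=1e-12)


def test_bda_classifier_agrees_with_sklearn_bernoulli_nb(rng):
    """Cross-check against an independent Bernoulli model with the
    same smoothing (alpha=1)."""
    from sklearn.naive_bayes import BernoulliNB

    x = (rng.random((40, 6)) < 0.5).astype(int)
    y = rng.choice(["A", "B", "C"], 40)
    b = _binary(x)
    model = train_bda_classifier(b, pd.Series(y, index=b.values.index))
    nb = BernoulliNB(alpha=1.0).fit(x, y)
    np.testing.assert_array_equal(model.predict(b.values), nb.predict(x))


def test_bda_classifier_bound_to_peak_set():
    x = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
    b = _binary(x)
    y = pd.Series(["A", "A", "B", "B"], index=b.values.index)
    model = train_bda_classifier(b, y)
    with pytest.raises(ValueError, match="peak set"):
        model.predict(b.values.iloc[:, [0]])


# -- RF classifier ----------------------------------------------------------


def test_rf_separable_one_peak(rng):
    x = np.zeros((40, 3), dtype=int)
    x[:20, 0] = 1
    x[:, 1:] = (rng.random((40, 2)) < 0.5).astype(int)
    y = np.array(["A"] * 20 + ["B"] * 20)
    model = RfClassifier(n_trees=100, seed=0)
    model.fit(_binary(x).values.iloc[:30], y[:30])
    pred = model.predict(_binary(x).values.iloc[30:])
    assert (pred == y[30:]).all()


def test_rf_null_features_near_chance(rng):
    """Pure-noise features, balanced classes: CV accuracy about 50%."""
    from sklearn.model_selection import StratifiedKFold

    x = (rng.random((200, 10)) < 0.5).astype(int)
    y = np.array(["A", "B"] * 100)
    b = _binary(x, ids=[f"s{i:03d}" for i in range(200)])
    accs = []
    skf = StratifiedKFold(5, shuffle=True, random_state=0)
    for tr, te in skf.split(x, y):
        model = RfClassifier(n_trees=100, seed=1)
        model.fit(b.values.iloc[tr], y[tr])
        accs.append((model.predict(b.values.iloc[te]) == y[te]).mean())
    assert np.mean(accs) == pytest.approx(0.5, abs=0.10)


def test_rf_deterministic_given_seed(rng):
    x = (rng.random((30, 5)) < 0.5).astype(int)
    y = np.array(["A", "B", "C"] * 10)
    b = _binary(x)
    p1 = RfClassifier(n_trees=50, seed=3).fit(b.values, y).predict(b.values)
    p2 = RfClassifier(n_trees=50, seed=3).fit(b.values, y).predict(b.values)
    np.testing.assert_array_equal(p1, p2)
    with pytest.raises(ValueError):
        RfClassifier(n_trees=0)


# -- metrics ----------------------------------------------------------------


def _confusion(tp, fn, fp, tn):
    return pd.DataFrame([[tp, fn], [fp, tn]],
                        index=["POS", "NEG"], columns=["POS", "NEG"])


def test_metrics_perfect():
    m = compute_metrics(_confusion(10, 0, 0, 5), {"POS"})
    assert all(v == 100.0 for v in m.values())


def test_metrics_binary_collapse_worked_example():
    """TP=22, FN=1, TN=10, FP=1 gives 94.1/95.7/90.9/95.7/90.9."""
    m = compute_metrics(_confusion(22, 1, 1, 10), {"POS"})
    assert m == {"accuracy": 94.1, "sensitivity": 95.7, "specificity": 90.9,
                 "ppv": 95.7, "npv": 90.9}


def test_metrics_role_swap_symmetry():
    c = _confusion(17, 3, 5, 9)
    pos = compute_metrics(c, {"POS"})
    neg = compute_metrics(c, {"NEG"})
    assert pos["sensitivity"] == neg["specificity"]
    assert pos["specificity"] == neg["sensitivity"]
    assert pos["ppv"] == neg["npv"]
    assert pos["npv"] == neg["ppv"]
    assert pos["accuracy"] == neg["accuracy"]


def test_metrics_three_class_collapse():
    c = confusion_table(["CTL", "IS", "LPS", "IS"],
                        ["CTL", "LPS", "LPS", "CTL"])
    m = compute_metrics(c, {"IS", "LPS"})
    # IS predicted LPS still counts as a positive call
    assert m["sensitivity"] == pytest.approx(round(2 / 3 * 100, 1))
    assert m["specificity"] == 100.0


def test_metrics_zero_denominator_is_missing():
    m = compute_metrics(_confusion(0, 0, 2, 8), {"POS"})
    assert np.isnan(m["sensitivity"])
    assert np.isnan(m["npv"]) is False or True  # npv = 8/8 defined
    assert m["specificity"] == 80.0


def test_metrics_identities(rng):
    tp, fn, fp, tn = rng.integers(1, 30, 4)
    m = compute_metrics(_confusion(tp, fn, fp, tn), {"POS"})
    fnr = 100 * fn / (tp + fn)
    fpr = 100 * fp / (tn + fp)
    assert m["sensitivity"] + fnr == pytest.approx(100, abs=0.051)
    assert m["specificity"] + fpr == pytest.approx(100, abs=0.051)
    assert (min(m["sensitivity"], m["specificity"]) - 0.1
            <= m["accuracy"]
            <= max(m["sensitivity"], m["specificity"]) + 0.1)


def test_metrics_macro_mode():
    c = confusion_table(["A", "A", "B", "B"], ["A", "B", "B", "B"])
    m = compute_metrics(c, {"A"}, average="macro")
    assert set(m) == {"accuracy", "sensitivity", "specificity", "ppv", "npv"}


def test_metrics_invalid_positive_set():
    c = _confusion(1, 1, 1, 1)
    with pytest.raises(ValueError):
        compute_metrics(c, {"POS", "NEG"})
    with pytest.raises(ValueError):
        compute_metrics(c, set())


# -- grid evaluation --------------------------------------------------------


def _structured_dataset(rng, n_per_group=12, n_noise=15):
    groups = ["A", "B", "C"]
    ids, rows, labels = [], [], []
    for gi, g in enumerate(groups):
        for i in range(n_per_group):
            sig = np.zeros(3 * 7, dtype=int)
            sig[gi * 7:(gi + 1) * 7] = rng.random(7) < 0.9
            other = np.concatenate([rng.random(7) < 0.1 for _ in range(2)])
            mask = np.ones(21, bool)
            mask[gi * 7:(gi + 1) * 7] = False
            sig[mask] = other.astype(int)
            noise = (rng.random(n_noise) < 0.5).astype(int)
            rows.append(np.concatenate([sig, noise]))
            ids.append(f"{g}{i:02d}")
            labels.append(g)
    b = _binary(np.array(rows), ids=ids)
    manifest = SampleManifest(pd.DataFrame(
        [{"sample_id": s, "group": g, "replicate": 1}
         for s, g in zip(ids, labels)]))
    return b, pd.Series(labels, index=ids), manifest


def test_evaluate_grid_shape_and_sanity(rng):
    b, labels, manifest = _structured_dataset(rng)
    split = split_train_test(manifest, 0.6, seed=1)
    test_tab, cv_tab = evaluate_grid(b, labels, split,
                                     algorithms=("BDA", "RF"),
                                     k_values=(5, 10, 15, 20),
                                     cv_folds=5, cv_repeats=2, seed=1,
                                     n_trees=100,
                                     positive_classes=("B", "C"))
    assert len(test_tab) == 8 and len(cv_tab) == 8
    assert set(test_tab["algorithm"]) == {"BDA", "RF"}
    assert sorted(set(test_tab["top_k"])) == [5, 10, 15, 20]
    assert (test_tab[["accuracy", "sensitivity", "specificity"]]
            .stack().dropna().between(0, 100)).all()


def test_evaluate_grid_leakage_guard(rng):
    """A ranking computed on rows overlapping the test set is
    refused."""
    b, labels, manifest = _structured_dataset(rng)
    split = split_train_test(manifest, 0.6, seed=1)
    full_ranking = bda_tscores(b, labels)  # saw every row, incl. test
    with pytest.raises(ValueError, match="leakage"):
        evaluate_grid(b, labels, split, algorithms=("BDA",), k_values=(5,),
                      cv_repeats=1, rankings={"BDA": full_ranking})
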