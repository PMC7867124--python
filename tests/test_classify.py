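"""Splitting, KNN vs brute-force distances, batch SOM, evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

from awear.classify import (
    BatchSOM,
    KnnClassifier,
    SplitSpec,
    evaluate,
    knn_fit_predict,
    som_fit,
    som_predict,
    stratified_holdout_split,
)


def _table(X, y):
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
    df.insert(0, "class_label", y)
    df.insert(0, "subject_id", [f"s{i}" for i in range(len(y))])
    return df


def _clusters(rng, centers, n_per, sd=0.5):
    X, y = [], []
    for label, c in centers.items():
        X.append(rng.normal(c, sd, size=(n_per, len(c))))
        y += [label] * n_per
    return np.vstack(X), np.array(y)


# --------------------------------------------------------------- split


def test_split_counts_20_10_10():
    rng = np.random.default_rng(0)
    X, y = _clusters(
        rng,
        {"healthy": [0, 0], "tremor": [5, 5], "bradykinesia": [-5, 5]},
        20,
    )
    table = _table(X[:40], np.array(["healthy"] * 20 + ["tremor"] * 10 + ["bradykinesia"] * 10))
    train, test = stratified_holdout_split(table, SplitSpec(seed=3))
    assert len(test) == 12 and len(train) == 28
    counts = test["class_label"].value_counts()
    assert counts["healthy"] == 6 and counts["tremor"] == 3 and counts["bradykinesia"] == 3
    assert set(train["subject_id"]).isdisjoint(test["subject_id"])
    assert len(train) + len(test) == 40


def test_split_half_of_444():
    y = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    table = _table(np.zeros((12, 2)), y)
    train, test = stratified_holdout_split(table, SplitSpec(holdout_fraction=0.5, seed=0))
    assert test["class_label"].value_counts().tolist() == [2, 2, 2]


def test_split_determinism_and_errors():
    y = np.array(["a"] * 4 + ["b"] * 4)
    table = _table(np.arange(16).reshape(8, 2), y)
    s = SplitSpec(seed=9)
    t1 = stratified_holdout_split(table, s)
    t2 = stratified_holdout_split(table, s)
    assert t1[1]["subject_id"].tolist() == t2[1]["subject_id"].tolist()
    with pytest.raises(ValueError):
        stratified_holdout_split(_table(np.zeros((3, 1)), np.array(["a", "a", "b"])), s)
    with pytest.raises(ValueError):
        SplitSpec(holdout_fraction=1.5).validate()


# ---------------------------------------------------------------- KNN


def test_knn_exact_match_k1():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
    y = np.array(["a", "b", "a", "b"])
    model = KnnClassifier(n_neighbors=1).fit(X, y)
    assert model.predict(X[[1]])[0] == "b"


def test_knn_separated_clusters_perfect():
    rng = np.random.default_rng(1)
    X, y = _clusters(
        rng, {"a": [0, 0, 0], "b": [10, 0, 0], "c": [0, 10, 0]}, 15, sd=1.0
    )
    table = _table(X, y)
    train, test = stratified_holdout_split(table, SplitSpec(seed=0))
    preds, scores = knn_fit_predict(train, test, k=10)
    assert (preds == test["class_label"].to_numpy()).all()
    assert np.allclose(scores.sum(axis=1), 1.0)


def test_knn_matches_bruteforce_oracle():
    """Majority label among the k nearest z-scored points, by exhaustive
    distance computation, on a 12-point 2-D fixture."""
    X = np.array(
        [
            [0.0, 0.0], [0.5, 0.2], [0.1, -0.3], [0.4, 0.5],
            [5.0, 5.0], [5.5, 4.8], [4.9, 5.3], [5.2, 5.1],
            [0.0, 5.0], [0.3, 5.2], [-0.2, 4.9], [0.1, 5.4],
        ]
    )
    y = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    queries = np.array([[0.2, 0.1], [5.1, 5.0], [0.0, 5.1], [2.5, 2.5]])
    k = 3
    model = KnnClassifier(n_neighbors=k).fit(X, y)
    # oracle: standardize with training mean/sd, full distance matrix
    mu, sd = X.mean(0), X.std(0, ddof=1)
    Z, Q = (X - mu) / sd, (queries - mu) / sd
    for qi in range(len(Q)):
        d = np.sqrt(((Z - Q[qi]) ** 2).sum(1))
        nearest = np.argsort(d, kind="stable")[:k]
        votes, counts = np.unique(y[nearest], return_counts=True)
        best = votes[counts == counts.max()]
        if len(best) > 1:  # tie: nearest neighbor decides
            expected = next(l for l in y[nearest] if l in best)
        else:
            expected = best[0]
        assert model.predict(queries[[qi]])[0] == expected


def test_knn_errors_and_zero_variance():
    X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 3.0]])
    y = np.array(["a", "a", "b", "b"])
    with pytest.raises(ValueError):
        KnnClassifier(n_neighbors=5).fit(X, y)
    with pytest.warns(UserWarning):
        model = KnnClassifier(n_neighbors=1).fit(X, y)  # first column constant
    assert model.predict(np.array([[1.0, 2.9]]))[0] == "b"


# ---------------------------------------------------------------- SOM


def test_som_separated_clusters_pure():
    rng = np.random.default_rng(2)
    X, y = _clusters(
        rng, {"a": [0, 0], "b": [10, 0], "c": [0, 10]}, 12, sd=0.8
    )
    table = _table(X, y)
    som = som_fit(table, seed=0)
    preds = som_predict(som, table)
    assert (preds == y).all()
    assert sorted(som.sample_hits_.tolist()) == [12, 12, 12]


def test_som_determinism_and_mse_decrease():
    rng = np.random.default_rng(3)
    X, y = _clusters(rng, {"a": [0, 0], "b": [6, 0], "c": [0, 6]}, 10)
    s1 = BatchSOM(random_state=5).fit(X)
    s2 = BatchSOM(random_state=5).fit(X)
    assert np.array_equal(s1.weights_, s2.weights_)
    assert s1.mse_history_[-1] <= s1.mse_history_[0]
    # once the neighborhood has shrunk the updates are k-means-like and the
    # quantization error is monotone non-increasing
    tail = s1.mse_history_[len(s1.mse_history_) // 2 :]
    assert np.all(np.diff(tail) <= 1e-12)


def test_som_all_identical_samples():
    X = np.ones((8, 3))
    som = BatchSOM(n_neurons=3, random_state=0, standardize=False).fit(X)
    assert som.mse_ == pytest.approx(0.0, abs=1e-20)
    assert np.allclose(som.weights_, 1.0)


def test_som_empty_neuron_inherits_nearest_label():
    # two tight clusters, three neurons: one neuron may end up empty
    X = np.vstack([np.zeros((5, 2)), np.full((5, 2), 10.0)])
    X = X + np.random.default_rng(0).normal(0, 0.01, X.shape)
    y = np.array(["a"] * 5 + ["b"] * 5)
    som = BatchSOM(n_neurons=3, random_state=1).fit(X)
    if (som.sample_hits_ == 0).any():
        with pytest.warns(UserWarning):
            som.assign_labels(y)
    else:
        som.assign_labels(y)
    assert set(som.neuron_labels_) <= {"a", "b"}
    assert (som.predict(X) == y).all()


# ----------------------------------------------------------- evaluation


def test_evaluate_all_correct():
    y = np.array(["healthy"] * 4 + ["tremor"] * 3 + ["bradykinesia"] * 3)
    rep = evaluate(y, y)
    assert rep.accuracy == 1.0
    for c in rep.classes:
        assert rep.sensitivity[c] == 1.0 and rep.specificity[c] == 1.0
        assert rep.ppv[c] + rep.fdr[c] == pytest.approx(1.0)


def test_evaluate_identities_random_labels():
    rng = np.random.default_rng(6)
    classes = ("healthy", "tremor", "bradykinesia")
    y_true = np.array(list(classes) * 5)
    y_pred = rng.choice(classes, size=15)
    rep = evaluate(y_true, y_pred)
    cm = rep.confusion_matrix
    assert cm.sum() == 15
    assert rep.accuracy == pytest.approx(np.trace(cm) / cm.sum())
    for i, c in enumerate(classes):
        assert cm[i].sum() == 5  # row sums = per-class counts
        if cm[:, i].sum() > 0:
            assert rep.ppv[c] + rep.fdr[c] == pytest.approx(1.0)
        assert rep.tpr[c] + rep.fnr[c] == pytest.approx(1.0)


def test_evaluate_unseen_label_rejected():
    with pytest.raises(ValueError):
        evaluate(["healthy", "tremor"], ["healthy", "dyskinesia"],
                 classes=("healthy", "tremor"))


def test_roc_monotone_and_anchored():
    rng = np.random.default_rng(7)
    X, y = _clusters(rng, {"a": [0, 0], "b": [3, 0], "c": [0, 3]}, 12, sd=1.5)
    table = _table(X, y)
    train, test = stratified_holdout_split(table, SplitSpec(seed=1))
    preds, scores = knn_fit_predict(train, test, k=5)
    rep = evaluate(test["class_label"].to_numpy(), preds, scores)
    assert rep.roc_points
    for pts in rep.roc_points.values():
        arr = np.asarray(pts)
        assert np.all(np.diff(arr[:, 0]) >= 0)
        assert np.all(np.diff(arr[:, 1]) >= 0)
        assert tuple(arr[0]) == (0.0, 0.0) and tuple(arr[-1]) == (1.0, 1.0)
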