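"""KNN and batch-SOM classification with the full evaluation surface.

Supervised route: a 30% stratified hold-out split, per-feature z-scoring
learned on the training split only, and k-nearest-neighbor majority vote
(k=10, Euclidean distance) with the single nearest neighbor breaking vote
ties. Per-class vote fractions feed one-vs-rest ROC curves.

Unsupervised route: a 1x3 batch self-organizing map (three neurons, one per
expected class). Each epoch assigns every sample to its best-matching
neuron, then moves each neuron to the neighborhood-weighted mean of the
assigned samples while the Gaussian neighborhood radius decays linearly to
zero; performance is tracked as the mean squared quantization error.
Training labels are used only afterwards, to name each neuron by the
majority class of its samples.

Evaluation reports the 3x3 confusion matrix (rows = true class), accuracy,
per-predicted-class PPV/FDR, per-true-class TPR/FNR, one-vs-rest
sensitivity/specificity, and per-class ROC points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.neighbors import NearestNeighbors

from .synth import CLASSES

__all__ = [
    "SplitSpec",
    "stratified_holdout_split",
    "KnnClassifier",
    "knn_fit_predict",
    "BatchSOM",
    "som_fit",
    "som_predict",
    "EvalReport",
    "evaluate",
]

_META_COLS = ("subject_id", "class_label")


def _feature_matrix(table: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    feats = [c for c in table.columns if c not in _META_COLS]
    X = table[feats].to_numpy(dtype=float)
    y = table["class_label"].to_numpy()
    return X, y, feats


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Hold-out split specification (default: stratified 30% test)."""

    holdout_fraction: float = 0.30
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.holdout_fraction < 1):
            raise ValueError("holdout_fraction must be in (0, 1)")


def stratified_holdout_split(
    table: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test split of a feature table.

    Stratified mode draws round(class size x holdout_fraction) test samples
    per class (a 20/10/10 cohort at 0.30 gives a 6/3/3 test set).
    Reproducible under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = len(table)
    if spec.stratified:
        test_idx: List[int] = []
        for label, grp in table.groupby("class_label", sort=True):
            size = len(grp)
            if size < 2:
                raise ValueError(f"class {label!r} too small to split ({size} sample)")
            n_test = int(round(size * spec.holdout_fraction))
            n_test = min(max(n_test, 1), size - 1)
            pos = rng.permutation(size)[:n_test]
            test_idx.extend(np.asarray(grp.index)[pos])
    else:
        if n < 2:
            raise ValueError("table too small to split")
        n_test = min(max(int(round(n * spec.holdout_fraction)), 1), n - 1)
        test_idx = list(np.asarray(table.index)[rng.permutation(n)[:n_test]])
    mask = table.index.isin(test_idx)
    return table.loc[~mask].copy(), table.loc[mask].copy()


# --------------------------------------------------------------------------
# KNN
# --------------------------------------------------------------------------


class KnnClassifier(BaseEstimator, ClassifierMixin):
    """K-nearest-neighbor classifier on z-scored features.

    Standardization parameters are learned on the training data only.
    Features with zero training SD are dropped with a warning. Vote ties are
    broken by the class of the single nearest neighbor. ``predict_proba``
    returns the neighbor vote fractions (multiples of 1/k), which drive the
    ROC curves.
    """

    def __init__(self, n_neighbors: int = 10):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if self.n_neighbors < 1 or self.n_neighbors > len(X):
            raise ValueError(
                f"n_neighbors must be in [1, {len(X)}], got {self.n_neighbors}"
            )
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1) if len(X) > 1 else np.ones(X.shape[1])
        keep = sds > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s)")
        if not keep.any():
            raise ValueError("all features have zero training variance")
        self.feature_mask_ = keep
        self.means_ = means[keep]
        self.scales_ = sds[keep]
        self.classes_ = np.unique(y)
        self._X = (X[:, keep] - self.means_) / self.scales_
        self._y = y
        self._nn = NearestNeighbors(metric="euclidean").fit(self._X)
        return self

    def _standardize(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X[:, self.feature_mask_] - self.means_) / self.scales_

    def _votes(self, X) -> Tuple[np.ndarray, np.ndarray]:
        Z = self._standardize(X)
        dist, idx = self._nn.kneighbors(Z, n_neighbors=self.n_neighbors)
        neigh_labels = self._y[idx]
        counts = np.stack(
            [(neigh_labels == c).sum(axis=1) for c in self.classes_], axis=1
        )
        return counts, neigh_labels

    def predict(self, X) -> np.ndarray:
        counts, neigh_labels = self._votes(X)
        winners = []
        for i in range(len(counts)):
            best = counts[i].max()
            tied = self.classes_[counts[i] == best]
            if len(tied) == 1:
                winners.append(tied[0])
            else:
                # tie-break: walk neighbors in distance order, first tied class
                pick = next(l for l in neigh_labels[i] if l in tied)
                winners.append(pick)
        return np.asarray(winners)

    def predict_proba(self, X) -> np.ndarray:
        counts, _ = self._votes(X)
        return counts / self.n_neighbors


def knn_fit_predict(
    train: pd.DataFrame,
    test: pd.DataFrame,
    k: int = 10,
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Fit KNN on a training feature table, predict the test table.

    Returns (predicted labels, per-class vote-fraction DataFrame).
    """
    X_train, y_train, feats = _feature_matrix(train)
    X_test = test[feats].to_numpy(dtype=float)
    model = KnnClassifier(n_neighbors=k).fit(X_train, y_train)
    preds = model.predict(X_test)
    scores = pd.DataFrame(model.predict_proba(X_test), columns=model.classes_,
                          index=test.index)
    return preds, scores


# --------------------------------------------------------------------------
# batch SOM
# --------------------------------------------------------------------------


class BatchSOM(BaseEstimator, ClusterMixin):
    """1-D batch self-organizing map (default three neurons in a row).

    Weight initialization samples data points k-means++ style under
    ``random_state``. The Gaussian neighborhood radius decays linearly from
    ``sigma0`` to (effectively) zero over ``n_epochs``, so late epochs
    reduce to batch k-means updates. ``standardize=True`` (default) z-scores
    the inputs with parameters learned in ``fit``.

    Fitted attributes: ``weights_`` (n_neurons x n_features),
    ``mse_`` (mean squared quantization error), ``mse_history_``,
    ``labels_`` (BMU index per training sample), ``sample_hits_`` and —
    after :meth:`assign_labels` — ``neuron_labels_``.
    """

    def __init__(
        self,
        n_neurons: int = 3,
        n_epochs: int = 200,
        sigma0: float = 1.0,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.n_neurons = n_neurons
        self.n_epochs = n_epochs
        self.sigma0 = sigma0
        self.standardize = standardize
        self.random_state = random_state

    # grid geometry: neurons on a line, unit spacing (for a 1x3 map the
    # hexagonal and rectangular topologies coincide)
    def _grid_dist2(self) -> np.ndarray:
        pos = np.arange(self.n_neurons, dtype=float)
        return (pos[:, None] - pos[None, :]) ** 2

    def _init_weights(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n = len(X)
        first = rng.integers(n)
        chosen = [first]
        for _ in range(1, self.n_neurons):
            d2 = np.min(
                ((X[:, None, :] - X[chosen][None, :, :]) ** 2).sum(-1), axis=1
            )
            total = d2.sum()
            if total == 0:
                chosen.append(int(rng.integers(n)))
            else:
                chosen.append(int(rng.choice(n, p=d2 / total)))
        return X[chosen].copy()

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) < self.n_neurons:
            raise ValueError(f"need >= {self.n_neurons} samples")
        if self.standardize:
            self._mean = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1) if len(X) > 1 else np.ones(X.shape[1])
            self._sd = np.where(sd > 0, sd, 1.0)
        else:
            self._mean = np.zeros(X.shape[1])
            self._sd = np.ones(X.shape[1])
        Z = (X - self._mean) / self._sd
        rng = np.random.default_rng(self.random_state)
        W = self._init_weights(Z, rng)
        grid_d2 = self._grid_dist2()
        history = []
        bmu = None
        for epoch in range(self.n_epochs):
            d2 = ((Z[:, None, :] - W[None, :, :]) ** 2).sum(-1)
            bmu = np.argmin(d2, axis=1)
            history.append(float(d2[np.arange(len(Z)), bmu].mean()))
            sigma = max(self.sigma0 * (1.0 - epoch / max(self.n_epochs - 1, 1)), 1e-3)
            h = np.exp(-grid_d2 / (2.0 * sigma**2))  # n_neurons x n_neurons
            # neighborhood-weighted batch update
            weights = h[:, bmu]  # n_neurons x n_samples
            denom = weights.sum(axis=1)
            numer = weights @ Z
            nonzero = denom > 0
            W[nonzero] = numer[nonzero] / denom[nonzero, None]
        d2 = ((Z[:, None, :] - W[None, :, :]) ** 2).sum(-1)
        self.labels_ = np.argmin(d2, axis=1)
        self.mse_ = float(d2[np.arange(len(Z)), self.labels_].mean())
        history.append(self.mse_)
        self.mse_history_ = np.asarray(history)
        self.weights_ = W
        self.sample_hits_ = np.bincount(self.labels_, minlength=self.n_neurons)
        return self

    def _bmu(self, X) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self._mean) / self._sd
        d2 = ((Z[:, None, :] - self.weights_[None, :, :]) ** 2).sum(-1)
        return np.argmin(d2, axis=1)

    def assign_labels(self, y: Sequence) -> np.ndarray:
        """Name each neuron by the majority true class of its samples.

        Labels are used only here, to name clusters — never during fitting.
        An empty neuron inherits the label of the nearest labeled neuron
        (with a warning).
        """
        y = np.asarray(y)
        if len(y) != len(self.labels_):
            raise ValueError("labels length != training-sample count")
        neuron_labels: List[Optional[str]] = [None] * self.n_neurons
        for j in range(self.n_neurons):
            members = y[self.labels_ == j]
            if len(members):
                vals, counts = np.unique(members, return_counts=True)
                neuron_labels[j] = vals[np.argmax(counts)]
        empty = [j for j, lab in enumerate(neuron_labels) if lab is None]
        for j in empty:
            warnings.warn(f"neuron {j} captured no samples; labeling by nearest neuron")
            others = [i for i in range(self.n_neurons) if neuron_labels[i] is not None]
            if not others:
                raise ValueError("no neuron captured any sample")
            dists = ((self.weights_[j] - self.weights_[others]) ** 2).sum(-1)
            neuron_labels[j] = neuron_labels[others[int(np.argmin(dists))]]
        self.neuron_labels_ = np.asarray(neuron_labels)
        return self.neuron_labels_

    def predict(self, X) -> np.ndarray:
        """Class label of each sample's best-matching neuron."""
        if not hasattr(self, "neuron_labels_"):
            raise ValueError("call assign_labels() before predict()")
        return self.neuron_labels_[self._bmu(X)]


def som_fit(
    table: pd.DataFrame,
    n_neurons: int = 3,
    n_epochs: int = 200,
    seed: int = 0,
) -> BatchSOM:
    """Fit the batch SOM on a feature table and name neurons by class."""
    X, y, _ = _feature_matrix(table)
    som = BatchSOM(n_neurons=n_neurons, n_epochs=n_epochs, random_state=seed).fit(X)
    som.assign_labels(y)
    return som


def som_predict(som: BatchSOM, table: pd.DataFrame) -> np.ndarray:
    X, _, _ = _feature_matrix(table)
    return som.predict(X)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Confusion matrix plus the derived per-class and overall metrics.

    Rows of ``confusion_matrix`` are true classes, columns predicted, in
    ``classes`` order. ``ppv``/``fdr`` are per predicted class (column-wise),
    ``tpr``/``fnr`` per true class (row-wise); ``sensitivity`` is ``tpr`` and
    ``specificity``/``fpr`` are one-vs-rest. ``roc_points`` maps a class to
    its (FPR, TPR) curve when scores were provided.
    """

    classes: Tuple[str, ...]
    confusion_matrix: np.ndarray
    accuracy: float
    ppv: Dict[str, float]
    fdr: Dict[str, float]
    tpr: Dict[str, float]
    fnr: Dict[str, float]
    sensitivity: Dict[str, float]
    specificity: Dict[str, float]
    fpr: Dict[str, float]
    roc_points: Dict[str, List[Tuple[float, float]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "fdr": self.fdr,
            "tpr": self.tpr,
            "fnr": self.fnr,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fpr": self.fpr,
            "roc_points": {
                c: [[float(a), float(b)] for a, b in pts]
                for c, pts in self.roc_points.items()
            },
        }


def _canonical_classes(labels: np.ndarray) -> Tuple[str, ...]:
    present = set(labels)
    known = tuple(c for c in CLASSES if c in present)
    if set(known) == present:
        return known
    return tuple(sorted(present))


def evaluate(
    y_true: Sequence,
    y_pred: Sequence,
    scores: Optional[pd.DataFrame] = None,
    classes: Optional[Sequence[str]] = None,
) -> EvalReport:
    """Build the full evaluation report from labels (and optional scores).

    ``scores`` is a per-class score table (e.g. KNN vote fractions) used
    for one-vs-rest ROC curves; columns must be class names.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred) or len(y_true) == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    if classes is None:
        classes = _canonical_classes(y_true)
    classes = tuple(classes)
    unseen = (set(y_true) | set(y_pred)) - set(classes)
    if unseen:
        raise ValueError(f"labels outside the class set: {sorted(unseen)}")
    cm = _sk_confusion(y_true, y_pred, labels=list(classes))
    total = cm.sum()
    accuracy = float(np.trace(cm) / total)
    ppv, fdr, tpr, fnr, sens, spec, fpr_d = {}, {}, {}, {}, {}, {}, {}
    for i, c in enumerate(classes):
        col = cm[:, i].sum()
        row = cm[i, :].sum()
        tp = cm[i, i]
        fp = col - tp
        fn = row - tp
        tn = total - tp - fp - fn
        ppv[c] = float(tp / col) if col else float("nan")
        fdr[c] = float(fp / col) if col else float("nan")
        tpr[c] = float(tp / row) if row else float("nan")
        fnr[c] = float(fn / row) if row else float("nan")
        sens[c] = tpr[c]
        spec[c] = float(tn / (tn + fp)) if (tn + fp) else float("nan")
        fpr_d[c] = float(fp / (fp + tn)) if (fp + tn) else float("nan")
    roc: Dict[str, List[Tuple[float, float]]] = {}
    if scores is not None:
        for c in classes:
            if c not in scores.columns:
                raise ValueError(f"scores missing column for class {c!r}")
            truth = (y_true == c).astype(int)
            if truth.min() == truth.max():
                continue  # ROC undefined with a single class present
            fpr_c, tpr_c, _ = _sk_roc_curve(truth, scores[c].to_numpy())
            roc[c] = list(zip(fpr_c.tolist(), tpr_c.tolist()))
    return EvalReport(
        classes=classes,
        confusion_matrix=cm,
        accuracy=accuracy,
        ppv=ppv,
        fdr=fdr,
        tpr=tpr,
        fnr=fnr,
        sensitivity=sens,
        specificity=spec,
        fpr=fpr_d,
        roc_points=roc,
    )
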