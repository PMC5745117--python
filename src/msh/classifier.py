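"""Five-class Raman tissue classifier and k-means annotation maps.

Tissue classes are BCC, dermis, fat, EMI and surgical dye, where EMI
merges epidermis, muscle and inflammation — their Raman spectra are too
similar to separate reliably and the diagnosis only needs them apart
from BCC. The classifier is a single-hidden-layer neural network (20
hidden nodes) over the 13 unit-normed band-area features; performance
is estimated by patient-grouped 5-fold cross-validation so spectra from
one patient never straddle a fold boundary.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.model_selection import GroupKFold
from sklearn.neural_network import MLPClassifier

CLASS_NAMES = ("BCC", "dermis", "fat", "EMI", "dye")
N_FEATURES = 13
N_HIDDEN = 20


@dataclass
class ConfusionMatrix:
    """Aggregated counts[true, predicted] with one-vs-rest metrics."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class list")

    def sensitivity(self, class_name: str) -> float:
        """Recall of ``class_name``: TP / (TP + FN)."""
        i = self.classes.index(class_name)
        row = self.counts[i].sum()
        return self.counts[i, i] / row if row else float("nan")

    def specificity(self, class_name: str) -> float:
        """One-vs-rest true-negative rate of ``class_name``."""
        i = self.classes.index(class_name)
        tn = self.counts.sum() - self.counts[i].sum() - self.counts[:, i].sum() + self.counts[i, i]
        negatives = self.counts.sum() - self.counts[i].sum()
        return tn / negatives if negatives else float("nan")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


@dataclass
class ClassifierModel:
    """Trained 13 -> 20 -> 5 network with its class order and seed."""

    network: MLPClassifier
    classes: tuple[str, ...]
    seed: int

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "ClassifierModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, ClassifierModel):
            raise ValueError(f"{path} does not contain a classifier model")
        return model


def _balance(
    features: np.ndarray, labels: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample minority classes to the majority count.

    Stands in for inverse-frequency loss weights, which the underlying
    network implementation does not expose.
    """
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() == counts.max():
        return features, labels
    target = counts.max()
    xs, ys = [features], [labels]
    for cls, cnt in zip(classes, counts):
        if cnt < target:
            idx = np.flatnonzero(labels == cls)
            extra = rng.choice(idx, size=target - cnt, replace=True)
            xs.append(features[extra])
            ys.append(labels[extra])
    return np.concatenate(xs), np.concatenate(ys)


def train_ann(
    features: np.ndarray,
    labels: "np.ndarray | list[str]",
    hidden: int = N_HIDDEN,
    seed: int = 0,
    max_iter: int = 600,
) -> ClassifierModel:
    """Train the single-hidden-layer network on band-area features.

    Uses a tanh hidden layer, softmax output, L2 penalty and the LBFGS
    optimiser (deterministic for a fixed seed). Imbalanced classes are
    oversampled to parity before fitting.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[1] != N_FEATURES:
        raise ValueError(f"features must be (n, {N_FEATURES})")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")
    rng = np.random.default_rng(seed)
    xb, yb = _balance(x, y, rng)
    net = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="tanh",
        solver="lbfgs",
        alpha=1e-4,
        max_iter=max_iter,
        random_state=int(seed) % (2**32),
    )
    net.fit(xb, yb)
    return ClassifierModel(net, tuple(net.classes_), int(seed))


def classify(model: ClassifierModel, feature_vector: np.ndarray):
    """Predict the tissue class of one feature vector.

    Returns ``(class_name, probabilities)`` where probabilities follow
    the order of ``model.classes`` and sum to 1.
    """
    v = np.asarray(feature_vector, dtype=float).ravel()
    if v.shape != (N_FEATURES,):
        raise ValueError(f"expected a {N_FEATURES}-dimensional feature vector")
    proba = model.network.predict_proba(v[None, :])[0]
    return model.classes[int(np.argmax(proba))], proba


def classify_batch(model: ClassifierModel, features: np.ndarray):
    """Vectorised :func:`classify`: ``(labels, probability matrix)``."""
    x = np.asarray(features, dtype=float)
    proba = model.network.predict_proba(x)
    labels = np.array([model.classes[i] for i in np.argmax(proba, axis=1)])
    return labels, proba


def group_folds(group_ids: np.ndarray, k: int):
    """Index splits with whole groups held out (the CV fold structure)."""
    g = np.asarray(group_ids)
    n_groups = len(np.unique(g))
    if n_groups < k:
        raise ValueError(f"only {n_groups} groups for {k} folds")
    dummy = np.zeros(len(g))
    return list(GroupKFold(n_splits=k).split(dummy, groups=g))


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    group_ids: np.ndarray,
    k: int = 5,
    seed: int = 0,
    hidden: int = N_HIDDEN,
) -> ConfusionMatrix:
    """Group-aware k-fold cross-validation of the network.

    Folds are built over ``group_ids`` (patients), so no group appears
    in both a training and a test split. Returns the confusion matrix
    aggregated over folds.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    g = np.asarray(group_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes = tuple(sorted(np.unique(y), key=list(CLASS_NAMES).index)
                    if set(np.unique(y)) <= set(CLASS_NAMES) else np.unique(y))
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for fold, (tr, te) in enumerate(group_folds(g, k)):
        model = train_ann(x[tr], y[tr], hidden=hidden, seed=seed + fold)
        pred, _ = classify_batch(model, x[te])
        for yt, yp in zip(y[te], pred):
            counts[idx[yt], idx[yp]] += 1
    return ConfusionMatrix(counts, classes)


def kmeans_annotation_map(
    raster: np.ndarray, k: int, seed: int = 0
) -> np.ndarray:
    """Cluster a raster of spectra for histology-guided annotation.

    ``raster`` has shape (rows, cols, n_points); returns an integer
    cluster-index image of shape (rows, cols). Deterministic for a
    fixed seed.
    """
    arr = np.asarray(raster, dtype=float)
    if arr.ndim != 3:
        raise ValueError("raster must be (rows, cols, n_points)")
    if k < 1:
        raise ValueError("k must be >= 1")
    flat = arr.reshape(-1, arr.shape[2])
    if k > flat.shape[0]:
        raise ValueError(f"k={k} exceeds the number of spectra ({flat.shape[0]})")
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**32))
    labels = km.fit_predict(flat)
    return labels.reshape(arr.shape[:2])
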