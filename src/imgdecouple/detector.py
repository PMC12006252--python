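"""K-nearest-neighbor coupled/decoupled classifier.

The final decoupling detector is deliberately simple: k = 4 neighbours,
Manhattan (city-block) distance on z-scored features, uniform votes.  The
positive class is ``decoupled``.  Because sensitivity to true decoupling is
valued over specificity (a salvage pass on a coupled event is nearly
harmless), 2-2 vote ties resolve to ``decoupled``.

An instance-based learner has no weights beyond its training data, so the
serialised model embeds the standardizer and the full training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateTrainingError, IncompleteInputError
from .features import FINAL_FEATURES, FeatureVector
from .signals import COUPLED, DECOUPLED

SCHEMA_VERSION = 1
DEFAULT_CV_SEED = 20250208


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on training data only."""

    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        if np.any(sds <= 0):
            bad = np.flatnonzero(sds <= 0).tolist()
            raise DegenerateTrainingError(
                f"feature column(s) {bad} are constant; cannot standardize")
        return cls(means=means, sds=sds)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.sds


@dataclass
class ConfusionMatrix:
    """2x2 counts with ``decoupled`` as the positive class."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, sensitivity (decoupled recall) and specificity.

    Margins with no events yield ``nan`` rather than raising, so callers
    can aggregate over folds that happen to miss a class.
    """
    out = {"accuracy": (cm.tp + cm.tn) / cm.n if cm.n else float("nan")}
    out["sensitivity"] = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else float("nan")
    out["specificity"] = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else float("nan")
    return out


@dataclass
class KnnModel:
    """Fitted detector: standardizer plus stored training instances."""

    standardizer: Standardizer
    train_features: np.ndarray  # standardized, (n, 4)
    train_labels: np.ndarray  # of {'coupled', 'decoupled'}
    train_event_ids: List[str]
    k: int = 4
    metric: str = "manhattan"
    feature_ids: Tuple[str, ...] = FINAL_FEATURES
    tie_label: str = DECOUPLED

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "k": self.k,
            "metric": self.metric,
            "feature_ids": list(self.feature_ids),
            "tie_label": self.tie_label,
            "means": self.standardizer.means.tolist(),
            "sds": self.standardizer.sds.tolist(),
            "train_features_standardized": self.train_features.tolist(),
            "train_labels": self.train_labels.tolist(),
            "train_event_ids": list(self.train_event_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KnnModel":
        return cls(
            standardizer=Standardizer(np.asarray(d["means"], dtype=float),
                                      np.asarray(d["sds"], dtype=float)),
            train_features=np.asarray(d["train_features_standardized"], dtype=float),
            train_labels=np.asarray(d["train_labels"], dtype=object),
            train_event_ids=list(d["train_event_ids"]),
            k=int(d["k"]),
            metric=d["metric"],
            feature_ids=tuple(d["feature_ids"]),
            tie_label=d.get("tie_label", DECOUPLED),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "KnnModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=float)
    rows = []
    for fv in features:
        rows.append(fv.as_array() if isinstance(fv, FeatureVector) else np.asarray(fv, dtype=float))
    return np.vstack(rows)


def fit(features, labels: Sequence[str], k: int = 4,
        event_ids: Optional[Sequence[str]] = None) -> KnnModel:
    """Fit (store and standardize) the training instances.

    ``features`` is an (n, 4) matrix or a sequence of
    :class:`FeatureVector`; ``labels`` are 'coupled'/'decoupled'.
    """
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=object)
    if len(X) != len(y):
        raise DegenerateTrainingError("features and labels differ in length")
    if len(X) < k:
        raise DegenerateTrainingError(f"need at least k={k} training events, got {len(X)}")
    if len(set(y.tolist())) < 2:
        raise DegenerateTrainingError("training data must contain both classes")
    if event_ids is None:
        width = len(str(len(X) - 1))
        event_ids = [f"train-{i:0{width}d}" for i in range(len(X))]
    std = Standardizer.fit(X)
    return KnnModel(standardizer=std, train_features=std.transform(X),
                    train_labels=y, train_event_ids=list(event_ids), k=k)


def predict(model: KnnModel, fv) -> str:
    """Classify one event by a majority vote of the k nearest neighbours.

    City-block distances on standardized features; distance ties at the
    k-th neighbour admit the lexicographically first event id; vote ties
    go to the model's ``tie_label`` (decoupled by default).
    """
    if isinstance(fv, FeatureVector):
        x = fv.as_array()
    else:
        x = np.asarray(fv, dtype=float)
    if x.shape != (model.train_features.shape[1],):
        raise IncompleteInputError(
            f"expected {model.train_features.shape[1]} features, got {x.shape}")
    if np.any(~np.isfinite(x)):
        raise IncompleteInputError("feature vector contains non-finite values")
    xs = model.standardizer.transform(x)
    d = np.abs(model.train_features - xs).sum(axis=1)
    order = sorted(range(len(d)), key=lambda i: (d[i], model.train_event_ids[i]))
    votes = model.train_labels[order[: model.k]]
    n_dec = int(np.sum(votes == DECOUPLED))
    n_cpl = len(votes) - n_dec
    if n_dec > n_cpl:
        return DECOUPLED
    if n_cpl > n_dec:
        return COUPLED
    return model.tie_label


def predict_batch(model: KnnModel, features) -> np.ndarray:
    X = _as_matrix(features)
    return np.array([predict(model, row) for row in X], dtype=object)


def cross_validate(features, labels: Sequence[str], folds: int = 10,
                   seed: int = DEFAULT_CV_SEED, k: int = 4):
    """Stratified k-fold cross-validation with per-fold refitting.

    The standardizer and neighbour store are refitted inside every training
    fold so no test-fold information leaks.  Returns the pooled
    out-of-fold :class:`ConfusionMatrix` and a list of per-fold metric
    dicts.  Deterministic for a fixed seed.
    """
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < folds:
        raise DegenerateTrainingError(
            f"stratified {folds}-fold CV needs >= {folds} events per class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled = ConfusionMatrix()
    fold_metrics = []
    for train_idx, test_idx in skf.split(X, y.astype(str)):
        model = fit(X[train_idx], y[train_idx], k=k)
        pred = predict_batch(model, X[test_idx])
        cm = ConfusionMatrix(
            tp=int(np.sum((pred == DECOUPLED) & (y[test_idx] == DECOUPLED))),
            fp=int(np.sum((pred == DECOUPLED) & (y[test_idx] == COUPLED))),
            fn=int(np.sum((pred == COUPLED) & (y[test_idx] == DECOUPLED))),
            tn=int(np.sum((pred == COUPLED) & (y[test_idx] == COUPLED))),
        )
        pooled = pooled + cm
        fold_metrics.append(confusion_metrics(cm))
    return pooled, fold_metrics
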