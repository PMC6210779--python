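"""FoG / no-FoG discrimination under a stratified 70:30 split protocol.

Four classifiers are benchmarked — an RBF-kernel support vector machine,
k-nearest neighbours, a decision tree and Gaussian naive Bayes — on the
28-dimensional augmented feature matrix. Each "simulation" re-draws the
stratified split (and re-seeds any stochastic model internals), re-fits the
PCA augmentation and the standardization on the training fold only, and
evaluates accuracy, sensitivity and specificity on the validation fold, with
FoG as the positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import InputError, ParameterError, StratificationError
from .features import pca_augment

POSITIVE_LABEL = "FoG"
NEGATIVE_LABEL = "noFoG"

CLASSIFIER_KINDS = ("svm_rbf", "knn", "dt", "nb")

#: Conventional default hyperparameters (none are reported for the protocol
#: this reproduces): unit-C RBF SVM with gamma = 1/(n_features x variance),
#: 5-nearest-neighbour vote, Gini decision tree of unlimited depth, Gaussian
#: naive Bayes.
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "svm_rbf": {"C": 1.0, "gamma": "scale"},
    "knn": {"n_neighbors": 5, "metric": "euclidean"},
    "dt": {"criterion": "gini", "max_depth": None},
    "nb": {},
}


@dataclass
class ConfusionMatrix:
    """Binary confusion counts with FoG as the positive class."""

    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self):
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP

    def accuracy(self) -> float:
        """(TP + TN) / total, in percent."""
        return 100.0 * (self.TP + self.TN) / self.total if self.total else float("nan")

    def sensitivity(self) -> float:
        """TP / (TP + FN), in percent; NaN when no positives were evaluated."""
        den = self.TP + self.FN
        return 100.0 * self.TP / den if den else float("nan")

    def specificity(self) -> float:
        """TN / (TN + FP), in percent; NaN when no negatives were evaluated."""
        den = self.TN + self.FP
        return 100.0 * self.TN / den if den else float("nan")


@dataclass
class SimulationResult:
    """Metrics of one train/validation simulation for one classifier."""

    seed: int
    confusion: ConfusionMatrix
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class ClassificationReport:
    """Per-simulation metrics and their arithmetic means for one classifier."""

    classifier_kind: str
    per_simulation: list[SimulationResult]

    @property
    def seeds(self) -> list[int]:
        return [r.seed for r in self.per_simulation]

    def _mean(self, attr: str) -> float:
        vals = [getattr(r, attr) for r in self.per_simulation]
        return float(np.mean(vals))

    @property
    def mean_accuracy(self) -> float:
        return self._mean("accuracy")

    @property
    def mean_sensitivity(self) -> float:
        return self._mean("sensitivity")

    @property
    def mean_specificity(self) -> float:
        return self._mean("specificity")

    def as_dict(self) -> dict:
        return {
            "classifier": self.classifier_kind,
            "seeds": self.seeds,
            "per_simulation": [
                {
                    "seed": r.seed,
                    "accuracy": r.accuracy,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "confusion": {
                        "TP": r.confusion.TP,
                        "FN": r.confusion.FN,
                        "TN": r.confusion.TN,
                        "FP": r.confusion.FP,
                    },
                }
                for r in self.per_simulation
            ],
            "mean_accuracy": self.mean_accuracy,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
        }


def mean_of_percentages(values) -> float:
    """Arithmetic mean of per-simulation percentage metrics."""
    return float(np.mean(np.asarray(values, dtype=float)))


def stratified_split(
    labels, train_fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation split of subject indices.

    Per class, round(train_fraction x class size) subjects (round half up)
    go to training, the remainder to validation; the within-class permutation
    is driven by ``seed``. Returns sorted index arrays that are disjoint and
    exhaustive.
    """
    labels = np.asarray(labels)
    if not 0 < train_fraction < 1:
        raise ParameterError("train_fraction must lie strictly between 0 and 1")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("both classes must be present")
    if np.any(counts < 2):
        small = classes[counts < 2]
        raise StratificationError(f"class(es) {list(small)} have fewer than 2 members")
    rng = np.random.default_rng(seed)
    train, val = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)  # keep both folds populated
        train.extend(perm[:n_train])
        val.extend(perm[n_train:])
    return np.sort(np.asarray(train, dtype=int)), np.sort(np.asarray(val, dtype=int))


def make_classifier(kind: str, hyperparams: dict | None = None, seed: int = 0) -> Pipeline:
    """Standardization + classifier pipeline for one of the four kinds."""
    if kind not in CLASSIFIER_KINDS:
        raise ParameterError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")
    params = dict(DEFAULT_HYPERPARAMS[kind])
    params.update(hyperparams or {})
    if kind == "svm_rbf":
        clf = SVC(kernel="rbf", random_state=seed, **params)
    elif kind == "knn":
        clf = KNeighborsClassifier(**params)
    elif kind == "dt":
        clf = DecisionTreeClassifier(random_state=seed, **params)
    else:
        clf = GaussianNB(**params)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_classifier(
    features: np.ndarray, labels, kind: str, hyperparams: dict | None = None, seed: int = 0
) -> Pipeline:
    """Fit one classifier; deterministic given (data, hyperparams, seed).

    Feature columns are standardized inside the pipeline with statistics from
    this training data only.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise InputError("training set contains a single class")
    if np.any(counts < 2):
        raise InputError("each class needs at least 2 training subjects")
    model = make_classifier(kind, hyperparams, seed)
    model.fit(np.asarray(features, dtype=float), labels)
    return model


def evaluate(model, features, labels) -> tuple[ConfusionMatrix, float, float, float]:
    """Confusion matrix and accuracy / sensitivity / specificity in percent.

    A metric whose denominator is empty (no positives, or no negatives, in
    the evaluated set) is returned as NaN rather than 0.
    """
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise InputError("empty evaluation set")
    pred = model.predict(np.asarray(features, dtype=float))
    pos = labels == POSITIVE_LABEL
    ppos = pred == POSITIVE_LABEL
    cm = ConfusionMatrix(
        TP=int(np.sum(pos & ppos)),
        FN=int(np.sum(pos & ~ppos)),
        TN=int(np.sum(~pos & ~ppos)),
        FP=int(np.sum(~pos & ppos)),
    )
    return cm, cm.accuracy(), cm.sensitivity(), cm.specificity()


def run_simulations(
    features,
    labels,
    kinds=CLASSIFIER_KINDS,
    n_simulations: int = 10,
    base_seed: int = 0,
    train_fraction: float = 0.7,
    hyperparams: dict | None = None,
    augment: bool = True,
) -> list[ClassificationReport]:
    """The full split protocol, repeated over successive simulations.

    Simulation ``s`` uses seed ``base_seed + s`` for the stratified split and
    the model internals. When ``augment`` is True, ``features`` is the n x 14
    feature table and within each simulation a PCA augmentation to 28 columns
    is fitted on the training fold and applied frozen to the validation fold;
    when False, ``features`` is used as-is.
    """
    if n_simulations < 1:
        raise ParameterError("n_simulations must be >= 1")
    if isinstance(features, pd.DataFrame):
        features = features.to_numpy(dtype=float)
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if len(features) != len(labels):
        raise InputError("features and labels must have the same number of rows")
    hyperparams = hyperparams or {}

    results: dict[str, list[SimulationResult]] = {k: [] for k in kinds}
    for s in range(n_simulations):
        seed = base_seed + s
        train_idx, val_idx = stratified_split(labels, train_fraction, seed)
        if augment:
            aug = pca_augment(features[train_idx], np.vstack([features[train_idx], features[val_idx]]))
            x_all = aug.values
            x_train = x_all[: len(train_idx)]
            x_val = x_all[len(train_idx) :]
        else:
            x_train, x_val = features[train_idx], features[val_idx]
        y_train, y_val = labels[train_idx], labels[val_idx]
        for kind in kinds:
            model = train_classifier(x_train, y_train, kind, hyperparams.get(kind), seed)
            cm, acc, sens, spec = evaluate(model, x_val, y_val)
            results[kind].append(
                SimulationResult(seed=seed, confusion=cm, accuracy=acc, sensitivity=sens, specificity=spec)
            )
    return [ClassificationReport(classifier_kind=k, per_simulation=results[k]) for k in kinds]
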