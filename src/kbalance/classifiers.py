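"""Simple ensemble classifiers over k-mer profile matrices.

Families:

- ``bagged_trees``: decision trees, each fit on a bootstrap resample.
- ``subspace_knn`` / ``subspace_discriminant``: k-nearest-neighbour or
  linear discriminant members, each restricted to a random subset of
  feature dimensions (random subspace method).
- ``svm_linear`` / ``svm_gaussian`` / ``svm_polynomial``: single SVMs
  with the named kernel, features standardized internally.
- ``mlp``: one hidden layer of 512 units, standardized inputs, early
  stopping.

Ensembles predict by hard majority vote; ties break toward the lowest
index in the model's sorted class list, so predictions are reproducible.
Tree and KNN families use the profiles as-is (they already live on
[0, 1]); SVM and MLP standardize internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import joblib
import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FAMILIES",
    "ClassifierSpec",
    "TrainedModel",
    "ModelFormatError",
    "train",
    "predict",
    "save_model",
    "load_model",
]

FAMILIES = (
    "bagged_trees",
    "subspace_knn",
    "subspace_discriminant",
    "svm_linear",
    "svm_gaussian",
    "svm_polynomial",
    "mlp",
)
_ENSEMBLE_FAMILIES = ("bagged_trees", "subspace_knn", "subspace_discriminant")
_SUBSPACE_FAMILIES = ("subspace_knn", "subspace_discriminant")
_MULTICLASS_ONLY = ("subspace_discriminant", "svm_linear", "svm_gaussian",
                    "svm_polynomial", "mlp")

MODEL_FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """Raised when a saved model cannot be loaded safely."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Family plus the few hyperparameters that matter.

    Unset fields (None) are resolved to family defaults at training time:
    100 bootstrap trees for bagging, 30 members on ceil(D/2)-dimensional
    subspaces for the subspace families, 10 neighbours for KNN.
    """

    family: str
    n_learners: int | None = None
    subspace_dim: int | None = None
    knn_k: int = 10
    hidden_size: int = 512
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.n_learners is not None and self.n_learners < 1:
            raise ValueError("n_learners must be >= 1")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")

    def resolved(self, n_features: int) -> "ClassifierSpec":
        n_learners = self.n_learners
        if n_learners is None:
            n_learners = 100 if self.family == "bagged_trees" else 30
        subspace_dim = self.subspace_dim
        if self.family in _SUBSPACE_FAMILIES:
            if subspace_dim is None:
                subspace_dim = math.ceil(n_features / 2)
            if not (1 <= subspace_dim <= n_features):
                raise ValueError(
                    f"subspace_dim must be in [1, {n_features}], got {subspace_dim}")
        return replace(self, n_learners=n_learners, subspace_dim=subspace_dim)


@dataclass
class TrainedModel:
    """A fitted classifier: ordered class list, ensemble members (each a
    fitted estimator plus its feature subset, or None for all features),
    and the feature-space fingerprint it refuses to violate."""

    spec: ClassifierSpec
    classes: list[str]
    members: list = field(default_factory=list)  # (estimator, feature_idx | None)
    fingerprint: dict = field(default_factory=dict)


def _check_features(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if X.size and not np.isfinite(X).all():
        raise ValueError("feature matrix contains NaN or Inf")
    return X


def train(X, y: Sequence[str], spec: ClassifierSpec, feature_config=None) -> TrainedModel:
    """Fit ``spec`` on profiles ``X`` with labels ``y``.

    Deterministic given ``spec.seed``. ``feature_config`` (a
    :class:`~kbalance.kmer_features.FeatureConfig`) stamps the model with
    the feature-space identity; without it only the dimensionality is
    recorded.
    """
    X = _check_features(X)
    y = list(y)
    n, d = X.shape
    if n != len(y):
        raise ValueError(f"X has {n} rows but y has {len(y)} labels")
    if n < 2:
        raise ValueError("need at least 2 training samples")
    classes = sorted(set(y))
    if len(classes) < 2 and spec.family in _MULTICLASS_ONLY:
        raise ValueError(f"family {spec.family!r} requires >= 2 classes")

    spec = spec.resolved(d)
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_to_idx[lab] for lab in y])
    rng = np.random.default_rng(spec.seed)

    members: list = []
    if spec.family == "bagged_trees":
        for _ in range(spec.n_learners):
            member_seed = int(rng.integers(2**31 - 1))
            idx = rng.integers(0, n, n) if spec.bootstrap else np.arange(n)
            est = DecisionTreeClassifier(random_state=member_seed)
            est.fit(X[idx], y_idx[idx])
            members.append((est, None))
    elif spec.family in _SUBSPACE_FAMILIES:
        for _ in range(spec.n_learners):
            feats = np.sort(rng.choice(d, size=spec.subspace_dim, replace=False))
            if spec.family == "subspace_knn":
                est = KNeighborsClassifier(n_neighbors=min(spec.knn_k, n))
            else:
                est = LinearDiscriminantAnalysis()
            est.fit(X[:, feats], y_idx)
            members.append((est, feats))
    else:
        seed = int(rng.integers(2**31 - 1))
        if spec.family == "mlp":
            est = make_pipeline(
                StandardScaler(),
                MLPClassifier(hidden_layer_sizes=(spec.hidden_size,),
                              early_stopping=True, max_iter=300, random_state=seed))
        else:
            kernel = {"svm_linear": "linear", "svm_gaussian": "rbf",
                      "svm_polynomial": "poly"}[spec.family]
            est = make_pipeline(StandardScaler(), SVC(kernel=kernel, random_state=seed))
        est.fit(X, y_idx)
        members.append((est, None))

    fingerprint = dict(feature_config.fingerprint()) if feature_config is not None \
        else {"k": None, "D": d, "ordering": None}
    return TrainedModel(spec=spec, classes=classes, members=members, fingerprint=fingerprint)


def predict(model: TrainedModel, X) -> list[str]:
    """Hard-label predictions; ensemble members vote, ties break to the
    lowest class index."""
    X = _check_features(X)
    expected = model.fingerprint.get("D")
    if X.shape[1] != expected:
        raise ValueError(
            f"feature dimension mismatch: model expects D={expected}, got {X.shape[1]}")
    m = X.shape[0]
    if m == 0:
        return []
    votes = np.zeros((m, len(model.classes)), dtype=np.int64)
    for est, feats in model.members:
        cols = X if feats is None else X[:, feats]
        pred = np.asarray(est.predict(cols), dtype=np.int64)
        votes[np.arange(m), pred] += 1
    winners = votes.argmax(axis=1)  # argmax takes the first max: lowest class index
    return [model.classes[i] for i in winners]


def save_model(model: TrainedModel, path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> TrainedModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # truncated/corrupt files must fail loudly
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFormatError(f"{path}: not a kbalance model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: model format {payload['format_version']} is not supported "
            f"(this build reads format {MODEL_FORMAT_VERSION})")
    return payload["model"]
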