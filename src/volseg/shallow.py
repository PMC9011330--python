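"""Supervoxel-based shallow machine learning segmentation.

The pipeline aggregates feature volumes into a per-supervoxel descriptor
matrix (mean and standard deviation of each feature layer over each
supervoxel), extracts a training set from a sparse annotation (a supervoxel is
a training sample iff it contains at least one annotated voxel; its class is
the majority nonzero label, ties going to the smallest label id), trains a
classical classifier, predicts a class for every supervoxel, and projects the
per-supervoxel labels back to a voxel volume.

Available classifier kinds: ``random_forest``, ``extra_random_forest``,
``gradient_boosting`` and ``svm`` (RBF kernel on standardized features).
Forests default to 100 trees with class-balanced weights. All estimators are
seeded, so a run is a pure function of (features, partition, annotation,
seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .annotation import AnnotationVolume
from .errors import ValidationError
from .supervoxels import SupervoxelPartition

CLASSIFIER_KINDS = ("random_forest", "extra_random_forest", "gradient_boosting", "svm")


@dataclass
class FeatureMatrix:
    """K supervoxels x C feature columns, with column names ``layer_stat``."""

    values: np.ndarray
    column_names: list[str]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def aggregate_features(
    feature_layers: dict[str, np.ndarray],
    partition: SupervoxelPartition,
) -> FeatureMatrix:
    """Mean and standard deviation of each feature layer over each supervoxel."""
    if not feature_layers:
        raise ValidationError("need at least one feature layer")
    flat = partition.labels.ravel()
    counts = np.bincount(flat, minlength=partition.count).astype(np.float64)
    cols, names = [], []
    for name, layer in feature_layers.items():
        layer = np.asarray(layer, dtype=np.float64)
        if layer.shape != partition.labels.shape:
            raise ValidationError(
                f"feature layer {name!r} shape {layer.shape} != partition shape {partition.labels.shape}"
            )
        sums = np.bincount(flat, weights=layer.ravel(), minlength=partition.count)
        sqsums = np.bincount(flat, weights=(layer**2).ravel(), minlength=partition.count)
        mean = sums / counts
        var = np.maximum(sqsums / counts - mean**2, 0.0)
        cols += [mean, np.sqrt(var)]
        names += [f"{name}_mean", f"{name}_sd"]
    X = np.stack(cols, axis=1)
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite values in aggregated feature matrix")
    return FeatureMatrix(values=X, column_names=names)


def extract_training_set(
    ann: AnnotationVolume,
    partition: SupervoxelPartition,
) -> tuple[np.ndarray, np.ndarray]:
    """Row indices and class labels of supervoxels holding any annotation.

    The class of a training supervoxel is the majority nonzero label among
    its annotated voxels; ties break toward the smallest label id.
    """
    if ann.labels.shape != partition.labels.shape:
        raise ValidationError("annotation and partition shapes differ")
    annotated = ann.labels.ravel() != 0
    if not annotated.any():
        raise ValidationError("annotation is empty: no training samples")
    sv = partition.labels.ravel()[annotated]
    lab = ann.labels.ravel()[annotated].astype(np.int64)
    n_lab = int(lab.max()) + 1
    # per-(supervoxel, label) vote counts
    pair_counts = np.bincount(sv * n_lab + lab, minlength=partition.count * n_lab)
    pair_counts = pair_counts.reshape(partition.count, n_lab)
    rows = np.flatnonzero(pair_counts.sum(axis=1) > 0)
    y = np.argmax(pair_counts[rows], axis=1)  # first max -> smallest label id on ties
    return rows, y.astype(np.int32)


@dataclass
class ShallowModel:
    """A trained classifier restricted to the class ids it saw in training."""

    kind: str
    estimator: object
    n_features: int
    classes: np.ndarray
    params: dict = field(default_factory=dict)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores (probabilities), shape (n_rows, n_classes_seen)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValidationError(
                f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns; "
                f"model was trained with {self.n_features}"
            )
        return self.estimator.predict_proba(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.predict_scores(X)
        return self.classes[np.argmax(scores, axis=1)]


def _build_estimator(kind: str, params: dict, seed: int):
    if kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 100)),
            max_depth=params.get("max_depth"),
            class_weight="balanced",
            random_state=seed,
        )
    if kind == "extra_random_forest":
        return ExtraTreesClassifier(
            n_estimators=int(params.get("n_estimators", 100)),
            max_depth=params.get("max_depth"),
            class_weight="balanced",
            random_state=seed,
        )
    if kind == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=int(params.get("n_estimators", 100)),
            learning_rate=float(params.get("learning_rate", 0.1)),
            random_state=seed,
        )
    if kind == "svm":
        svc = SVC(
            kernel="rbf",
            C=float(params.get("C", 1.0)),
            gamma=params.get("gamma", "scale"),
            random_state=seed,
        )
        # calibration wrapper supplies per-class probability scores
        return make_pipeline(
            StandardScaler(), CalibratedClassifierCV(svc, ensemble=False, cv=3)
        )
    raise ValidationError(f"unknown classifier kind {kind!r}; expected one of {CLASSIFIER_KINDS}")


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    kind: str = "random_forest",
    params: dict | None = None,
    seed: int = 0,
) -> ShallowModel:
    """Fit a shallow classifier on supervoxel descriptors. Deterministic per seed."""
    params = dict(params or {})
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError(f"X shape {X.shape} inconsistent with y length {y.shape}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("training features contain non-finite values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError(f"need at least 2 classes to train, got {classes.tolist()}")
    est = _build_estimator(kind, params, seed)
    est.fit(X, y)
    return ShallowModel(kind=kind, estimator=est, n_features=X.shape[1], classes=classes, params=params)


def predict_partition(
    model: ShallowModel,
    X_all: FeatureMatrix | np.ndarray,
    partition: SupervoxelPartition,
) -> np.ndarray:
    """One class id per supervoxel, for all K supervoxels."""
    X = X_all.values if isinstance(X_all, FeatureMatrix) else np.asarray(X_all)
    if X.shape[0] != partition.count:
        raise ValidationError(f"feature matrix has {X.shape[0]} rows, partition has {partition.count}")
    return model.predict(X).astype(np.int32)


def project_to_voxels(sv_labels: np.ndarray, partition: SupervoxelPartition) -> np.ndarray:
    """Broadcast per-supervoxel labels to a voxel label volume."""
    sv_labels = np.asarray(sv_labels)
    if sv_labels.ndim != 1 or sv_labels.shape[0] != partition.count:
        raise ValidationError(
            f"label vector length {sv_labels.shape} != supervoxel count {partition.count}"
        )
    return sv_labels.astype(np.int32)[partition.labels]


def segment(
    feature_layers: dict[str, np.ndarray],
    partition: SupervoxelPartition,
    ann: AnnotationVolume,
    kind: str = "random_forest",
    params: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Full shallow pipeline: aggregate, train on the annotation, predict, project."""
    fm = aggregate_features(feature_layers, partition)
    rows, y = extract_training_set(ann, partition)
    model = train_classifier(fm.values[rows], y, kind=kind, params=params, seed=seed)
    sv_pred = predict_partition(model, fm, partition)
    return project_to_voxels(sv_pred, partition)
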