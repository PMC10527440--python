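"""Classifier evaluation: stratified 10-fold CV per subject, channel sweeps.

Three classifiers are supported with fixed defaults: an RBF support vector
machine (C = 1.0, tol = 1e-3, gamma = 'scale'), k-nearest neighbours
(k = 10, Euclidean), and linear discriminant analysis with the eigen solver
and no shrinkage. Stress is the positive class. Metrics come from the
confusion counts pooled across folds; feature standardization is fit on the
training folds only (leakage-free, via a per-fold pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .annotation import STRESS
from .errors import ValidationError
from .features import FEATURE_COLUMNS

__all__ = [
    "CLASSIFIER_NAMES",
    "make_classifier",
    "confusion_metrics",
    "design_matrix",
    "crossvalidate_subject",
    "crossvalidate",
    "channel_sweep",
    "SubjectMetrics",
    "CVReport",
]

CLASSIFIER_NAMES = ("svm", "knn", "rlda")

DEFAULT_SWEEP_SIZES = [1, 5, 8, 9, 15, 19, 32]


def make_classifier(name: str):
    """Instantiate one of the three fixed-parameter classifiers."""
    if name == "svm":
        return SVC(C=1.0, kernel="rbf", tol=1e-3, gamma="scale")
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=10, metric="euclidean")
    if name == "rlda":
        return LinearDiscriminantAnalysis(solver="eigen", shrinkage=None)
    raise ValidationError(f"unknown classifier {name!r} (choose from {CLASSIFIER_NAMES})")


def confusion_metrics(tp: int, fp: int, tn: int, fn: int):
    """(precision, recall, accuracy) from confusion counts; stress positive.

    A metric with a zero denominator is returned as nan (undefined), never
    silently as 0.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValidationError("confusion counts must be non-negative")
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total if total > 0 else float("nan")
    return precision, recall, accuracy


@dataclass
class SubjectMetrics:
    subject_id: str
    classifier: str
    precision: float
    recall: float
    accuracy: float
    counts: dict = field(default_factory=dict)  # pooled tp/fp/tn/fn


@dataclass
class CVReport:
    per_subject: list[SubjectMetrics]
    n_folds: int
    seed: int

    def mean(self, metric: str = "accuracy") -> float:
        vals = [getattr(m, metric) for m in self.per_subject]
        return float(np.nanmean(vals)) if vals else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject": m.subject_id,
                    "classifier": m.classifier,
                    "precision": m.precision,
                    "recall": m.recall,
                    "accuracy": m.accuracy,
                }
                for m in self.per_subject
            ]
        )


def design_matrix(
    features: pd.DataFrame, channels: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pivot a per-(segment, channel) feature table to one row per segment.

    Each channel contributes its 20 features; X has 20 * n_channels columns
    ordered (channel, feature). y is 1 for stress rows, 0 for calm.
    """
    if channels is not None:
        present = set(features["channel"].unique())
        missing = [c for c in channels if c not in present]
        if missing:
            raise ValidationError(f"channels absent from feature table: {missing}")
        features = features[features["channel"].isin(channels)]
    else:
        channels = sorted(features["channel"].unique())
    wide = features.pivot_table(
        index=["subject", "trial", "segment"],
        columns="channel",
        values=FEATURE_COLUMNS,
        sort=False,
    )
    # order columns (channel, feature) and rebuild labels per segment
    cols = [(f, c) for c in channels for f in FEATURE_COLUMNS]
    X = wide[cols].to_numpy()
    labels = (
        features.drop_duplicates(["subject", "trial", "segment"])
        .set_index(["subject", "trial", "segment"])
        .loc[wide.index, "label"]
    )
    y = (labels == STRESS).to_numpy().astype(int)
    return X, y


def _pooled_cv_counts(X, y, clf_name: str, n_folds: int, seed: int, scale: bool):
    counts = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        clf = make_classifier(clf_name)
        model = make_pipeline(StandardScaler(), clf) if scale else clf
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        counts["tp"] += int(np.sum((pred == 1) & (y[test] == 1)))
        counts["fp"] += int(np.sum((pred == 1) & (y[test] == 0)))
        counts["tn"] += int(np.sum((pred == 0) & (y[test] == 0)))
        counts["fn"] += int(np.sum((pred == 0) & (y[test] == 1)))
    return counts


def crossvalidate_subject(
    features: pd.DataFrame,
    classifier: str,
    channels: list[str] | None = None,
    n_folds: int = 10,
    seed: int = 0,
    scale: bool = True,
) -> SubjectMetrics:
    """Stratified k-fold CV on one subject's feature table.

    Folds are a seeded stratified partition; metrics come from the confusion
    counts pooled over the k test folds.
    """
    subjects = features["subject"].unique()
    if len(subjects) != 1:
        raise ValidationError(f"expected a single subject, got {list(subjects)}")
    X, y = design_matrix(features, channels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) < n_folds:
        raise ValidationError(
            f"class with {min(n_pos, n_neg)} rows cannot fill {n_folds} folds; "
            f"use n_folds <= {min(n_pos, n_neg)}"
        )
    counts = _pooled_cv_counts(X, y, classifier, n_folds, seed, scale)
    precision, recall, accuracy = confusion_metrics(**counts)
    return SubjectMetrics(
        subject_id=str(subjects[0]),
        classifier=classifier,
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        counts=counts,
    )


def crossvalidate(
    features: pd.DataFrame,
    classifiers: list[str] | None = None,
    channels: list[str] | None = None,
    n_folds: int = 10,
    seed: int = 0,
    scale: bool = True,
) -> CVReport:
    """Subject-independent evaluation: CV within each subject, then averaged."""
    classifiers = classifiers or list(CLASSIFIER_NAMES)
    per_subject = []
    for sid, grp in features.groupby("subject", sort=True):
        for name in classifiers:
            per_subject.append(
                crossvalidate_subject(
                    grp, name, channels=channels, n_folds=n_folds, seed=seed, scale=scale
                )
            )
    return CVReport(per_subject=per_subject, n_folds=n_folds, seed=seed)


def channel_sweep(
    features: pd.DataFrame,
    ranked_channels: list[str],
    set_sizes: list[int] | None = None,
    classifier: str = "svm",
    n_folds: int = 10,
    seed: int = 0,
    scale: bool = True,
) -> pd.DataFrame:
    """Mean accuracy (+/- sd across subjects) versus ranked channel-set size."""
    sizes = set_sizes or [s for s in DEFAULT_SWEEP_SIZES if s <= len(ranked_channels)]
    rows = []
    for s in sizes:
        if s > len(ranked_channels):
            raise ValidationError(
                f"size {s} exceeds the {len(ranked_channels)} ranked channels"
            )
        subset = ranked_channels[:s]
        report = crossvalidate(
            features, [classifier], channels=subset, n_folds=n_folds, seed=seed, scale=scale
        )
        accs = [m.accuracy for m in report.per_subject]
        rows.append(
            {
                "n_channels": s,
                "classifier": classifier,
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
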