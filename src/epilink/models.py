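"""Tree-ensemble classifiers and imbalanced-class evaluation metrics.

Three classifiers are compared: a random forest (100 trees), AdaBoost, and
gradient-boosted decision trees (100 estimators, learning rate 0.1, full
subsample). All expose a positive-class probability per pair. Evaluation
reports six metrics: sensitivity (Sn = recall = TPR), specificity
(Sp = TNR), precision, accuracy, AUROC, and the area under the
precision-recall curve (AUPRC) — the last being the most informative
summary under the fixed 1:4 positive:negative class imbalance.

Thresholded metrics use a decision threshold of 0.5 on the predicted
probability by default (a score >= threshold predicts "interacting").
AUPRC uses step-wise (rectangular) integration of the precision-recall
curve rather than trapezoids, which avoids optimistic linear interpolation
between operating points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

ALGOS = ("RF", "AdaBoost", "GBDT")


@dataclass(frozen=True)
class ClassifierSpec:
    """Which ensemble to fit and with what hyperparameters.

    Defaults follow the study configuration: RF with 100 trees; GBDT with
    100 estimators, learning rate 0.1, subsample 1. AdaBoost uses library
    defaults apart from the shared seed.
    """

    algo: str = "RF"
    n_estimators: int = 100
    learning_rate: float = 0.1
    subsample: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algo not in ALGOS:
            raise ValueError(f"algo must be one of {ALGOS}, got {self.algo!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    """Hard-threshold confusion counts."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsReport:
    """The six evaluation metrics, each in [0, 1]."""

    sn: float
    sp: float
    precision: float
    acc: float
    auc: float
    auprc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sn": self.sn,
            "sp": self.sp,
            "precision": self.precision,
            "acc": self.acc,
            "auc": self.auc,
            "auprc": self.auprc,
        }

    def __str__(self) -> str:
        return (
            f"Sn={self.sn:.3f}  Sp={self.sp:.3f}  precision={self.precision:.3f}  "
            f"Acc={self.acc:.3f}  AUC={self.auc:.3f}  AUPRC={self.auprc:.3f}"
        )


def _make_estimator(spec: ClassifierSpec):
    if spec.algo == "RF":
        return RandomForestClassifier(
            n_estimators=spec.n_estimators, random_state=spec.seed, n_jobs=1
        )
    if spec.algo == "AdaBoost":
        return AdaBoostClassifier(random_state=spec.seed)
    return GradientBoostingClassifier(
        n_estimators=spec.n_estimators,
        learning_rate=spec.learning_rate,
        subsample=spec.subsample,
        random_state=spec.seed,
    )


class PairClassifier:
    """A fitted ensemble bound to a feature schema hash.

    The schema hash guards cross-cell-line transfer: scoring a matrix built
    under a different geometry (tracks, bin width, bin counts) is refused.
    """

    def __init__(self, spec: ClassifierSpec, schema_hash: str | None = None):
        self.spec = spec
        self.schema_hash = schema_hash
        self.estimator = _make_estimator(spec)

    def fit(self, matrix: np.ndarray, labels: np.ndarray) -> "PairClassifier":
        labels = np.asarray(labels)
        if len(np.unique(labels)) < 2:
            raise ValueError("training labels contain a single class")
        self.estimator.fit(matrix, labels)
        return self

    def scores(self, matrix: np.ndarray) -> np.ndarray:
        """Positive-class probability per row."""
        pos = list(self.estimator.classes_).index(1)
        return self.estimator.predict_proba(matrix)[:, pos]

    def save(self, path) -> None:
        joblib.dump(
            {"spec": self.spec, "schema_hash": self.schema_hash, "estimator": self.estimator},
            path,
        )

    @classmethod
    def load(cls, path) -> "PairClassifier":
        blob = joblib.load(path)
        obj = cls.__new__(cls)
        obj.spec = blob["spec"]
        obj.schema_hash = blob["schema_hash"]
        obj.estimator = blob["estimator"]
        return obj


def train(
    matrix: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    schema_hash: str | None = None,
) -> PairClassifier:
    """Fit the requested ensemble; deterministic under ``spec.seed``."""
    return PairClassifier(spec, schema_hash).fit(matrix, labels)


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Hard confusion counts, predicting positive iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
    )


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """All six metrics from scores and binary labels.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), precision = TP/(TP+FP) (0 when no
    positive predictions), Acc = (TP+TN)/total. AUC is the area under the
    TPR-FPR curve over all thresholds (equivalently the tie-aware
    Mann-Whitney probability); AUPRC is the step-wise area under
    precision-recall.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    c = confusion_at_threshold(scores, labels, threshold)
    sn = c.TP / (c.TP + c.FN)
    sp = c.TN / (c.TN + c.FP)
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else 0.0
    acc = (c.TP + c.TN) / c.total
    auc = float(roc_auc_score(labels, scores))
    auprc = float(average_precision_score(labels, scores))
    return MetricsReport(sn, sp, precision, acc, auc, auprc)


def cross_validate(
    matrix: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    k: int = 10,
    threshold: float = 0.5,
) -> tuple[list[MetricsReport], MetricsReport]:
    """Stratified k-fold cross-validation; returns per-fold and mean reports.

    Folds are disjoint, stratified, and shuffled under ``spec.seed``; the
    model is refit from scratch for each fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= k={k} members, got {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    folds: list[MetricsReport] = []
    for train_idx, val_idx in skf.split(matrix, labels):
        model = train(matrix[train_idx], labels[train_idx], spec)
        folds.append(
            compute_metrics(model.scores(matrix[val_idx]), labels[val_idx], threshold)
        )
    mean = MetricsReport(
        **{
            key: float(np.mean([f.as_dict()[key] for f in folds]))
            for key in folds[0].as_dict()
        }
    )
    return folds, mean


def evaluate_transfer(
    model: PairClassifier,
    matrix: np.ndarray,
    labels: np.ndarray,
    schema_hash: str | None = None,
    threshold: float = 0.5,
) -> MetricsReport:
    """Score a model on another cell line's matrix; no refitting.

    If both the model and the matrix carry a schema hash they must agree —
    transfer across differing feature geometries is meaningless.
    """
    if (
        model.schema_hash is not None
        and schema_hash is not None
        and model.schema_hash != schema_hash
    ):
        raise ValueError(
            f"schema mismatch: model {model.schema_hash} vs matrix {schema_hash}"
        )
    return compute_metrics(model.scores(matrix), labels, threshold)


def write_metrics_json(path, report: MetricsReport, extra: dict | None = None) -> None:
    payload = report.as_dict()
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def write_curve_points(path, scores: np.ndarray, labels: np.ndarray) -> None:
    """Write ROC and PR operating points as TSV for external plotting."""
    from sklearn.metrics import precision_recall_curve, roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    with open(path, "w") as fh:
        fh.write("curve\tx\ty\n")
        for x, y in zip(fpr, tpr):
            fh.write(f"roc\t{x:.6g}\t{y:.6g}\n")
        for x, y in zip(rec, prec):
            fh.write(f"pr\t{x:.6g}\t{y:.6g}\n")
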