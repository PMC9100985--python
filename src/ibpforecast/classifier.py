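"""Imbalance-aware random-forest training and evaluation.

Hypotension samples are rare (a few percent of windows), so the training
protocol is built around that imbalance: minority up-sampling inside each
training fold (never in held-out data), stratified 5-fold cross-validation,
and optional class weights on the Gini split criterion. Metrics are
accuracy over both classes plus precision and recall of the hypotension
(positive) class; per-fold ROC curves and Gini feature importances complete
the report.

The forest itself is scikit-learn's ``RandomForestClassifier`` (100 trees,
bootstrap bagging, random feature subsets, Gini criterion); this module owns
the protocol around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from ibpforecast.features import FEATURE_NAMES

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "SampleTable",
    "ConfusionMatrix",
    "Metrics",
    "FoldResult",
    "CVReport",
    "upsample_minority",
    "stratified_kfold",
    "train_forest",
    "evaluate",
    "roc_points",
    "gini_importance",
    "cross_validate",
    "parse_class_weight",
]

POSITIVE = "hypotension"
NEGATIVE = "normal"


@dataclass
class SampleTable:
    """Feature matrix + labels (+ optional patient groups) for learning."""

    features: NDArray[np.float64]
    labels: NDArray[np.str_]
    groups: NDArray | None = None
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels row counts must match")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape[0] != self.labels.shape[0]:
                raise ValueError("groups length must match labels")

    @property
    def n(self) -> int:
        return int(self.labels.shape[0])

    def subset(self, idx: NDArray) -> "SampleTable":
        return SampleTable(
            self.features[idx],
            self.labels[idx],
            None if self.groups is None else self.groups[idx],
            self.feature_names,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df["label"] = self.labels
        if self.groups is not None:
            df["patient_id"] = self.groups
        return df


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    """Accuracy over both classes; precision/recall of the positive class.

    ``precision_defined`` is False when no positive prediction was made
    (TP+FP = 0); precision is then reported as 0 so sweeps can proceed.
    """

    accuracy: float
    precision: float
    recall: float
    precision_defined: bool = True


@dataclass
class FoldResult:
    confusion: ConfusionMatrix
    metrics: Metrics
    fpr: NDArray[np.float64]
    tpr: NDArray[np.float64]
    auc: float


@dataclass
class CVReport:
    """Per-fold and pooled cross-validation outcome."""

    folds: list[FoldResult]
    pooled_confusion: ConfusionMatrix
    pooled: Metrics
    mean_importances: NDArray[np.float64]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))

    def top_features(self, k: int = 10) -> list[tuple[str, float]]:
        order = np.argsort(-self.mean_importances)[:k]
        return [(self.feature_names[i], float(self.mean_importances[i])) for i in order]


def upsample_minority(table: SampleTable, seed: int) -> SampleTable:
    """Duplicate minority rows (with replacement) until classes are equal.

    Training-fold use only: held-out data must keep its natural imbalance.
    """
    labels, counts = np.unique(table.labels, return_counts=True)
    if labels.size < 2:
        raise ValueError("both classes must be present")
    minority = labels[np.argmin(counts)]
    deficit = int(np.max(counts) - np.min(counts))
    if deficit == 0:
        return table
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(table.labels == minority)
    extra = rng.choice(pool, size=deficit, replace=True)
    idx = np.concatenate([np.arange(table.n), extra])
    return table.subset(idx)


def stratified_kfold(
    table: SampleTable, k: int = 5, seed: int = 0
) -> list[tuple[NDArray, NDArray]]:
    """Seeded stratified k-fold (train, test) index pairs.

    Test sets partition the rows; each fold's class proportions match the
    global ones to within one sample.
    """
    labels, counts = np.unique(table.labels, return_counts=True)
    if labels.size < 2 or np.min(counts) < k:
        raise ValueError(f"each class needs at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(table.features, table.labels)]


def parse_class_weight(scheme: str | None):
    """Map a scheme name to the forest's class_weight argument.

    ``none``/None, ``balanced``, ``balanced_subsample``, or an explicit
    ratio ``"a:b"`` read as hypotension:normal weight (e.g. ``"9:1"`` puts
    nine-fold weight on the hypotension class).
    """
    if scheme is None or scheme == "none":
        return None
    if scheme in ("balanced", "balanced_subsample"):
        return scheme
    if ":" in scheme:
        a, b = scheme.split(":")
        return {POSITIVE: float(a), NEGATIVE: float(b)}
    raise ValueError(f"unknown class weight scheme {scheme!r}")


def train_forest(
    train: SampleTable,
    n_trees: int = 100,
    class_weight: str | None = None,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit the 100-tree Gini random forest; deterministic given the seed."""
    labels, counts = np.unique(train.labels, return_counts=True)
    if labels.size < 2 or np.min(counts) < 2:
        raise ValueError("need at least 2 rows per class")
    model = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        class_weight=parse_class_weight(class_weight),
        random_state=seed,
        n_jobs=1,
    )
    model.fit(train.features, train.labels)
    return model


def positive_scores(model: RandomForestClassifier, features: NDArray) -> NDArray[np.float64]:
    """Vote fraction for the hypotension class."""
    col = list(model.classes_).index(POSITIVE)
    return model.predict_proba(features)[:, col]


def confusion(predictions: NDArray, truth: NDArray) -> ConfusionMatrix:
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("predictions and truth must have equal length")
    pos_p, pos_t = pred == POSITIVE, true == POSITIVE
    return ConfusionMatrix(
        tp=int(np.sum(pos_p & pos_t)),
        tn=int(np.sum(~pos_p & ~pos_t)),
        fp=int(np.sum(pos_p & ~pos_t)),
        fn=int(np.sum(~pos_p & pos_t)),
    )


def evaluate(predictions: NDArray, truth: NDArray) -> tuple[ConfusionMatrix, Metrics]:
    """Confusion counts and accuracy / precision / recall (positive class)."""
    cm = confusion(predictions, truth)
    acc = (cm.tp + cm.tn) / cm.total if cm.total else 0.0
    if cm.tp + cm.fp > 0:
        prec, defined = cm.tp / (cm.tp + cm.fp), True
    else:
        prec, defined = 0.0, False
    rec = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else 0.0
    return cm, Metrics(accuracy=acc, precision=prec, recall=rec, precision_defined=defined)


def roc_points(scores: NDArray, truth: NDArray) -> tuple[NDArray, NDArray, float]:
    """ROC curve (FPR, TPR) over distinct score thresholds + trapezoid area."""
    truth = np.asarray(truth)
    if np.unique(truth).size < 2:
        raise ValueError("both classes must be present in truth")
    fpr, tpr, _ = roc_curve(truth, np.asarray(scores, dtype=np.float64), pos_label=POSITIVE)
    area = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, area


def gini_importance(model: RandomForestClassifier) -> NDArray[np.float64]:
    """Mean-decrease-in-Gini importances, normalized to sum to 1."""
    if not hasattr(model, "feature_importances_"):
        raise ValueError("model is not fitted")
    imp = np.asarray(model.feature_importances_, dtype=np.float64)
    s = imp.sum()
    return imp / s if s > 0 else imp


def cross_validate(
    table: SampleTable,
    k: int = 5,
    n_trees: int = 100,
    class_weight: str | None = None,
    seed: int = 0,
    upsample: bool = True,
    group_by_patient: bool = False,
) -> CVReport:
    """Stratified k-fold evaluation with in-fold minority up-sampling.

    Up-sampling happens strictly inside each training fold; test folds keep
    their natural class balance. Pooled metrics aggregate the confusion
    counts of all test folds; per-fold metrics and ROC curves are kept too.

    ``group_by_patient=False`` (default) splits per sample, so windows of
    one patient can appear on both sides of a fold — convenient but subject
    to patient-level coupling (a held-out positive depletes its own
    patient's training prevalence, biasing its score down). With
    ``group_by_patient=True`` folds are stratified while keeping each
    patient's windows on one side only (requires ``table.groups``), the
    leakage-safe protocol.
    """
    if group_by_patient:
        if table.groups is None:
            raise ValueError("group_by_patient requires table.groups")
        sgkf = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in sgkf.split(table.features, table.labels, table.groups)]
    else:
        folds = stratified_kfold(table, k=k, seed=seed)
    results: list[FoldResult] = []
    importances = []
    pooled_pred: list[NDArray] = []
    pooled_true: list[NDArray] = []
    for i, (tr, te) in enumerate(folds):
        train = table.subset(tr)
        if upsample:
            train = upsample_minority(train, seed=seed + 1000 + i)
        model = train_forest(train, n_trees=n_trees, class_weight=class_weight, seed=seed + i)
        test = table.subset(te)
        pred = model.predict(test.features)
        cm, met = evaluate(pred, test.labels)
        fpr, tpr, auc = roc_points(positive_scores(model, test.features), test.labels)
        results.append(FoldResult(cm, met, fpr, tpr, auc))
        importances.append(gini_importance(model))
        pooled_pred.append(pred)
        pooled_true.append(test.labels)
    pooled_cm, pooled_met = evaluate(np.concatenate(pooled_pred), np.concatenate(pooled_true))
    return CVReport(
        folds=results,
        pooled_confusion=pooled_cm,
        pooled=pooled_met,
        mean_importances=np.mean(importances, axis=0),
        feature_names=table.feature_names,
    )
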