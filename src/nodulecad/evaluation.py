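"""Confusion-matrix metrics, Cohen's kappa, ROC/AUROC and report bundling.

The positive class is *nodule*.  Metrics follow the definitions used for
the classification approach:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    TCA         = (TP + TN) / total          (total classification accuracy)
    FPR         = FP / (FP + TP)
    RMSE        = sqrt(sum((y' - y)^2) / n)

Note that this FPR is a false-discovery-style ratio, retained as defined;
the conventional false-positive rate FP / (FP + TN) is also emitted as
``fpr_conventional``.  A metric whose denominator is zero is reported as
None (undefined), never silently 0.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve


@dataclasses.dataclass
class ConfusionMatrix:
    """TP/FP/FN/TN counts; the constructor order matches the tabulated
    (TP, FP, FN, TN) convention of the reference matrices."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.fn, self.tn):
            if v < 0:
                raise ValueError("negative count")
        if self.total < 1:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Rate metrics of a confusion matrix; undefined rates are None."""
    return {
        "sensitivity": _ratio(cm.tp, cm.tp + cm.fn),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
        "tca": _ratio(cm.tp + cm.tn, cm.total),
        "fpr": _ratio(cm.fp, cm.fp + cm.tp),
        "fpr_conventional": _ratio(cm.fp, cm.fp + cm.tn),
    }


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement between predictions and truth."""
    n = cm.total
    po = (cm.tp + cm.tn) / n
    pred_pos, pred_neg = cm.tp + cm.fp, cm.fn + cm.tn
    true_pos, true_neg = cm.tp + cm.fn, cm.fp + cm.tn
    pe = (pred_pos * true_pos + pred_neg * true_neg) / (n * n)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def rmse(y_true: Sequence[float], scores: Sequence[float]) -> float:
    """Root mean squared error between continuous scores and 0/1 labels."""
    y_true = np.asarray(y_true, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    if y_true.shape != scores.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((scores - y_true) ** 2)))


def roc_auroc(
    y_true: Sequence[int], scores: Sequence[float]
) -> tuple[list[tuple[float, float]], float]:
    """ROC by threshold sweep and its trapezoidal area.

    The trapezoidal area over the full (no intermediate points dropped)
    curve equals the Mann-Whitney rank statistic, i.e. the probability a
    random positive scores above a random negative (ties count 1/2).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _roc_curve(y_true, scores, drop_intermediate=False)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return points, float(_trapezoid_auc(fpr, tpr))


@dataclasses.dataclass
class EvaluationReport:
    """Full metric bundle for one classifier on one evaluation set."""

    cm: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    tca: float | None
    fpr: float | None
    fpr_conventional: float | None
    rmse: float
    kappa: float
    auroc: float
    roc_points: list[tuple[float, float]]
    feature_names: list[str] = dataclasses.field(default_factory=list)
    extra: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "tp": self.cm.tp, "fp": self.cm.fp,
                "fn": self.cm.fn, "tn": self.cm.tn,
            },
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tca": self.tca,
            "fpr": self.fpr,
            "fpr_conventional": self.fpr_conventional,
            "rmse": self.rmse,
            "kappa": self.kappa,
            "auroc": self.auroc,
            "roc_points": self.roc_points,
            "feature_names": self.feature_names,
            **self.extra,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def report_from_scores(
    y_true: Sequence[int],
    scores: Sequence[float],
    feature_names: Sequence[str] | None = None,
    **extra,
) -> EvaluationReport:
    """Build a full report from continuous positive-class scores
    (hard labels at threshold 0.5)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    y_pred = (scores >= 0.5).astype(int)
    cm = confusion(y_true, y_pred)
    m = metrics(cm)
    points, area = roc_auroc(y_true, scores)
    return EvaluationReport(
        cm=cm,
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        tca=m["tca"],
        fpr=m["fpr"],
        fpr_conventional=m["fpr_conventional"],
        rmse=rmse(y_true, scores),
        kappa=kappa(cm),
        auroc=area,
        roc_points=points,
        feature_names=list(feature_names or []),
        extra=dict(extra),
    )


def evaluate_split(spec, trainset, testset) -> EvaluationReport:
    """Run a method pipeline on a train/test split (see pipeline.run_method)."""
    from .pipeline import run_method

    return run_method(spec, trainset, testset)


def cross_validate(spec, dataset, folds: int = 5, seed: int = 0):
    """Stratified k-fold cross-validation (see pipeline.cross_validate)."""
    from .pipeline import cross_validate as _cv

    return _cv(spec, dataset, folds=folds, seed=seed)
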