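"""Evaluation metrics and reporting.

Segmentation overlap (Dice / IoU), mean absolute error, multiclass
classification reports (accuracy, per-class precision/recall/F1,
sensitivity/specificity, confusion matrix, per-class and macro/micro AUC),
percentile-bootstrap confidence intervals, decision-curve net benefit, and
paired reader-study summaries (unassisted vs assisted accuracy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)


@dataclass
class SegmentationScore:
    dice: float
    iou: float


def dice_iou(pred: np.ndarray, truth: np.ndarray) -> SegmentationScore:
    """Dice and IoU of two binary masks in the same frame.

    Both-empty masks score 1 by convention (logged); Dice = 2·IoU/(1+IoU).
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"frame mismatch: {pred.shape} vs {truth.shape}")
    inter = float((pred & truth).sum())
    union = float((pred | truth).sum())
    if union == 0:
        logger.info("both masks empty; Dice = IoU = 1 by convention")
        return SegmentationScore(1.0, 1.0)
    iou = inter / union
    dice = 2.0 * inter / (pred.sum() + truth.sum())
    return SegmentationScore(float(dice), float(iou))


def mean_absolute_error(pred: Sequence[float], truth: Sequence[float]) -> float:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.mean(np.abs(pred - truth)))


@dataclass
class ClassificationReport:
    classes: list[str]
    accuracy: float
    confusion: np.ndarray  # (k, k) counts, rows = truth
    precision: dict[str, float] = field(default_factory=dict)
    recall: dict[str, float] = field(default_factory=dict)
    f1: dict[str, float] = field(default_factory=dict)
    sensitivity: dict[str, float] = field(default_factory=dict)
    specificity: dict[str, float] = field(default_factory=dict)
    auc: dict[str, float] = field(default_factory=dict)
    macro_auc: float = np.nan
    micro_auc: float = np.nan

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "macro_auc": self.macro_auc,
            "micro_auc": self.micro_auc,
        }


def classification_metrics(
    preds: Sequence[str],
    labels: Sequence[str],
    scores: np.ndarray | None = None,
    *,
    classes: list[str] | None = None,
) -> ClassificationReport:
    """One-vs-rest multiclass metrics with macro/micro AUC.

    ``scores`` is an (n, k) class-probability matrix in the order of
    ``classes``.  The AUC is the Mann–Whitney rank statistic (ties
    averaged); macro AUC is the unweighted mean of per-class AUCs (classes
    with zero support excluded with a warning), micro AUC pools all
    (sample, class) decisions.
    """
    preds = np.asarray([str(p) for p in preds])
    labels = np.asarray([str(v) for v in labels])
    if classes is None:
        classes = sorted(set(labels) | set(preds))
    cm = _sk_confusion(labels, preds, labels=classes)
    total = cm.sum()
    rep = ClassificationReport(
        classes=list(classes),
        accuracy=float(np.trace(cm) / total) if total else np.nan,
        confusion=cm,
    )
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        rep.precision[c] = float(tp / (tp + fp)) if tp + fp else np.nan
        rep.recall[c] = float(tp / (tp + fn)) if tp + fn else np.nan
        rep.sensitivity[c] = rep.recall[c]
        rep.specificity[c] = float(tn / (tn + fp)) if tn + fp else np.nan
        pr, rc = rep.precision[c], rep.recall[c]
        rep.f1[c] = float(2 * pr * rc / (pr + rc)) if pr + rc and np.isfinite(pr + rc) else np.nan

    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        aucs = []
        for i, c in enumerate(classes):
            yb = (labels == c).astype(int)
            if yb.sum() in (0, len(yb)):
                logger.warning("class %s has degenerate support; AUC undefined", c)
                rep.auc[c] = np.nan
                continue
            rep.auc[c] = float(roc_auc_score(yb, scores[:, i]))
            aucs.append(rep.auc[c])
        rep.macro_auc = float(np.mean(aucs)) if aucs else np.nan
        Yb = np.zeros_like(scores, dtype=int)
        for i, c in enumerate(classes):
            Yb[:, i] = labels == c
        rep.micro_auc = float(roc_auc_score(Yb.ravel(), scores.ravel()))
    return rep


def bootstrap_ci(
    metric: Callable[[np.ndarray], float],
    data: np.ndarray,
    *,
    B: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of ``metric`` over rows of ``data``."""
    if B < 100:
        raise ValueError("B must be >= 100")
    data = np.asarray(data)
    rng = np.random.default_rng(seed)
    n = len(data)
    stats = np.array([metric(data[rng.integers(0, n, n)]) for _ in range(B)])
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray
    prevalence: float


def decision_curve(
    scores: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> NetBenefitCurve:
    """Decision-curve net benefit of a binary score across thresholds.

    ``NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)`` where a sample is treated when
    its score exceeds p_t; treat-all and treat-none reference curves are
    included.  Thresholds must lie in (0, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.linspace(0.05, 0.95, 19)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must be strictly inside (0, 1)")
    n = len(labels)
    prev = labels.mean() if n else np.nan
    nb = np.empty_like(thresholds)
    ta = np.empty_like(thresholds)
    for j, pt in enumerate(thresholds):
        treat = scores >= pt
        tp = float((treat & (labels == 1)).sum())
        fp = float((treat & (labels == 0)).sum())
        w = pt / (1 - pt)
        nb[j] = tp / n - (fp / n) * w
        ta[j] = prev - (1 - prev) * w
    return NetBenefitCurve(
        thresholds=thresholds,
        net_benefit=nb,
        treat_all=ta,
        treat_none=np.zeros_like(thresholds),
        prevalence=float(prev),
    )


@dataclass
class ReaderStudySummary:
    unassisted: np.ndarray
    assisted: np.ndarray
    differences: np.ndarray
    mean_unassisted: float
    mean_assisted: float
    mean_increase: float
    sd_increase: float
    mean_increase_pct: float
    sd_increase_pct: float


def reader_study_summary(pre_acc: Sequence[float], post_acc: Sequence[float]) -> ReaderStudySummary:
    """Paired unassisted/assisted reader accuracies.

    Differences are assisted − unassisted per reader; the spread uses the
    sample (n−1) standard deviation; increases are reported both as
    fractions and percentage points.
    """
    pre = np.asarray(pre_acc, dtype=float)
    post = np.asarray(post_acc, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("need paired pre/post accuracies for >= 2 readers")
    if np.any((pre < 0) | (pre > 1) | (post < 0) | (post > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    diff = post - pre
    return ReaderStudySummary(
        unassisted=pre,
        assisted=post,
        differences=diff,
        mean_unassisted=float(pre.mean()),
        mean_assisted=float(post.mean()),
        mean_increase=float(diff.mean()),
        sd_increase=float(diff.std(ddof=1)),
        mean_increase_pct=float(diff.mean() * 100.0),
        sd_increase_pct=float(diff.std(ddof=1) * 100.0),
    )
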