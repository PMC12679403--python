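"""Voxel-wise evaluation of probabilistic segmentations.

Threshold-free metrics (AUROC, average precision) and hard metrics at a
binarization threshold (DICE, precision, recall, confusion counts), plus the
underlying ROC and precision-recall curves. AUROC equals the probability
that a random vessel voxel outscores a random background voxel (ties count
half); AP is the step-wise integral of precision over recall with no
interpolation. Both are computed with scikit-learn, which implements
exactly those definitions.

An optional mask restricts scoring to a labelled subregion, as when only a
manually annotated subvolume of a large dataset has ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)

__all__ = ["EvaluationReport", "confusion_at_threshold", "dice_score",
           "auroc", "average_precision", "evaluate", "plot_curves"]

MAX_EXACT_THRESHOLDS = 10_000
N_QUANTILE_THRESHOLDS = 1024


def _flatten(prob, truth, mask=None):
    prob = np.asarray(prob)
    truth = np.asarray(truth)
    if prob.shape != truth.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs truth "
                         f"{truth.shape}")
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != prob.shape:
            raise ValueError(f"mask shape {mask.shape} != volume shape "
                             f"{prob.shape}")
        prob, truth = prob[mask], truth[mask]
    scores = prob.ravel().astype(np.float64)
    labels = (truth.ravel() != 0)
    return scores, labels


def confusion_at_threshold(prob_volume, truth_volume, threshold: float = 0.5,
                           mask=None) -> tuple[int, int, int, int]:
    """Voxel-wise ``(TP, FP, FN, TN)`` with prediction = (prob >= threshold)."""
    scores, labels = _flatten(prob_volume, truth_volume, mask)
    pred = scores >= threshold
    tp = int(np.count_nonzero(pred & labels))
    fp = int(np.count_nonzero(pred & ~labels))
    fn = int(np.count_nonzero(~pred & labels))
    tn = int(np.count_nonzero(~pred & ~labels))
    return tp, fp, fn, tn


def dice_score(pred_mask, truth_mask) -> float:
    """Hard DICE: 2|A∩B| / (|A|+|B|); 1.0 for two empty masks."""
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(truth_mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shape mismatch")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.count_nonzero(a & b) / denom)


def _require_both_classes(labels: np.ndarray, metric: str) -> None:
    if labels.all() or not labels.any():
        raise ValueError(f"{metric} undefined: ground truth contains a "
                         "single class")


def auroc(prob_volume, truth_volume, mask=None) -> float:
    """Area under the ROC curve (= Mann-Whitney pairwise statistic)."""
    scores, labels = _flatten(prob_volume, truth_volume, mask)
    _require_both_classes(labels, "AUROC")
    return float(roc_auc_score(labels, scores))


def average_precision(prob_volume, truth_volume, mask=None) -> float:
    """Average precision: sum over thresholds of (R_i - R_{i-1}) * P_i."""
    scores, labels = _flatten(prob_volume, truth_volume, mask)
    _require_both_classes(labels, "average precision")
    return float(average_precision_score(labels, scores))


@dataclass
class EvaluationReport:
    """Voxel-wise metrics for one prediction/ground-truth pair."""

    auroc: float
    average_precision: float
    dice: float
    precision: float
    recall: float
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    roc_points: list          # [(fpr, tpr, threshold), ...]
    pr_points: list           # [(recall, precision, threshold), ...]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "EvaluationReport":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def evaluate(prob_volume, truth_volume, threshold: float = 0.5,
             mask=None) -> EvaluationReport:
    """Full voxel-wise evaluation of a probability volume.

    Ties in scores are grouped into single threshold steps. When the score
    set has more than 10^4 unique values, the stored curve points are
    thinned to 1024 quantile-spaced thresholds (the scalar metrics are
    always computed from the full data).
    """
    scores, labels = _flatten(prob_volume, truth_volume, mask)
    _require_both_classes(labels, "evaluation")
    tp, fp, fn, tn = confusion_at_threshold(prob_volume, truth_volume,
                                            threshold, mask)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    dice = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 1.0

    fpr, tpr, roc_thr = roc_curve(labels, scores)
    prec_c, rec_c, pr_thr = precision_recall_curve(labels, scores)
    roc_points = list(zip(fpr.tolist(), tpr.tolist(), roc_thr.tolist()))
    pr_points = list(zip(rec_c.tolist(), prec_c.tolist(),
                         np.append(pr_thr, np.inf).tolist()))
    max_pts = N_QUANTILE_THRESHOLDS
    if len(roc_points) > max_pts:
        keep = np.linspace(0, len(roc_points) - 1, max_pts).astype(int)
        roc_points = [roc_points[i] for i in keep]
    if len(pr_points) > max_pts:
        keep = np.linspace(0, len(pr_points) - 1, max_pts).astype(int)
        pr_points = [pr_points[i] for i in keep]

    return EvaluationReport(
        auroc=float(roc_auc_score(labels, scores)),
        average_precision=float(average_precision_score(labels, scores)),
        dice=float(dice), precision=float(precision), recall=float(recall),
        threshold=float(threshold), tp=tp, fp=fp, fn=fn, tn=tn,
        roc_points=roc_points, pr_points=pr_points)


def plot_curves(report: EvaluationReport, out_path) -> None:
    """Write ROC and precision-recall curve plots (PNG) for a report."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    fpr = [p[0] for p in report.roc_points]
    tpr = [p[1] for p in report.roc_points]
    ax1.plot(fpr, tpr, label=f"AUROC = {report.auroc:.3f}")
    ax1.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax1.set_xlabel("False positive rate")
    ax1.set_ylabel("True positive rate")
    ax1.set_title("ROC")
    ax1.legend()
    rec = [p[0] for p in report.pr_points]
    prec = [p[1] for p in report.pr_points]
    ax2.plot(rec, prec, label=f"AP = {report.average_precision:.3f}")
    ax2.set_xlabel("Recall")
    ax2.set_ylabel("Precision")
    ax2.set_ylim(0, 1.05)
    ax2.set_title("Precision-recall")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
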