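"""Scoring predictions against ground truth.

Continuous variables are scored with two-level means: per-trajectory mean
absolute error over frames, then a mean over trajectories (MAE for alpha;
MALE for K, i.e. the same average taken in log10(K+1) space).  States are
scored with a row-normalised 4x4 confusion matrix and the mean of its
diagonal (average class accuracy; rows of absent classes are excluded).

Changepoints are scored after minimum-cost (squared-distance) Hungarian
pairing of predicted against true points.  Pairs closer than 5 frames are
true positives; everything else counts as a false negative (ground-truth
side) or false positive (prediction side).  The Jaccard index is
TP / (TP + FN + FP) and the RMSE is computed over the paired points only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import confusion_matrix

__all__ = [
    "CP_TOLERANCE",
    "mae",
    "male",
    "state_metrics",
    "pair_changepoints",
    "jaccard",
    "cp_rmse",
    "score_changepoints",
    "MetricsReport",
    "evaluate_predictions",
]

CP_TOLERANCE = 5  # frames; a pair is a true positive when |t_g - t_p| < 5
N_STATES = 4


def _two_level_mean(preds: list[np.ndarray], gts: list[np.ndarray]) -> float:
    per_traj = [np.mean(np.abs(np.asarray(p) - np.asarray(g))) for p, g in zip(preds, gts)]
    return float(np.mean(per_traj))


def mae(preds: list[np.ndarray], gts: list[np.ndarray]) -> float:
    """Mean absolute error: per-trajectory mean over frames, then over trajectories."""
    return _two_level_mean(preds, gts)


def male(pred_logK: list[np.ndarray], gt_K: list[np.ndarray],
         gt_in_log_space: bool = False) -> float:
    """Mean absolute log error for K; predictions already in log10(K+1) space."""
    if not gt_in_log_space:
        gt_K = [np.log10(np.asarray(g) + 1.0) for g in gt_K]
    return _two_level_mean(pred_logK, gt_K)


def state_metrics(pred_s: list[np.ndarray], gt_s: list[np.ndarray]):
    """Row-normalised confusion matrix and average class accuracy.

    Rows are ground-truth classes pooled over all frames of all
    trajectories; rows for classes absent from the ground truth are NaN
    and excluded from the average.
    """
    gt = np.concatenate([np.asarray(g, dtype=int) for g in gt_s])
    pr = np.concatenate([np.asarray(p, dtype=int) for p in pred_s])
    counts = confusion_matrix(gt, pr, labels=list(range(N_STATES))).astype(float)
    row_sums = counts.sum(axis=1)
    conf = np.full_like(counts, np.nan)
    present = row_sums > 0
    conf[present] = counts[present] / row_sums[present, None]
    avg_acc = float(np.nanmean(np.diag(conf)))
    return conf, avg_acc


def pair_changepoints(gt: np.ndarray, pred: np.ndarray, tol: int = CP_TOLERANCE):
    """Hungarian pairing by minimum total squared distance.

    Returns ``(pairs, fn, fp)`` where ``pairs`` is a list of
    ``(t_gt, t_pred)`` true-positive pairs with ``|t_gt - t_pred| < tol``.
    """
    gt = np.asarray(gt, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if gt.size == 0 or pred.size == 0:
        return [], int(gt.size), int(pred.size)
    cost = (gt[:, None] - pred[None, :]) ** 2
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(gt[i]), int(pred[j]))
        for i, j in zip(rows, cols)
        if abs(gt[i] - pred[j]) < tol
    ]
    fn = int(gt.size - len(pairs))
    fp = int(pred.size - len(pairs))
    return pairs, fn, fp


def jaccard(tp: int, fn: int, fp: int) -> float:
    """TP / (TP + FN + FP); two empty sets agree perfectly (1.0)."""
    denom = tp + fn + fp
    if denom == 0:
        return 1.0
    return tp / denom


def cp_rmse(pairs: list[tuple[int, int]]) -> float | None:
    """RMSE over paired changepoints; None when nothing was paired."""
    if not pairs:
        return None
    sq = [(g - p) ** 2 for g, p in pairs]
    return float(np.sqrt(np.mean(sq)))


def score_changepoints(
    gt_sets: list[np.ndarray], pred_sets: list[np.ndarray], tol: int = CP_TOLERANCE
):
    """Per-trajectory Jaccard / RMSE plus their averages.

    RMSE is averaged over trajectories where at least one pair formed.
    """
    js, rmses = [], []
    for gt, pred in zip(gt_sets, pred_sets):
        pairs, fn, fp = pair_changepoints(gt, pred, tol)
        js.append(jaccard(len(pairs), fn, fp))
        r = cp_rmse(pairs)
        if r is not None:
            rmses.append(r)
    return {
        "jaccard": float(np.mean(js)) if js else np.nan,
        "cp_rmse": float(np.mean(rmses)) if rmses else np.nan,
        "per_traj_jaccard": np.array(js),
        "n_with_pairs": len(rmses),
    }


@dataclass
class MetricsReport:
    """Aggregate evaluation of pointwise predictions and changepoints."""

    mae_alpha: float | None = None
    male_K: float | None = None
    state_loss: float | None = None
    confusion: np.ndarray | None = None
    avg_class_accuracy: float | None = None
    jaccard: float | None = None
    cp_rmse: float | None = None
    breakdowns: dict[str, pd.DataFrame] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "mae_alpha": self.mae_alpha,
            "male_K": self.male_K,
            "state_loss": self.state_loss,
            "avg_class_accuracy": self.avg_class_accuracy,
            "jaccard": self.jaccard,
            "cp_rmse": self.cp_rmse,
            "metadata": self.metadata,
        }
        if self.confusion is not None:
            out["confusion"] = np.asarray(self.confusion).tolist()
        return out


def evaluate_predictions(
    gt_alpha: list[np.ndarray] | None = None,
    pred_alpha: list[np.ndarray] | None = None,
    gt_K: list[np.ndarray] | None = None,
    pred_logK: list[np.ndarray] | None = None,
    gt_state: list[np.ndarray] | None = None,
    pred_state: list[np.ndarray] | None = None,
    gt_cps: list[np.ndarray] | None = None,
    pred_cps: list[np.ndarray] | None = None,
    tol: int = CP_TOLERANCE,
) -> MetricsReport:
    """Assemble a :class:`MetricsReport` from whatever is available."""
    report = MetricsReport(metadata={"cp_tolerance": tol,
                                     "rmse_denominator": "paired changepoints"})
    if pred_alpha is not None:
        report.mae_alpha = mae(pred_alpha, gt_alpha)
    if pred_logK is not None:
        report.male_K = male(pred_logK, gt_K)
    if pred_state is not None:
        report.confusion, report.avg_class_accuracy = state_metrics(pred_state, gt_state)
    if pred_cps is not None:
        scores = score_changepoints(gt_cps, pred_cps, tol)
        report.jaccard = scores["jaccard"]
        report.cp_rmse = scores["cp_rmse"]
    return report
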