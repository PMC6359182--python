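"""Detection and pose-accuracy metrics.

Detection is scored by one-to-one matching of predicted and true fruit
centres within a distance tolerance, giving precision (true positives
over detections) and recall (true positives over true fruits).  Pose
accuracy is summarised robustly by the median angular error (MEDE) and
the median absolute deviation about it (MAD), plus the percentage of
errors under a set of angle limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DetectionEvalResult",
    "PoseErrorStats",
    "match_detections",
    "precision_recall",
    "evaluate_detections",
    "pose_stats",
    "DEFAULT_MATCH_TOL_MM",
    "DEFAULT_ANGLE_LIMITS",
]

DEFAULT_MATCH_TOL_MM = 30.0
DEFAULT_ANGLE_LIMITS = (45.0, 35.0, 25.0)


@dataclass
class DetectionEvalResult:
    n_gt_fruits: int
    n_true_positives: int
    n_false_positives: int
    n_false_negatives: int
    precision: float  # NaN when there are no detections
    recall: float  # NaN when there are no true fruits
    matching: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_gt_fruits": self.n_gt_fruits,
            "n_true_positives": self.n_true_positives,
            "n_false_positives": self.n_false_positives,
            "n_false_negatives": self.n_false_negatives,
            "precision": self.precision,
            "recall": self.recall,
        }


@dataclass
class PoseErrorStats:
    errors: np.ndarray
    mede: float
    mad: float
    freq_within: dict[float, float]  # limit (deg) -> percentage strictly below

    def to_dict(self) -> dict:
        return {
            "n": len(self.errors),
            "mede": self.mede,
            "mad": self.mad,
            "freq_within": {f"{k:g}": v for k, v in self.freq_within.items()},
        }


def match_detections(
    pred_centers: np.ndarray,
    gt_centers: np.ndarray,
    tol: float = DEFAULT_MATCH_TOL_MM,
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Greedy one-to-one nearest-pair matching within ``tol`` mm.

    Candidate pairs are taken in order of increasing centre distance, so
    the result does not depend on input ordering.  Returns
    ``(TP, FP, FN, matching)`` with ``matching`` as (pred index, truth
    index) pairs.
    """
    if tol <= 0:
        raise ValueError("matching tolerance must be positive")
    pred = np.asarray(pred_centers, dtype=np.float64).reshape(-1, 3)
    gt = np.asarray(gt_centers, dtype=np.float64).reshape(-1, 3)
    matching: list[tuple[int, int]] = []
    if len(pred) and len(gt):
        dist = cdist(pred, gt)
        order = np.argsort(dist, axis=None, kind="stable")
        used_pred: set[int] = set()
        used_gt: set[int] = set()
        for flat in order:
            i, j = divmod(int(flat), len(gt))
            if dist[i, j] > tol:
                break
            if i in used_pred or j in used_gt:
                continue
            used_pred.add(i)
            used_gt.add(j)
            matching.append((i, j))
    tp = len(matching)
    return tp, len(pred) - tp, len(gt) - tp, matching


def precision_recall(tp: int, fp: int, n_gt: int) -> tuple[float, float]:
    """Precision = TP/(TP+FP); recall = TP/n_gt; 0/0 reported as NaN."""
    if tp < 0 or fp < 0 or n_gt < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / n_gt if n_gt > 0 else float("nan")
    return precision, recall


def evaluate_detections(
    pred_centers: np.ndarray,
    gt_centers: np.ndarray,
    tol: float = DEFAULT_MATCH_TOL_MM,
) -> DetectionEvalResult:
    """Match centres and report counts with precision/recall."""
    tp, fp, fn, matching = match_detections(pred_centers, gt_centers, tol)
    prec, rec = precision_recall(tp, fp, tp + fn)
    return DetectionEvalResult(
        n_gt_fruits=tp + fn,
        n_true_positives=tp,
        n_false_positives=fp,
        n_false_negatives=fn,
        precision=prec,
        recall=rec,
        matching=matching,
    )


def pose_stats(
    errors: np.ndarray, limits: tuple[float, ...] = DEFAULT_ANGLE_LIMITS
) -> PoseErrorStats:
    """Robust summary of pose angular errors (degrees).

    MEDE = median of the errors; MAD = median of |error - MEDE|;
    ``freq_within[L]`` = percentage of errors strictly below L degrees.
    Medians of even-length lists are the mean of the two central values.
    """
    err = np.asarray(errors, dtype=np.float64).reshape(-1)
    if len(err) == 0:
        raise ValueError("pose_stats requires at least one error value")
    mede = float(np.median(err))
    mad = float(np.median(np.abs(err - mede)))
    freq = {float(L): float(100.0 * np.count_nonzero(err < L) / len(err)) for L in limits}
    return PoseErrorStats(errors=err, mede=mede, mad=mad, freq_within=freq)
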