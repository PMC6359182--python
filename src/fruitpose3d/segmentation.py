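"""Three-class segmentation interface and pixel-wise quality metrics.

The pipeline consumes a per-pixel class map with codes 0 background,
1 fruit, 2 branch.  Any external segmenter (e.g. a trained network) can
supply the map; a simple colour-rule baseline is provided so the full
pipeline runs without one.  Quality is scored per class by mean accuracy
``n_ii / t_i`` and intersection-over-union
``n_ii / (t_i + sum_j n_ji - n_ii)`` computed from the 3x3 confusion
matrix of pixel counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .core_geometry import LABEL_BACKGROUND, LABEL_BRANCH, LABEL_FRUIT

__all__ = [
    "SegmentationMap",
    "ConfusionMatrix",
    "BaselineSegmenterConfig",
    "segment_baseline",
    "confusion",
    "class_metrics",
    "NUM_CLASSES",
]

NUM_CLASSES = 3
CLASS_NAMES = ("background", "fruit", "branch")


@dataclass
class SegmentationMap:
    """A 2D map of class ids in {0 background, 1 fruit, 2 branch}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels, dtype=np.int64)
        if arr.ndim != 2:
            raise ValueError("segmentation map must be 2D")
        if arr.size and (arr.min() < 0 or arr.max() >= NUM_CLASSES):
            raise ValueError(f"label codes must lie in [0, {NUM_CLASSES - 1}]")
        self.labels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_mask(self, class_id: int) -> np.ndarray:
        """Binary plane of one class (e.g. the fruit or branch map)."""
        return self.labels == class_id


@dataclass
class ConfusionMatrix:
    """Pixel counts ``n[i, j]`` = true class i predicted as class j."""

    n: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.n, dtype=np.int64)
        if arr.shape != (NUM_CLASSES, NUM_CLASSES):
            raise ValueError(f"confusion matrix must be {NUM_CLASSES}x{NUM_CLASSES}")
        if (arr < 0).any():
            raise ValueError("confusion counts must be non-negative")
        self.n = arr

    @property
    def ti(self) -> np.ndarray:
        """Per-class true pixel counts (row sums)."""
        return self.n.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.n.sum())


@dataclass(frozen=True)
class BaselineSegmenterConfig:
    """Hue/saturation/value bands for the colour-rule baseline.

    A pixel is classified fruit if its hue falls in ``fruit_hue`` (a
    circular interval: lo > hi wraps through 1.0) with saturation and
    value above the floors; branch likewise with ``branch_hue``; anything
    else is background.  Defaults match red fruit on green branches.
    """

    fruit_hue: tuple[float, float] = (0.90, 0.10)
    branch_hue: tuple[float, float] = (0.18, 0.45)
    min_saturation: float = 0.25
    min_value: float = 0.10

    def __post_init__(self) -> None:
        for name in ("fruit_hue", "branch_hue"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= 1 and 0 <= hi <= 1):
                raise ValueError(f"{name} bounds must lie in [0, 1]")
        if not (0 <= self.min_saturation <= 1 and 0 <= self.min_value <= 1):
            raise ValueError("saturation/value floors must lie in [0, 1]")


def _hue_in_band(hue: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    if lo <= hi:
        return (hue >= lo) & (hue <= hi)
    return (hue >= lo) | (hue <= hi)  # wrap-around interval


def segment_baseline(
    rgb: np.ndarray, config: BaselineSegmenterConfig | None = None
) -> SegmentationMap:
    """Classify each pixel by colour rules into background/fruit/branch.

    A deterministic stand-in for a learned segmenter; externally produced
    maps plug into the same :class:`SegmentationMap` interface.
    """
    if config is None:
        config = BaselineSegmenterConfig()
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("segment_baseline expects a 3-channel RGB image")
    hsv = rgb2hsv(rgb[..., :3])
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    vivid = (sat >= config.min_saturation) & (val >= config.min_value)
    out = np.full(rgb.shape[:2], LABEL_BACKGROUND, dtype=np.int64)
    out[vivid & _hue_in_band(hue, config.branch_hue)] = LABEL_BRANCH
    out[vivid & _hue_in_band(hue, config.fruit_hue)] = LABEL_FRUIT
    return SegmentationMap(out)


def confusion(pred: SegmentationMap, truth: SegmentationMap) -> ConfusionMatrix:
    """Count pixels per (true class, predicted class) pair."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    idx = truth.labels.ravel() * NUM_CLASSES + pred.labels.ravel()
    counts = np.bincount(idx, minlength=NUM_CLASSES * NUM_CLASSES)
    return ConfusionMatrix(counts.reshape(NUM_CLASSES, NUM_CLASSES))


def class_metrics(cm: ConfusionMatrix) -> dict:
    """Per-class mean accuracy and IOU, plus unweighted means.

    Classes absent from the ground truth (``t_i = 0``) are reported as
    NaN and excluded from the means.
    """
    n = cm.n.astype(np.float64)
    nii = np.diag(n)
    ti = n.sum(axis=1)
    col = n.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        accuracy = np.where(ti > 0, nii / ti, np.nan)
        denom = ti + col - nii
        iou = np.where(ti > 0, np.where(denom > 0, nii / denom, 0.0), np.nan)
    defined = ti > 0
    per_class = {
        CLASS_NAMES[i]: {"accuracy": float(accuracy[i]), "iou": float(iou[i])}
        for i in range(NUM_CLASSES)
    }
    return {
        "per_class": per_class,
        "mean_accuracy": float(np.nanmean(accuracy)) if defined.any() else float("nan"),
        "mean_iou": float(np.nanmean(iou)) if defined.any() else float("nan"),
    }
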