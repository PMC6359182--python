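"""Pinhole camera model and depth-pixel <-> 3D conversions.

All geometry in this package lives in the camera frame, in millimetres:
``x`` right, ``y`` down (image row direction), ``z`` along the optical
axis.  A depth image stores, per pixel, the ``z`` coordinate of the
surface seen through that pixel; the value 0 marks "no measurement".
Back-projection of a pixel ``(u, v)`` with depth ``z`` is

    x = z * (u - Ux) / fx,   y = z * (v - Uy) / fy,

the standard pinhole relation for an already-aligned RGB-D frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "DepthImage",
    "LabeledPointCloud",
    "backproject",
    "project",
    "LABEL_BACKGROUND",
    "LABEL_FRUIT",
    "LABEL_BRANCH",
]

LABEL_BACKGROUND = 0
LABEL_FRUIT = 1
LABEL_BRANCH = 2

#: Default closest usable sensor-to-scene distance, mm.
DEFAULT_MIN_RANGE_MM = 550.0


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole parameters of the depth camera.

    Parameters
    ----------
    fx, fy:
        Focal lengths in pixel units.
    ux, uy:
        Principal point (column, row) in pixels, 0-based.
    min_range_mm:
        Closest distance at which depth readings are trusted; readings
        below it are kept but trigger a warning on load.
    """

    fx: float
    fy: float
    ux: float
    uy: float
    min_range_mm: float = DEFAULT_MIN_RANGE_MM

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")
        if not (np.isfinite(self.ux) and np.isfinite(self.uy)):
            raise ValueError("principal point must be finite")

    def to_dict(self) -> dict:
        return {
            "fx": float(self.fx),
            "fy": float(self.fy),
            "ux": float(self.ux),
            "uy": float(self.uy),
            "min_range_mm": float(self.min_range_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(
            fx=float(d["fx"]),
            fy=float(d["fy"]),
            ux=float(d["ux"]),
            uy=float(d["uy"]),
            min_range_mm=float(d.get("min_range_mm", DEFAULT_MIN_RANGE_MM)),
        )


@dataclass
class DepthImage:
    """A single-channel range image in millimetres.

    ``values[v, u]`` is the z-coordinate of the surface at pixel
    ``(u, v)``; 0 means no measurement.  NaN or negative inputs are
    mapped to 0 on construction.
    """

    values: np.ndarray
    min_range_mm: float = DEFAULT_MIN_RANGE_MM

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"depth image must be 2D, got shape {v.shape}")
        v = np.where(np.isfinite(v) & (v > 0), v, 0.0)
        self.values = v
        valid = v > 0
        if valid.any() and (v[valid] < self.min_range_mm).any():
            warnings.warn(
                f"depth values below the minimum range of {self.min_range_mm:g} mm are present",
                stacklevel=2,
            )

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean map of pixels with a measurement."""
        return self.values > 0


@dataclass
class LabeledPointCloud:
    """3D points (mm) with their source pixels and class labels.

    ``points`` is (n, 3); ``pixel_index`` is (n, 2) as (u, v) columns;
    ``label`` is (n,) with codes 0 background / 1 fruit / 2 branch.
    """

    points: np.ndarray
    pixel_index: np.ndarray
    label: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.pixel_index = np.asarray(self.pixel_index, dtype=np.int64).reshape(-1, 2)
        n = len(self.points)
        if self.label is None:
            self.label = np.zeros(n, dtype=np.int64)
        self.label = np.asarray(self.label, dtype=np.int64).reshape(-1)
        if not (len(self.pixel_index) == n and len(self.label) == n):
            raise ValueError("points, pixel_index and label must have equal length")
        if n and not (self.points[:, 2] > 0).all():
            raise ValueError("all cloud points must have z > 0")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask: np.ndarray) -> "LabeledPointCloud":
        """Subset of the cloud by boolean mask or index array."""
        return LabeledPointCloud(self.points[mask], self.pixel_index[mask], self.label[mask])


def backproject(
    depth: DepthImage,
    intr: CameraIntrinsics,
    mask: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> LabeledPointCloud:
    """Convert depth pixels to a 3D point cloud.

    Parameters
    ----------
    depth:
        The range image; pixels with value 0 are skipped.
    intr:
        Camera intrinsics.
    mask:
        Optional boolean map restricting which pixels are converted.
    labels:
        Optional per-pixel class map copied onto the emitted points.

    Returns
    -------
    LabeledPointCloud
        One point per selected valid pixel, in row-major pixel order.
    """
    select = depth.valid_mask
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != depth.values.shape:
            raise ValueError("mask shape must match the depth image")
        select = select & mask
    vv, uu = np.nonzero(select)  # row-major order
    z = depth.values[vv, uu]
    x = z * (uu - intr.ux) / intr.fx
    y = z * (vv - intr.uy) / intr.fy
    pts = np.column_stack([x, y, z])
    pix = np.column_stack([uu, vv])
    lab = None
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape != depth.values.shape:
            raise ValueError("label map shape must match the depth image")
        lab = labels[vv, uu].astype(np.int64)
    return LabeledPointCloud(pts, pix, lab)


def project(points: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Project 3D points (mm) to continuous pixel coordinates.

    Returns an array of ``(u, v, z)`` rows; inverse of :func:`backproject`
    on pixel centres.  Raises for any point with ``z <= 0``.
    """
    pts = np.asarray(points, dtype=np.float64)
    single = pts.ndim == 1
    pts = pts.reshape(-1, 3)
    z = pts[:, 2]
    if (z <= 0).any():
        raise ValueError("cannot project points with z <= 0")
    u = intr.fx * pts[:, 0] / z + intr.ux
    v = intr.fy * pts[:, 1] / z + intr.uy
    out = np.column_stack([u, v, z])
    return out[0] if single else out
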