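"""File I/O: 16-bit depth PNG, 8-bit label PNG, RGB PNG, ASCII PLY, intrinsics YAML/JSON."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .core_geometry import CameraIntrinsics, DepthImage, LabeledPointCloud

__all__ = [
    "read_depth_png",
    "write_depth_png",
    "read_label_png",
    "write_label_png",
    "read_rgb_png",
    "write_rgb_png",
    "read_intrinsics",
    "write_intrinsics",
    "write_ply",
    "read_ply",
]


def write_depth_png(path: str | Path, depth: DepthImage | np.ndarray) -> None:
    """Store depth as 16-bit single-channel PNG, value = millimetres (rounded)."""
    values = depth.values if isinstance(depth, DepthImage) else np.asarray(depth)
    out = np.clip(np.rint(values), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    iio.imwrite(Path(path), out)


def read_depth_png(path: str | Path, min_range_mm: float | None = None) -> DepthImage:
    arr = iio.imread(Path(path)).astype(np.float64)
    if arr.ndim != 2:
        raise ValueError(f"depth PNG must be single-channel, got shape {arr.shape}")
    kwargs = {} if min_range_mm is None else {"min_range_mm": min_range_mm}
    return DepthImage(arr, **kwargs)


def write_label_png(path: str | Path, labels: np.ndarray) -> None:
    """Store a class-id map as 8-bit PNG with codes {0, 1, 2}."""
    arr = np.asarray(labels)
    if arr.ndim != 2:
        raise ValueError("label map must be 2D")
    iio.imwrite(Path(path), arr.astype(np.uint8))


def read_label_png(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"label PNG must be single-channel, got shape {arr.shape}")
    return arr.astype(np.int64)


def write_rgb_png(path: str | Path, rgb: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(rgb, dtype=np.uint8))


def read_rgb_png(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"expected a 3-channel RGB PNG, got shape {arr.shape}")
    return arr[..., :3]


def write_intrinsics(path: str | Path, intr: CameraIntrinsics) -> None:
    """Serialize intrinsics; format chosen by extension (.json or YAML)."""
    path = Path(path)
    d = intr.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def read_intrinsics(path: str | Path) -> CameraIntrinsics:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return CameraIntrinsics.from_dict(d)


def write_ply(path: str | Path, cloud: LabeledPointCloud) -> None:
    """Write an ASCII PLY with per-vertex ``x y z label`` (mm)."""
    n = len(cloud)
    header = (
        "ply\nformat ascii 1.0\n"
        f"element vertex {n}\n"
        "property float x\nproperty float y\nproperty float z\n"
        "property uchar label\n"
        "end_header\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for (x, y, z), lab in zip(cloud.points, cloud.label):
            fh.write(f"{x:.4f} {y:.4f} {z:.4f} {int(lab)}\n")


def read_ply(path: str | Path) -> LabeledPointCloud:
    """Read an ASCII PLY written by :func:`write_ply`."""
    lines = Path(path).read_text().splitlines()
    try:
        start = lines.index("end_header") + 1
    except ValueError as exc:
        raise ValueError("not an ASCII PLY file (missing end_header)") from exc
    pts, labs = [], []
    for line in lines[start:]:
        if not line.strip():
            continue
        x, y, z, lab = line.split()
        pts.append((float(x), float(y), float(z)))
        labs.append(int(lab))
    pts_arr = np.asarray(pts, dtype=np.float64).reshape(-1, 3)
    pix = np.zeros((len(pts_arr), 2), dtype=np.int64)  # source pixels not stored in PLY
    return LabeledPointCloud(pts_arr, pix, np.asarray(labs, dtype=np.int64))
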