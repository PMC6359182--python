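"""Individual fruit extraction from a labelled point cloud.

Fruits are isolated by Euclidean clustering: two points belong to the
same fruit iff they are connected by a chain of hops each no longer than
a distance threshold (default 4 mm, a value small enough to keep
adjacent fruits apart at typical sensing ranges).  Each cluster's centre
is estimated either as the member mean ("bounding box" method) or as
the centre of a least-squares sphere fit; a RANSAC sphere fit is also
provided for robust centre estimation on hand-labelled data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core_geometry import LABEL_FRUIT, LabeledPointCloud

__all__ = [
    "ClusterParams",
    "Sphere",
    "FruitDetection",
    "DegenerateFitError",
    "RansacFailure",
    "euclidean_cluster",
    "center_bounding_box",
    "fit_sphere_lsq",
    "fit_sphere_ransac",
    "detect_fruits",
]


class DegenerateFitError(ValueError):
    """Sphere fit impossible: too few points or a rank-deficient design."""


class RansacFailure(RuntimeError):
    """No consensus sphere model found."""


@dataclass(frozen=True)
class ClusterParams:
    """Euclidean clustering parameters.

    ``distance_threshold`` is the hop radius in mm; ``min_cluster_size``
    discards speckle clusters that a pixel-wise segmenter inevitably
    produces.
    """

    distance_threshold: float = 4.0
    min_cluster_size: int = 30

    def __post_init__(self) -> None:
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be positive")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")
        if not np.all(np.isfinite(self.center)):
            raise ValueError("sphere center must be finite")

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=np.float64)


@dataclass
class FruitDetection:
    """One clustered fruit with its centre estimate."""

    member_indices: np.ndarray
    center: np.ndarray
    center_method: str  # "bounding_box" or "sphere_fit"
    sphere: Sphere | None = None
    fallback: bool = field(default=False)  # sphere fit degenerated to bounding box

    @property
    def n_points(self) -> int:
        return len(self.member_indices)

    def to_dict(self) -> dict:
        d = {
            "n_points": self.n_points,
            "center": [float(c) for c in self.center],
            "center_method": self.center_method,
            "fallback": bool(self.fallback),
        }
        if self.sphere is not None:
            d["sphere"] = {
                "center": [float(c) for c in self.sphere.center],
                "radius": float(self.sphere.radius),
            }
        return d


def euclidean_cluster(
    points: np.ndarray | LabeledPointCloud, params: ClusterParams | None = None
) -> list[np.ndarray]:
    """Partition points into clusters of radius-connected components.

    Exact radius search on a kd-tree; the resulting partition is
    identical to connected components of the graph with an edge between
    every pair of points at distance <= ``distance_threshold``.  Clusters
    below ``min_cluster_size`` are dropped.  Output is ordered by
    descending size, ties broken by smallest member index.
    """
    if params is None:
        params = ClusterParams()
    pts = points.points if isinstance(points, LabeledPointCloud) else np.asarray(points, float)
    pts = pts.reshape(-1, 3)
    if len(pts) == 0:
        return []
    tree = cKDTree(pts)
    pairs = tree.query_pairs(params.distance_threshold, output_type="ndarray")
    n = len(pts)
    if len(pairs):
        data = np.ones(len(pairs), dtype=np.int8)
        adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        _, comp = connected_components(adj, directed=False)
    else:
        comp = np.arange(n)
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(comp):
        clusters.setdefault(int(c), []).append(i)
    out = [np.asarray(v, dtype=np.int64) for v in clusters.values()]
    out = [c for c in out if len(c) >= params.min_cluster_size]
    out.sort(key=lambda c: (-len(c), int(c[0])))
    return out


def center_bounding_box(cluster_points: np.ndarray) -> np.ndarray:
    """Fruit centre as the arithmetic mean of the cluster's points."""
    pts = np.asarray(cluster_points, dtype=np.float64).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("cannot compute the centre of an empty cluster")
    return pts.mean(axis=0)


def _sphere_design(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # ||x||^2 = 2 c.x + (r^2 - ||c||^2): linear in (c, k)
    a = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    return a, b


def _solve_sphere(pts: np.ndarray) -> Sphere:
    a, b = _sphere_design(pts)
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 4:
        raise DegenerateFitError("coplanar or collinear points: sphere fit is rank-deficient")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0 or not np.isfinite(r2):
        raise DegenerateFitError("sphere fit produced a non-positive radius")
    return Sphere(tuple(center), float(np.sqrt(r2)))


def fit_sphere_lsq(cluster_points: np.ndarray) -> Sphere:
    """Algebraic linear least-squares sphere fit.

    Solves ``||x||^2 = 2 c.x + (r^2 - ||c||^2)`` for centre ``c`` and
    radius ``r``.  Exact sphere samples are recovered to numerical
    precision.  Raises :class:`DegenerateFitError` for < 4 points or a
    coplanar/collinear configuration; callers fall back to the
    bounding-box centre.
    """
    pts = np.asarray(cluster_points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 4:
        raise DegenerateFitError(f"sphere fit needs >= 4 points, got {len(pts)}")
    return _solve_sphere(pts)


def fit_sphere_ransac(
    points: np.ndarray,
    inlier_threshold: float = 5.0,
    iterations: int = 1000,
    seed: int | np.random.Generator = 0,
    radius_bounds: tuple[float, float] | None = None,
) -> Sphere:
    """Consensus sphere fit robust to gross outliers.

    Repeatedly fits a sphere to 4 random points, keeps the model with
    the most surface inliers (|distance to surface| <= threshold), and
    refits by least squares on those inliers.  ``radius_bounds`` is an
    optional (lo, hi) prior on plausible fruit radii: candidate models
    outside it are rejected, so a structureless cloud is reported as a
    failure instead of a chance 4-point sphere.  Deterministic given the
    seed.  Raises :class:`RansacFailure` if no admissible model gathers
    more than 4 inliers (strictly more than its own minimal sample).
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 4:
        raise DegenerateFitError(f"sphere fit needs >= 4 points, got {len(pts)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    min_support = 4 if radius_bounds is None else 5
    best_count = 0
    best_inliers: np.ndarray | None = None
    for _ in range(iterations):
        sample = rng.choice(len(pts), size=4, replace=False)
        try:
            model = _solve_sphere(pts[sample])
        except DegenerateFitError:
            continue
        if radius_bounds is not None and not (
            radius_bounds[0] <= model.radius <= radius_bounds[1]
        ):
            continue
        dist = np.abs(np.linalg.norm(pts - model.center_array, axis=1) - model.radius)
        inliers = dist <= inlier_threshold
        count = int(inliers.sum())
        if count > best_count:
            best_count = count
            best_inliers = inliers
    if best_inliers is None or best_count < min_support:
        raise RansacFailure("no sphere model reached the minimum inlier support")
    return fit_sphere_lsq(pts[best_inliers])


def detect_fruits(
    cloud: LabeledPointCloud,
    params: ClusterParams | None = None,
    center_method: str = "bounding_box",
    ransac_seed: int = 0,
) -> list[FruitDetection]:
    """Cluster the fruit-labelled points and estimate a centre per cluster.

    ``center_method`` is one of ``bounding_box``, ``sphere_fit`` or
    ``sphere_ransac``; sphere fits fall back to the bounding-box centre
    on degenerate clusters (flagged on the detection).
    ``member_indices`` index into the fruit-labelled sub-cloud
    (``cloud.select(cloud.label == 1)``).
    """
    if params is None:
        params = ClusterParams()
    if center_method not in ("bounding_box", "sphere_fit", "sphere_ransac"):
        raise ValueError(f"unknown center_method {center_method!r}")
    fruit_cloud = cloud.select(cloud.label == LABEL_FRUIT)
    clusters = euclidean_cluster(fruit_cloud.points, params)
    detections: list[FruitDetection] = []
    for idx in clusters:
        pts = fruit_cloud.points[idx]
        sphere = None
        fallback = False
        if center_method == "bounding_box":
            center = center_bounding_box(pts)
        else:
            try:
                if center_method == "sphere_fit":
                    sphere = fit_sphere_lsq(pts)
                else:
                    sphere = fit_sphere_ransac(pts, seed=ransac_seed)
                center = sphere.center_array
            except (DegenerateFitError, RansacFailure):
                center = center_bounding_box(pts)
                fallback = True
        detections.append(
            FruitDetection(
                member_indices=idx,
                center=center,
                center_method=center_method,
                sphere=sphere,
                fallback=fallback,
            )
        )
    return detections
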