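"""Branch-relative fruit pose.

A fruit's pose is the unit vector from the nearest point of its mother
branch to the fruit centre.  The mother branch is the reconstructed
line segment whose infinite line is nearest to the centre,

    j = argmin_k || (c - p_k) - ((c - p_k).t_k) t_k ||,

the nearest branch point is the orthogonal projection
``n = p_j + ((c - p_j).t_j) t_j``, and the pose ``q = (c - n)/||c - n||``
is perpendicular to the branch axis by construction — an approach
direction along which a gripper does not collide with the branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .branch_reconstruction import LineSegment3D
from .fruit_detection import FruitDetection

__all__ = [
    "FruitPose",
    "DegeneratePoseError",
    "assign_mother_branch",
    "estimate_pose",
    "pose_error",
    "estimate_all_poses",
]

#: Fruit centres closer than this to the axis (mm) have no defined pose.
DEGENERACY_TOL_MM = 1e-6


class DegeneratePoseError(ValueError):
    """The fruit centre lies on the branch axis; the pose is undefined."""


@dataclass
class FruitPose:
    """Pose of one fruit relative to its mother branch."""

    fruit_id: int
    center: np.ndarray
    branch_index: int
    nearest_point: np.ndarray
    pose: np.ndarray  # unit vector, perpendicular to the mother branch
    distance_to_branch: float

    def to_dict(self) -> dict:
        return {
            "fruit_id": int(self.fruit_id),
            "center": [float(v) for v in self.center],
            "branch_index": int(self.branch_index),
            "nearest_point": [float(v) for v in self.nearest_point],
            "pose": [float(v) for v in self.pose],
            "distance_to_branch": float(self.distance_to_branch),
        }


def _segment_distance(center: np.ndarray, seg: LineSegment3D, clamp: bool) -> float:
    d = center - seg.anchor
    s = float(d @ seg.direction)
    if clamp:
        s = min(max(s, seg.extent[0]), seg.extent[1])
    return float(np.linalg.norm(d - s * seg.direction))


def assign_mother_branch(
    center: np.ndarray, segments: list[LineSegment3D], clamp_to_extent: bool = False
) -> int:
    """Index of the nearest branch segment to a fruit centre.

    By default the distance is to the infinite line of each segment;
    with ``clamp_to_extent`` the projection is clipped to the segment's
    inlier extent, which avoids adopting a far-away collinear segment.
    Ties go to the smallest index.  Raises ``ValueError`` when no
    segments exist (the caller records the fruit as unposed).
    """
    if not segments:
        raise ValueError("no branch segments available")
    c = np.asarray(center, dtype=np.float64).reshape(3)
    dists = [_segment_distance(c, seg, clamp_to_extent) for seg in segments]
    return int(np.argmin(dists))  # argmin takes the first minimum: smallest index wins ties


def estimate_pose(
    center: np.ndarray, segment: LineSegment3D, fruit_id: int = 0, branch_index: int = 0
) -> FruitPose:
    """Nearest branch point and unit pose vector for one fruit.

    Raises :class:`DegeneratePoseError` when the centre lies on the
    branch axis (within 1e-6 mm), where the direction is undefined.
    """
    c = np.asarray(center, dtype=np.float64).reshape(3)
    p, t = segment.anchor, segment.direction
    nearest = p + ((c - p) @ t) * t
    offset = c - nearest
    dist = float(np.linalg.norm(offset))
    if dist <= DEGENERACY_TOL_MM:
        raise DegeneratePoseError("fruit centre lies on the branch axis")
    return FruitPose(
        fruit_id=fruit_id,
        center=c,
        branch_index=branch_index,
        nearest_point=nearest,
        pose=offset / dist,
        distance_to_branch=dist,
    )


def pose_error(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Angle in degrees between an estimated and a reference pose vector.

    ``acos`` of the normalised dot product, clamped against rounding, so
    the result is always in [0, 180] and never NaN for non-zero inputs.
    """
    a = np.asarray(estimated, dtype=np.float64).reshape(3)
    b = np.asarray(truth, dtype=np.float64).reshape(3)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("pose vectors must be non-zero")
    cos = np.clip((a @ b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def estimate_all_poses(
    detections: list[FruitDetection],
    segments: list[LineSegment3D],
    clamp_to_extent: bool = False,
) -> tuple[list[FruitPose], list[int]]:
    """Pose for every detection that has a resolvable mother branch.

    Returns ``(poses, unposed_ids)``: fruits facing an empty segment
    list or a degenerate geometry are listed by id rather than raising,
    mirroring field conditions where a mother branch may be invisible.
    """
    poses: list[FruitPose] = []
    unposed: list[int] = []
    for fruit_id, det in enumerate(detections):
        if not segments:
            unposed.append(fruit_id)
            continue
        j = assign_mother_branch(det.center, segments, clamp_to_extent=clamp_to_extent)
        try:
            poses.append(estimate_pose(det.center, segments[j], fruit_id=fruit_id, branch_index=j))
        except DegeneratePoseError:
            unposed.append(fruit_id)
    return poses, unposed
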