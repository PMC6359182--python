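"""Synthetic orchard scenes with exact ground truth.

Scenes are built from cylindrical branches with spherical fruits held
off the branch surface by a short pedicel, always perpendicular to the
branch axis — so the true fruit centre, mother branch, attachment point
and pose vector are known by construction.  The scene is rendered to an
aligned depth + label frame by per-pixel ray casting (analytic
ray-sphere and ray-finite-cylinder intersection, nearest hit wins),
with optional Gaussian noise on the depth channel.  Every stage of the
detection pipeline can therefore be verified end-to-end without field
data.

The stored depth at a hit pixel is the z-coordinate of the hit point
(the convention of real depth cameras), not the Euclidean ray length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core_geometry import (
    LABEL_BRANCH,
    LABEL_FRUIT,
    CameraIntrinsics,
    DepthImage,
)
from .segmentation import SegmentationMap

__all__ = [
    "BranchSpec",
    "FruitSpec",
    "SceneSpec",
    "FruitTruth",
    "BranchTruth",
    "RenderedScene",
    "build_scene",
    "render",
    "make_fixture",
    "PRESETS",
    "DEFAULT_CAMERA",
]

#: Plausible depth-camera intrinsics for a 512x424 time-of-flight frame.
DEFAULT_CAMERA = CameraIntrinsics(fx=365.0, fy=365.0, ux=256.0, uy=212.0)
DEFAULT_WIDTH = 512
DEFAULT_HEIGHT = 424

#: Per-class colours for the RGB preview (fruit red, branch green).
PREVIEW_COLORS = {0: (0, 0, 0), LABEL_FRUIT: (200, 40, 40), LABEL_BRANCH: (60, 160, 60)}


@dataclass(frozen=True)
class BranchSpec:
    """A finite cylinder: ``anchor + s*axis`` for s in [0, length]."""

    anchor: tuple[float, float, float]
    axis: tuple[float, float, float]
    length: float
    radius: float


@dataclass(frozen=True)
class FruitSpec:
    """A sphere attached to a branch, perpendicular to its axis.

    The centre sits at ``attach_s`` mm along the mother axis, offset by
    branch radius + pedicel length + fruit radius in ``offset_dir``.
    """

    branch: int
    offset_dir: tuple[float, float, float]
    pedicel: float
    radius: float
    attach_s: float = 0.0


@dataclass(frozen=True)
class SceneSpec:
    branches: tuple[BranchSpec, ...]
    fruits: tuple[FruitSpec, ...]
    camera: CameraIntrinsics = DEFAULT_CAMERA
    width: int = DEFAULT_WIDTH
    height: int = DEFAULT_HEIGHT
    noise_sigma: float = 0.0
    seed: int = 0


@dataclass
class FruitTruth:
    center: np.ndarray
    pose: np.ndarray
    mother_branch: int
    nearest_point: np.ndarray
    radius: float


@dataclass
class BranchTruth:
    anchor: np.ndarray
    direction: np.ndarray
    extent: tuple[float, float]
    radius: float


@dataclass
class Scene:
    spec: SceneSpec
    fruit_truth: list[FruitTruth]
    branch_truth: list[BranchTruth]


@dataclass
class RenderedScene:
    depth: DepthImage
    labels: SegmentationMap
    rgb: np.ndarray
    scene: Scene

    @property
    def fruit_truth(self) -> list[FruitTruth]:
        return self.scene.fruit_truth

    @property
    def branch_truth(self) -> list[BranchTruth]:
        return self.scene.branch_truth


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n


def perpendicular_offset(axis, toward) -> tuple[float, float, float]:
    """Unit vector perpendicular to ``axis``, as close as possible to ``toward``."""
    w = _unit(axis)
    v = np.asarray(toward, dtype=np.float64)
    perp = v - (v @ w) * w
    return tuple(_unit(perp))


def build_scene(spec: SceneSpec) -> Scene:
    """Resolve a scene spec into geometry plus per-object ground truth."""
    branch_truth = []
    for b in spec.branches:
        if b.length <= 0 or b.radius <= 0:
            raise ValueError("branch length and radius must be positive")
        branch_truth.append(
            BranchTruth(
                anchor=np.asarray(b.anchor, dtype=np.float64),
                direction=_unit(b.axis),
                extent=(0.0, float(b.length)),
                radius=float(b.radius),
            )
        )
    fruit_truth = []
    for f in spec.fruits:
        if f.radius <= 0 or f.pedicel < 0:
            raise ValueError("fruit radius must be positive and pedicel non-negative")
        branch = branch_truth[f.branch]
        offset = np.asarray(f.offset_dir, dtype=np.float64)
        if abs(np.linalg.norm(offset) - 1.0) > 1e-9:
            raise ValueError("fruit offset direction must be a unit vector")
        if abs(offset @ branch.direction) > 1e-9:
            raise ValueError("fruit offset direction must be perpendicular to the branch axis")
        attach = branch.anchor + f.attach_s * branch.direction
        center = attach + (branch.radius + f.pedicel + f.radius) * offset
        fruit_truth.append(
            FruitTruth(
                center=center,
                pose=offset.copy(),
                mother_branch=f.branch,
                nearest_point=attach,
                radius=float(f.radius),
            )
        )
    for t in fruit_truth:
        if t.center[2] - t.radius <= 0:
            raise ValueError("fruit must lie entirely in front of the camera")
    for t in branch_truth:
        for end in t.extent:
            if (t.anchor + end * t.direction)[2] - t.radius <= 0:
                raise ValueError("branch must lie entirely in front of the camera")
    return Scene(spec=spec, fruit_truth=fruit_truth, branch_truth=branch_truth)


def _raycast_spheres(d: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Smallest positive ray parameter per pixel per sphere (inf for a miss)."""
    a = np.einsum("hwk,hwk->hw", d, d)
    hits = np.full((len(centers),) + d.shape[:2], np.inf)
    for i, (c, r) in enumerate(zip(centers, radii)):
        b = -2.0 * np.einsum("hwk,k->hw", d, c)
        cc = c @ c - r * r
        disc = b * b - 4.0 * a * cc
        ok = disc >= 0
        sqrt_disc = np.sqrt(np.where(ok, disc, 0.0))
        s = (-b - sqrt_disc) / (2.0 * a)
        s_far = (-b + sqrt_disc) / (2.0 * a)
        s = np.where(s > 0, s, s_far)  # camera inside: take the far root
        hits[i] = np.where(ok & (s > 0), s, np.inf)
    return hits


def _raycast_cylinders(d: np.ndarray, branches: list[BranchTruth]) -> np.ndarray:
    """Smallest positive ray parameter per pixel per finite cylinder."""
    hits = np.full((len(branches),) + d.shape[:2], np.inf)
    for i, br in enumerate(branches):
        w = br.direction
        a0 = br.anchor
        lo, hi = br.extent
        dw = np.einsum("hwk,k->hw", d, w)
        dp = d - dw[..., None] * w
        mp = -(a0 - (a0 @ w) * w)  # ray origin (0) minus axis foot
        a = np.einsum("hwk,hwk->hw", dp, dp)
        b = 2.0 * np.einsum("hwk,k->hw", dp, mp)
        c = mp @ mp - br.radius**2
        disc = b * b - 4.0 * a * c
        ok = (disc >= 0) & (a > 1e-12)
        sqrt_disc = np.sqrt(np.where(ok, disc, 0.0))
        safe_a = np.where(a > 1e-12, a, 1.0)
        best = np.full(d.shape[:2], np.inf)
        for sign in (-1.0, 1.0):
            s = (-b + sign * sqrt_disc) / (2.0 * safe_a)
            h = s * dw - (a0 @ w)  # axial coordinate of the hit
            valid = ok & (s > 0) & (h >= lo) & (h <= hi)
            best = np.where(valid & (s < best), s, best)
        hits[i] = best
    return hits


def render(spec_or_scene: SceneSpec | Scene) -> RenderedScene:
    """Ray-cast the scene to aligned depth, label and RGB-preview images.

    Nearest hit wins per pixel (z-buffer); pixels with no hit get depth
    0 and the background label.  Gaussian depth noise of
    ``spec.noise_sigma`` mm is then added to valid pixels (seeded,
    clipped to stay positive).
    """
    scene = spec_or_scene if isinstance(spec_or_scene, Scene) else build_scene(spec_or_scene)
    spec = scene.spec
    intr = spec.camera
    uu, vv = np.meshgrid(np.arange(spec.width), np.arange(spec.height))
    d = np.stack(
        [(uu - intr.ux) / intr.fx, (vv - intr.uy) / intr.fy, np.ones_like(uu, dtype=float)],
        axis=-1,
    )
    zbuf = np.full((spec.height, spec.width), np.inf)
    labels = np.zeros((spec.height, spec.width), dtype=np.int64)
    if scene.fruit_truth:
        centers = np.array([t.center for t in scene.fruit_truth])
        radii = np.array([t.radius for t in scene.fruit_truth])
        for s in _raycast_spheres(d, centers, radii):
            closer = s < zbuf
            zbuf = np.where(closer, s, zbuf)
            labels = np.where(closer, LABEL_FRUIT, labels)
    if scene.branch_truth:
        for s in _raycast_cylinders(d, scene.branch_truth):
            closer = s < zbuf
            zbuf = np.where(closer, s, zbuf)
            labels = np.where(closer, LABEL_BRANCH, labels)
    # ray parameter s equals the hit z-coordinate because d_z == 1
    depth = np.where(np.isfinite(zbuf), zbuf, 0.0)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sigma, size=depth.shape)
        valid = depth > 0
        depth = np.where(valid, np.clip(depth + noise, 1.0, None), 0.0)
    rgb = np.zeros((spec.height, spec.width, 3), dtype=np.uint8)
    for code, color in PREVIEW_COLORS.items():
        rgb[labels == code] = color
    return RenderedScene(
        depth=DepthImage(depth, min_range_mm=intr.min_range_mm),
        labels=SegmentationMap(labels),
        rgb=rgb,
        scene=scene,
    )


def _canopy_spec(noise_sigma: float = 0.0, seed: int = 0) -> SceneSpec:
    ax1 = _unit((0.2, 1.0, 0.1))
    ax2 = _unit((1.0, 0.3, 0.2))
    # thin fruit-bearing laterals: a single view sees the branch front
    # surface, so the reconstructed line sits about one branch radius in
    # front of the axis — thin laterals keep that pose bias small.  The
    # three axes stay > 100 mm apart everywhere so no line candidate can
    # bridge two branches within the inlier tube.
    branches = (
        BranchSpec(anchor=(-180.0, -80.0, 680.0), axis=(1.0, 0.0, 0.0), length=360.0, radius=4.5),
        BranchSpec(anchor=(-60.0, -180.0, 840.0), axis=tuple(ax1), length=320.0, radius=4.5),
        BranchSpec(anchor=(60.0, -150.0, 780.0), axis=tuple(ax2), length=300.0, radius=4.0),
    )
    fruits = (
        FruitSpec(branch=0, offset_dir=(0.0, 1.0, 0.0), pedicel=28.0, radius=32.0, attach_s=70.0),
        FruitSpec(
            branch=0,
            offset_dir=(0.0, 0.8, 0.6),
            pedicel=30.0,
            radius=30.0,
            attach_s=290.0,
        ),
        FruitSpec(
            branch=1,
            offset_dir=perpendicular_offset(ax1, (1.0, 0.0, 0.0)),
            pedicel=28.0,
            radius=31.0,
            attach_s=200.0,
        ),
        FruitSpec(
            branch=2,
            offset_dir=perpendicular_offset(ax2, (0.0, 1.0, 0.0)),
            pedicel=28.0,
            radius=29.0,
            attach_s=120.0,
        ),
    )
    return SceneSpec(branches=branches, fruits=fruits, noise_sigma=noise_sigma, seed=seed)


def _preset_single_fruit(seed: int) -> SceneSpec:
    branch = BranchSpec(
        anchor=(-150.0, -40.0, 700.0), axis=(1.0, 0.0, 0.0), length=300.0, radius=10.0
    )
    fruit = FruitSpec(
        branch=0, offset_dir=(0.0, 1.0, 0.0), pedicel=20.0, radius=35.0, attach_s=150.0
    )
    return SceneSpec(branches=(branch,), fruits=(fruit,), seed=seed)


def _preset_two_touching(seed: int) -> SceneSpec:
    branch = BranchSpec(
        anchor=(-150.0, -70.0, 700.0), axis=(1.0, 0.0, 0.0), length=300.0, radius=9.0
    )
    # surface gap along x = |attach difference| - 2*radius = 1 mm (< the 4 mm hop).
    # A narrow-FOV close-range camera gives ~1 mm lateral pixel spacing,
    # fine enough that the near-touching caps are bridged in the point
    # cloud; at coarser sampling the steep depth gradient at each
    # sphere's silhouette isolates the rims and the merge cannot occur.
    camera = CameraIntrinsics(fx=730.0, fy=730.0, ux=256.0, uy=212.0)
    fruits = (
        FruitSpec(branch=0, offset_dir=(0.0, 1.0, 0.0), pedicel=15.0, radius=35.0, attach_s=110.0),
        FruitSpec(branch=0, offset_dir=(0.0, 1.0, 0.0), pedicel=15.0, radius=35.0, attach_s=181.0),
    )
    return SceneSpec(branches=(branch,), fruits=fruits, camera=camera, seed=seed)


def _preset_collinear_split(seed: int) -> SceneSpec:
    # both axes lie in the y=0 plane through the camera centre, so they
    # project onto the same image row while sitting 200 mm apart in depth
    branches = (
        BranchSpec(anchor=(-250.0, 0.0, 680.0), axis=(1.0, 0.0, 0.0), length=230.0, radius=8.0),
        BranchSpec(anchor=(20.0, 0.0, 880.0), axis=(1.0, 0.0, 0.0), length=230.0, radius=8.0),
    )
    return SceneSpec(branches=branches, fruits=(), seed=seed)


PRESETS = {
    "single_fruit": _preset_single_fruit,
    "two_touching_fruits": _preset_two_touching,
    "three_branch_canopy": lambda seed: _canopy_spec(0.0, seed),
    "collinear_2d_depth_split": _preset_collinear_split,
    # noon-sun noise level for a time-of-flight camera at ~1 m range
    "noisy_noon": lambda seed: _canopy_spec(32.0, seed),
}


def make_fixture(
    preset: str,
    seed: int = 0,
    out_dir: str | Path | None = None,
    noise_sigma: float | None = None,
) -> tuple[SceneSpec, RenderedScene]:
    """Render a named preset scene, optionally writing its files.

    When ``out_dir`` is given, writes depth PNG, label PNG, RGB preview,
    intrinsics YAML and a truth JSON into that folder.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[preset](seed)
    if noise_sigma is not None:
        spec = replace(spec, noise_sigma=noise_sigma)
    rendered = render(spec)
    if out_dir is not None:
        _write_fixture(Path(out_dir), spec, rendered)
    return spec, rendered


def _write_fixture(out_dir: Path, spec: SceneSpec, rendered: RenderedScene) -> None:
    import json

    from . import io as fio

    out_dir.mkdir(parents=True, exist_ok=True)
    fio.write_depth_png(out_dir / "depth.png", rendered.depth)
    fio.write_label_png(out_dir / "labels.png", rendered.labels.labels)
    fio.write_rgb_png(out_dir / "rgb.png", rendered.rgb)
    fio.write_intrinsics(out_dir / "intrinsics.yaml", spec.camera)
    truth = {
        "fruits": [
            {
                "center": t.center.tolist(),
                "pose": t.pose.tolist(),
                "mother_branch": t.mother_branch,
                "nearest_point": t.nearest_point.tolist(),
                "radius": t.radius,
            }
            for t in rendered.fruit_truth
        ],
        "branches": [
            {
                "anchor": t.anchor.tolist(),
                "direction": t.direction.tolist(),
                "extent": list(t.extent),
                "radius": t.radius,
            }
            for t in rendered.branch_truth
        ],
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
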