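"""Scene construction and depth rendering with exact ground truth."""

import numpy as np
import pytest

from fruitpose3d import (
    BranchSpec,
    CameraIntrinsics,
    FruitSpec,
    SceneSpec,
    build_scene,
    fit_sphere_lsq,
    make_fixture,
    project,
    render,
)
from fruitpose3d.core_geometry import LABEL_BRANCH, LABEL_FRUIT, backproject


def single_fruit_spec(noise_sigma=0.0, seed=0):
    branch = BranchSpec(anchor=(0.0, 0.0, 1000.0), axis=(1.0, 0.0, 0.0), length=1.0, radius=10.0)
    fruit = FruitSpec(branch=0, offset_dir=(0.0, 1.0, 0.0), pedicel=20.0, radius=40.0)
    return SceneSpec(branches=(branch,), fruits=(fruit,), noise_sigma=noise_sigma, seed=seed)


class TestBuildScene:
    def test_fruit_centre_is_sum_of_radii_and_pedicel_along_offset(self):
        scene = build_scene(single_fruit_spec())
        truth = scene.fruit_truth[0]
        np.testing.assert_allclose(truth.center, [0.0, 70.0, 1000.0])
        np.testing.assert_allclose(truth.pose, [0.0, 1.0, 0.0])
        np.testing.assert_allclose(truth.nearest_point, [0.0, 0.0, 1000.0])

    def test_zero_fruits_gives_empty_truth(self):
        spec = SceneSpec(
            branches=(BranchSpec((0, 0, 900.0), (1, 0, 0), 100.0, 5.0),), fruits=()
        )
        assert build_scene(spec).fruit_truth == []

    def test_every_truth_pose_perpendicular_to_its_axis(self):
        _, rendered = make_fixture("three_branch_canopy", seed=0)
        for t in rendered.fruit_truth:
            axis = rendered.branch_truth[t.mother_branch].direction
            assert abs(t.pose @ axis) < 1e-9
            assert np.linalg.norm(t.pose) == pytest.approx(1.0, abs=1e-9)

    def test_non_perpendicular_offset_rejected(self):
        branch = BranchSpec((0, 0, 900.0), (1.0, 0.0, 0.0), 100.0, 5.0)
        h = float(np.sqrt(0.5))
        bad = FruitSpec(branch=0, offset_dir=(h, h, 0.0), pedicel=10.0, radius=30.0)
        with pytest.raises(ValueError, match="perpendicular"):
            build_scene(SceneSpec(branches=(branch,), fruits=(bad,)))


class TestRender:
    def test_principal_ray_depth_is_analytic_sphere_hit(self):
        # sphere centre (0,0,1000), r=40: the optical axis enters at z=960
        branch = BranchSpec((0.0, -300.0, 1000.0), (1.0, 0.0, 0.0), 1.0, 1.0)
        fruit = FruitSpec(branch=0, offset_dir=(0.0, 1.0, 0.0), pedicel=259.0, radius=40.0)
        camera = CameraIntrinsics(fx=365.0, fy=365.0, ux=256.0, uy=212.0)
        rendered = render(SceneSpec(branches=(branch,), fruits=(fruit,), camera=camera))
        assert rendered.depth.values[212, 256] == pytest.approx(960.0, abs=1e-9)
        assert rendered.labels.labels[212, 256] == LABEL_FRUIT

    def test_empty_scene_renders_invalid_background(self):
        rendered = render(SceneSpec(branches=(), fruits=()))
        assert (rendered.depth.values == 0).all()
        assert (rendered.labels.labels == 0).all()

    def test_depth_matches_analytic_ray_sphere_everywhere(self):
        rendered = render(single_fruit_spec())
        truth = rendered.fruit_truth[0]
        intr = rendered.scene.spec.camera
        vv, uu = np.nonzero(rendered.labels.labels == LABEL_FRUIT)
        d = np.stack(
            [(uu - intr.ux) / intr.fx, (vv - intr.uy) / intr.fy, np.ones_like(uu, float)], axis=1
        )
        a = np.einsum("ij,ij->i", d, d)
        b = -2.0 * d @ truth.center
        c = truth.center @ truth.center - truth.radius**2
        s = (-b - np.sqrt(b * b - 4 * a * c)) / (2 * a)
        np.testing.assert_allclose(rendered.depth.values[vv, uu], s, atol=1e-6)

    def test_sphere_occludes_cylinder_on_shared_rays(self):
        # fruit offset toward the camera sits in front of its branch
        branch = BranchSpec((-100.0, 0.0, 900.0), (1.0, 0.0, 0.0), 200.0, 8.0)
        fruit = FruitSpec(
            branch=0, offset_dir=(0.0, 0.0, -1.0), pedicel=5.0, radius=30.0, attach_s=100.0
        )
        rendered = render(SceneSpec(branches=(branch,), fruits=(fruit,)))
        intr = rendered.scene.spec.camera
        center_px = project(rendered.fruit_truth[0].center, intr)
        u, v = int(round(center_px[0])), int(round(center_px[1]))
        assert rendered.labels.labels[v, u] == LABEL_FRUIT
        assert rendered.depth.values[v, u] < 900.0 - 8.0

    def test_noise_is_seeded_and_only_on_valid_pixels(self):
        r1 = render(single_fruit_spec(noise_sigma=2.0, seed=5))
        r2 = render(single_fruit_spec(noise_sigma=2.0, seed=5))
        r3 = render(single_fruit_spec(noise_sigma=2.0, seed=6))
        np.testing.assert_array_equal(r1.depth.values, r2.depth.values)
        assert (r1.depth.values != r3.depth.values).any()
        clean = render(single_fruit_spec())
        assert ((r1.depth.values > 0) == (clean.depth.values > 0)).all()

    def test_noiseless_round_trip_recovers_sphere(self):
        # back-projecting the rendered fruit cap and fitting a sphere
        # must return the true centre and radius
        rendered = render(single_fruit_spec())
        truth = rendered.fruit_truth[0]
        cloud = backproject(
            rendered.depth,
            rendered.scene.spec.camera,
            mask=rendered.labels.labels == LABEL_FRUIT,
        )
        assert len(cloud) >= 200
        sphere = fit_sphere_lsq(cloud.points)
        assert np.linalg.norm(sphere.center_array - truth.center) < 0.5
        assert abs(sphere.radius - truth.radius) < 0.5


class TestPresets:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            make_fixture("no_such_scene")

    def test_single_fruit_has_one_truth_record(self):
        _, rendered = make_fixture("single_fruit", seed=1)
        assert len(rendered.fruit_truth) == 1

    def test_two_touching_fruits_gap_below_cluster_hop(self):
        _, rendered = make_fixture("two_touching_fruits", seed=1)
        a, b = rendered.fruit_truth
        surface_gap = np.linalg.norm(a.center - b.center) - a.radius - b.radius
        assert 0 < surface_gap < 4.0

    def test_collinear_preset_projects_to_one_image_line_with_depth_split(self):
        spec, rendered = make_fixture("collinear_2d_depth_split", seed=0)
        rows = []
        for bt in rendered.branch_truth:
            ends = [bt.anchor, bt.anchor + bt.extent[1] * bt.direction]
            rows.extend(project(np.array(ends), spec.camera)[:, 1])
        assert np.ptp(rows) < 1e-9  # all endpoints on the same image row
        depths = sorted(bt.anchor[2] for bt in rendered.branch_truth)
        assert depths[1] - depths[0] > 100.0

    def test_noisy_noon_preset_uses_noon_sun_noise_level(self):
        spec, _ = make_fixture("noisy_noon", seed=0)
        assert spec.noise_sigma == 32.0

    def test_fixture_files_written_and_consistent(self, tmp_path):
        from fruitpose3d import io as fio

        _, rendered = make_fixture("single_fruit", seed=2, out_dir=tmp_path)
        for name in ("depth.png", "labels.png", "rgb.png", "intrinsics.yaml", "truth.json"):
            assert (tmp_path / name).exists()
        depth = fio.read_depth_png(tmp_path / "depth.png")
        np.testing.assert_allclose(depth.values, rendered.depth.values, atol=0.5)
        labels = fio.read_label_png(tmp_path / "labels.png")
        np.testing.assert_array_equal(labels, rendered.labels.labels)
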