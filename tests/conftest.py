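import numpy as np
import pytest

from fruitpose3d import CameraIntrinsics, PipelineConfig, make_fixture


@pytest.fixture
def intrinsics():
    """Round-number pinhole model for hand-computed cases."""
    return CameraIntrinsics(fx=500.0, fy=500.0, ux=256.0, uy=212.0)


@pytest.fixture(scope="session")
def canopy():
    """Noiseless three-branch scene with four fruits, rendered once."""
    spec, rendered = make_fixture("three_branch_canopy", seed=1)
    return spec, rendered


@pytest.fixture(scope="session")
def canopy_result(canopy):
    from fruitpose3d import run_pipeline

    spec, rendered = canopy
    config = PipelineConfig(intrinsics=spec.camera, seed=7)
    return run_pipeline(rendered.depth, rendered.labels, config)


def sample_sphere_surface(center, radius, n, rng):
    """Uniform points on a full sphere surface (test helper oracle)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.asarray(center) + radius * v
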