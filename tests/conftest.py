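import numpy as np
import pytest

from dtrack.camera import (CalibrationPoint, Camera, CameraPose,
                           DistortionCoefficients, Intrinsics)
from dtrack.scene import SceneConfig


@pytest.fixture
def paper_coeffs() -> DistortionCoefficients:
    """The wide-angle lens calibration shipped as the package default."""
    return DistortionCoefficients()


@pytest.fixture
def default_intrinsics() -> Intrinsics:
    return Intrinsics()


@pytest.fixture
def scene_config() -> SceneConfig:
    """Default 21 m pool with two opposite 4 m-high cameras, seed 0."""
    return SceneConfig(seed=0)


@pytest.fixture
def synthetic_camera() -> Camera:
    """A camera with a known non-trivial pose, for round-trip tests."""
    pose = CameraPose.look_at((11.0, 0.0, -4.0), (0.0, 0.0, 1.0))
    return Camera(pose=pose)


@pytest.fixture
def landmarks(synthetic_camera) -> list[CalibrationPoint]:
    """Eight exact world/pixel correspondences through the known pose."""
    rng = np.random.default_rng(42)
    pts = []
    while len(pts) < 8:
        w = np.array([rng.uniform(-8, 8), rng.uniform(-8, 8), rng.uniform(0, 4)])
        try:
            px = synthetic_camera.project(w)
        except Exception:
            continue
        intr = synthetic_camera.intrinsics
        if 0 <= px[0] <= intr.width - 1 and 0 <= px[1] <= intr.height - 1:
            pts.append(CalibrationPoint(world=tuple(w), pixel=tuple(px)))
    return pts
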