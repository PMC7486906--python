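"""Shared fixtures: rigs, skeletons and short synthetic sequences.

Session-scoped where construction is expensive; all randomness is seeded
so the suite is reproducible run to run.
"""

import numpy as np
import pytest

from primatemocap import (
    MotionScript,
    NoiseModel,
    RigSpec,
    emulate_detections,
    make_rig,
    simulate_motion,
)
from primatemocap.core import default_skeleton


@pytest.fixture(scope="session")
def skeleton():
    return default_skeleton()


@pytest.fixture(scope="session")
def rig62():
    return make_rig(RigSpec())


@pytest.fixture(scope="session")
def rig8():
    return make_rig(RigSpec(n_cameras=8, n_levels=1))


@pytest.fixture(scope="session")
def simple_camera():
    """Camera at the origin looking along +z, no distortion."""
    from primatemocap import CameraModel

    return CameraModel(
        camera_id="simple",
        focal=(625.0, 625.0),
        principal_point=(640.0, 512.0),
        rotation=np.eye(3),
        translation=np.zeros(3),
        image_size=(1280, 1024),
    )


@pytest.fixture(scope="session")
def walk_sit_sequence(skeleton):
    """4 s walk + sit ground truth at 30 fps (120 frames)."""
    script = MotionScript.from_pairs([("walk", 2.0), ("sit", 2.0)])
    return simulate_motion(skeleton, script, seed=3)


@pytest.fixture(scope="session")
def noisy_detections(walk_sit_sequence, rig62, skeleton):
    """sigma=2 px, 10% outliers, occlusion on — the standard benchmark noise."""
    poses, _ = walk_sit_sequence
    noise = NoiseModel(pixel_sigma=2.0, outlier_prob=0.10, occlusion=True, seed=5)
    return emulate_detections(poses, rig62, noise, skeleton)


@pytest.fixture(scope="session")
def raw_reconstruction(noisy_detections, rig62, skeleton):
    from primatemocap import reconstruct_sequence

    return reconstruct_sequence(noisy_detections, rig62,
                                landmark_names=list(skeleton.landmark_names))
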