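import numpy as np
import pytest

from phasetrack.segmentation import FrameImage, SegmentationConfig
from phasetrack.synthetic import SceneSpec, render_scene, simulate_trajectory, cancer_like_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def seg_config():
    return SegmentationConfig(edge_threshold=60.0)


@pytest.fixture(scope="session")
def single_cell_scene():
    """One slowly moving rendered cell, 31 frames, with ground truth."""
    spec = cancer_like_spec(duration_min=30, seed=7)
    traj, _ = simulate_trajectory(spec, seed=7, start_um=(83.2, 83.2))
    scene = SceneSpec(seed=7)
    frames, truth = render_scene([traj], scene)
    return frames, truth


@pytest.fixture(scope="session")
def five_cell_scene():
    """Five non-contacting rendered cells, 61 frames, with ground truth."""
    spec = cancer_like_spec(duration_min=60, seed=3)
    scene = SceneSpec(frame_shape=(512, 512), seed=3)
    starts = [(90, 90), (240, 90), (90, 240), (240, 240), (166, 166)]
    trajs = [
        simulate_trajectory(spec, seed=100 + i, start_um=s, cell_id=i)[0]
        for i, s in enumerate(starts)
    ]
    frames, truth = render_scene(trajs, scene)
    return frames, truth
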