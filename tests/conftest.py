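import numpy as np
import pytest

from striderforce import (
    RunConfig,
    SceneParams,
    StrokeModel,
    render_frames,
    simulate_propulsion,
)


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig(seed=0)


@pytest.fixture(scope="session")
def noiseless_scene() -> SceneParams:
    return SceneParams(noise_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_scene):
    """One rendered noiseless trial shared across tracking/kinematics tests."""
    model = StrokeModel()
    trajectory, truth = simulate_propulsion(model, noiseless_scene, 80.0)
    frames = render_frames(trajectory, noiseless_scene, seed=7)
    return frames, trajectory, truth, noiseless_scene


@pytest.fixture(scope="session")
def dragfree_trial(noiseless_scene):
    """Noiseless drag-free trial: v_max = 2AT/pi is the exact truth."""
    model = StrokeModel(drag_coeff_uNs_per_mm=0.0)
    trajectory, truth = simulate_propulsion(model, noiseless_scene, 80.0)
    frames = render_frames(trajectory, noiseless_scene, seed=7)
    return frames, trajectory, truth, noiseless_scene


def brute_force_centroid(frame: np.ndarray, region: np.ndarray,
                         background: float) -> tuple[float, float]:
    """Explicit double-loop intensity-weighted centroid oracle."""
    total = 0.0
    sum_r = 0.0
    sum_c = 0.0
    for r in range(frame.shape[0]):
        for c in range(frame.shape[1]):
            if region[r, c]:
                w = max(float(frame[r, c]) - background, 0.0)
                total += w
                sum_r += w * r
                sum_c += w * c
    return sum_c / total, sum_r / total
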