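import numpy as np
import pytest

from gazekit.geometry import DisplayGeometry
from gazekit.render import EyeRenderConfig, render_eye_frame
from gazekit.synth import (
    LinearForwardMap,
    NoiseParams,
    SessionScript,
    TargetEvent,
    generate_gaze_session,
    grid_targets,
    make_model_selection_script,
)


@pytest.fixture(scope="session")
def display():
    return DisplayGeometry()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def make_noise_free_script(n_targets=12, duration=0.5, seed=0, fps=20.0):
    """Short script with all stochastic components switched off."""
    quiet = NoiseParams(tremor_sd=0.0, drift_sd=0.0, microsaccade_rate=0.0,
                        blink_rate=0.0, corner_sd=0.0)
    grid = grid_targets(3, 4)[:n_targets]
    targets = tuple(
        TargetEvent(gx, gy, i * duration, duration, target_id=i)
        for i, (gx, gy) in enumerate(grid)
    )
    return SessionScript(targets=targets, noise=quiet, fps=fps, seed=seed)


@pytest.fixture(scope="session")
def noise_free_linear_session():
    """Noise-free session whose forward map lies inside every model family."""
    return generate_gaze_session(make_noise_free_script(), LinearForwardMap())


@pytest.fixture(scope="session")
def pose_protocol_session():
    """Default 8-pose model-selection session with generator defaults."""
    return generate_gaze_session(make_model_selection_script(seed=3))


@pytest.fixture(scope="session")
def eye_frame():
    """One clean rendered eye frame plus its ground truth."""
    cfg = EyeRenderConfig(noise_sd=0.0)
    img, truth = render_eye_frame((300.0, 250.0), (430.0, 260.0), config=cfg)
    return img, truth
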