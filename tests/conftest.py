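import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from thermalvitals.io_core import RectROI
from thermalvitals.synthgen import SceneConfig, generate_scene

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

# Standard analysis rectangles for the default 128x128 scene geometry:
# the lower face (below the eye line, enclosing the maxillary contour)
# and the mouth exclusion inside it.
LOWER_FACE_ROI = RectROI(70, 34, 34, 60)
MOUTH_ROI = RectROI(88, 52, 10, 24)


def lower_face(rows: int, cols: int) -> RectROI:
    """Lower-face rectangle scaled to an arbitrary scene size."""
    return RectROI(int(0.55 * rows), int(0.27 * cols),
                   int(0.27 * rows), int(0.47 * cols))


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, motionless-background scene used by several modules:
    70.2 beats/min at 0.3 px, no sensor noise, no nostril modulation."""
    cfg = SceneConfig(rows=64, cols=64, duration=6.0, hr_bpm=70.2,
                      bcg_amp_px=0.3, noise_sd_k=0.0, nostril_amp_k=0.0,
                      seed=7)
    video, hr_truth, rr_truth = generate_scene(cfg)
    return cfg, video


@pytest.fixture(scope="session")
def default_scene():
    """Study-condition scene: 128x128, 50 fps, NETD noise, 70 bpm / 15
    breaths per min.  Kept to 20 s so several suites can share it."""
    cfg = SceneConfig(duration=20.0, seed=2)
    video, hr_truth, rr_truth = generate_scene(cfg)
    return cfg, video, hr_truth, rr_truth


def normalized_stack(video) -> np.ndarray:
    """Globally normalized frames in [0, 1] (rigid-translation tracking
    fixtures bypass the per-frame preprocessing on purpose)."""
    f = video.frames
    return ((f - f.min()) / (f.max() - f.min())).astype(np.float32)
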