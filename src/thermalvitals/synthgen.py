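"""Synthetic thermal scenes with known cardiac/respiratory ground truth.

The generator emulates the measurement situation the two pipelines were
designed for: a warm head (skin ~34 degC) against a cooler indoor
background (~22.3 degC), imaged by a thermal camera with a noise floor
(NETD) of about 0.025 K.  Two physiological signals are injected:

* the whole head translates vertically by a sub-pixel sinusoid at the
  cardiac frequency (head ballistocardiography, typically well below one
  pixel at a ~1.5 m camera distance), and
* pixels in a nostril rectangle receive an additive temperature
  oscillation at the respiratory frequency, negative-going on
  inspiration (inhaled room air cools the nostril margin).

The head carries a frozen spatial speckle field (smoothed Gaussian
texture) so that corner detection has something to latch onto, mirroring
the natural thermal texture of facial skin.  Sub-pixel motion is rendered
by bilinear resampling of the static template, which is exactly the
regime the point tracker must resolve.

The generator is deliberately simple: no radiative physics, no airflow,
no facial deformation, no occlusion.  Passing tests on these scenes
demonstrates that the signal path recovers known frequencies at realistic
amplitude and noise; it does not certify behaviour on real faces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .io_core import RateSeries, RectROI, ThermalVideo

__all__ = ["SceneConfig", "generate_scene", "generate_two_tone", "head_mask"]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic scene.

    Defaults reproduce the study conditions: 50 fps acquisition, ambient
    22.3 degC, skin 34 degC, sensor noise 0.025 K.  The
    ballistocardiographic amplitude (0.3 px) is a test choice — no
    measured pixel amplitude is available — placed firmly in the
    sub-pixel regime the tracker must handle.
    """

    rows: int = 128
    cols: int = 128
    fps: float = 50.0
    duration: float = 60.0
    ambient_c: float = 22.3
    skin_c: float = 34.0
    head_center: tuple[float, float] | None = None   # (row, col); default frame center
    head_axes: tuple[float, float] | None = None     # semi-axes (row, col)
    texture_sd: float = 0.8       # K, facial speckle contrast
    hr_bpm: float = 70.0
    bcg_amp_px: float = 0.3       # vertical oscillation amplitude
    rr_bpm: float = 15.0
    nostril_roi: RectROI | None = None
    nostril_amp_k: float = 0.5    # peak respiratory modulation, K
    resp_waveform: str = "sine"   # "sine" or "asymmetric" (fast inspiration)
    noise_sd_k: float = 0.025     # NETD-scale i.i.d. Gaussian noise
    drift_px_per_s: float = 0.0   # slow vertical posture drift
    seed: int = 0

    def resolved(self) -> "SceneConfig":
        """Fill geometry defaults (head centered, axes 35%/28% of frame,
        nostril rectangle under the head center)."""
        cfg = self
        if cfg.head_center is None:
            cfg = replace(cfg, head_center=(cfg.rows / 2.0, cfg.cols / 2.0))
        if cfg.head_axes is None:
            cfg = replace(cfg, head_axes=(0.35 * cfg.rows, 0.28 * cfg.cols))
        if cfg.nostril_roi is None:
            cr, cc = cfg.head_center
            h = max(2, int(round(0.06 * cfg.rows)))
            w = max(2, int(round(0.10 * cfg.cols)))
            cfg = replace(cfg, nostril_roi=RectROI(
                int(round(cr + 0.08 * cfg.rows)), int(round(cc - w / 2)), h, w))
        return cfg

    def validate(self) -> "SceneConfig":
        cfg = self.resolved()
        if cfg.rows < 8 or cfg.cols < 8:
            raise ConfigurationError("scene must be at least 8x8 pixels")
        if cfg.fps <= 0 or cfg.duration <= 0:
            raise ConfigurationError("fps and duration must be positive")
        if not (0.65 < cfg.hr_bpm / 60.0 < 2.0):
            raise ConfigurationError(
                f"hr_bpm {cfg.hr_bpm} outside the cardiac band (39-120 bpm)")
        if not (0.1 < cfg.rr_bpm / 60.0 < 0.85):
            raise ConfigurationError(
                f"rr_bpm {cfg.rr_bpm} outside the respiratory band (6-51/min)")
        if cfg.bcg_amp_px < 0 or cfg.noise_sd_k < 0 or cfg.nostril_amp_k < 0:
            raise ConfigurationError("amplitudes and noise must be >= 0")
        if cfg.resp_waveform not in ("sine", "asymmetric"):
            raise ConfigurationError("resp_waveform must be 'sine' or 'asymmetric'")
        cfg.nostril_roi.require_inside((cfg.rows, cfg.cols))
        mask = head_mask(cfg)
        rs, cs = cfg.nostril_roi.slices()
        if not np.all(mask[rs, cs]):
            raise ConfigurationError("nostril_roi must lie inside the head ellipse")
        return cfg


def head_mask(config: SceneConfig) -> np.ndarray:
    """Boolean support of the head ellipse at rest (no motion applied)."""
    cfg = config.resolved()
    rr, cc = np.mgrid[0:cfg.rows, 0:cfg.cols]
    (cr, ccol), (ar, ac) = cfg.head_center, cfg.head_axes
    return ((rr - cr) / ar) ** 2 + ((cc - ccol) / ac) ** 2 <= 1.0


def _respiratory_waveform(phase: np.ndarray, kind: str) -> np.ndarray:
    """Unit-peak periodic waveform; positive values warm the nostril.

    ``asymmetric`` skews the cycle so the cooling (inspiration) flank is
    faster than the warming flank, a shape closer to real nasal airflow
    than a sine; the interval estimators must not depend on sinusoidality.
    """
    if kind == "sine":
        return np.sin(phase)
    w = np.sin(phase - 0.5 * np.sin(phase))
    return w / np.max(np.abs(w)) if w.size else w


def generate_scene(config: SceneConfig) -> tuple[ThermalVideo, RateSeries, RateSeries]:
    """Render a scene; returns (video, hr_truth, rr_truth).

    Deterministic for a fixed ``config.seed``.  Per frame: the static
    template (ambient background + speckled warm ellipse) is shifted
    vertically by ``bcg_amp_px * sin(2*pi*f_hr*t) + drift`` with bilinear
    interpolation, the nostril rectangle receives
    ``-nostril_amp_k * waveform(2*pi*f_rr*t)``, and i.i.d. Gaussian noise
    of sd ``noise_sd_k`` is added last.  Truth series are constant at the
    configured rates, sampled at 1 Hz.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)

    mask = head_mask(cfg)
    speckle = rng.normal(0.0, 1.0, size=(cfg.rows, cfg.cols))
    speckle = ndimage.gaussian_filter(speckle, sigma=1.5)
    sd = speckle[mask].std()
    if sd > 0:
        speckle *= cfg.texture_sd / sd
    template = np.full((cfg.rows, cfg.cols), cfg.ambient_c, dtype=np.float64)
    template[mask] = cfg.skin_c + speckle[mask]

    n_frames = int(round(cfg.duration * cfg.fps))
    t = np.arange(n_frames) / cfg.fps
    dy = (cfg.bcg_amp_px * np.sin(2 * np.pi * cfg.hr_bpm / 60.0 * t)
          + cfg.drift_px_per_s * t)
    resp = -cfg.nostril_amp_k * _respiratory_waveform(
        2 * np.pi * cfg.rr_bpm / 60.0 * t, cfg.resp_waveform)

    rs, cs = cfg.nostril_roi.slices()
    frames = np.empty((n_frames, cfg.rows, cfg.cols), dtype=np.float32)
    for k in range(n_frames):
        if dy[k] != 0.0:
            frame = ndimage.shift(template, (dy[k], 0.0), order=1,
                                  mode="nearest")
        else:
            frame = template.copy()
        frame[rs, cs] += resp[k]
        if cfg.noise_sd_k > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sd_k, size=frame.shape)
        frames[k] = frame

    video = ThermalVideo(frames, cfg.fps)
    truth_t = np.arange(0.0, cfg.duration, 1.0)
    hr_truth = RateSeries(truth_t, np.full(truth_t.size, cfg.hr_bpm), "heart")
    rr_truth = RateSeries(truth_t, np.full(truth_t.size, cfg.rr_bpm), "respiration")
    return video, hr_truth, rr_truth


def generate_two_tone(rows: int, cols: int, low_c: float, high_c: float,
                      split_col: int) -> np.ndarray:
    """Single frame: columns < ``split_col`` at ``low_c``, the rest at
    ``high_c``.  A minimal fixture for threshold-selection tests."""
    if not (low_c < high_c):
        raise ConfigurationError("low_c must be < high_c")
    frame = np.full((rows, cols), high_c, dtype=np.float64)
    frame[:, :split_col] = low_c
    return frame
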