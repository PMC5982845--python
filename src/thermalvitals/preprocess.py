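"""Per-frame head segmentation and contrast enhancement.

The head is separated from the background by multilevel Otsu
thresholding — easy in thermograms because skin is warmer than the room —
and in-mask gray levels are then linearly stretched to [0, 1] so that
corner scores and tracking residuals live on a fixed scale regardless of
the absolute temperature calibration.  Both steps run on every frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .errors import DegenerateInputError, SegmentationError
from .io_core import ThermalVideo

__all__ = [
    "ThresholdSet",
    "multilevel_otsu",
    "segment_head",
    "contrast_stretch",
    "preprocess_video",
]

OTSU_BINS = 256  # histogram quantization for threshold search


@dataclass(frozen=True)
class ThresholdSet:
    """Ascending thresholds partitioning an image into ``len(levels)+1``
    classes."""

    levels: tuple[float, ...]

    def __post_init__(self):
        levels = tuple(float(v) for v in self.levels)
        if len(levels) < 1:
            raise ValueError("need at least one threshold")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("thresholds must be strictly ascending")
        object.__setattr__(self, "levels", levels)

    @property
    def n_classes(self) -> int:
        return len(self.levels) + 1


def multilevel_otsu(image: np.ndarray, n_classes: int = 2) -> ThresholdSet:
    """Optimal thresholds maximizing between-class variance.

    The search runs over a 256-bin histogram of the image's value range
    (discriminant-analysis criterion, exhaustive over bin boundaries);
    supported for 2-4 classes.
    """
    if not 2 <= n_classes <= 4:
        raise ValueError("n_classes must be in 2..4")
    image = np.asarray(image, dtype=np.float64)
    # cheap distinctness guard: a constant (or near-constant) image has no
    # between-class structure to optimize
    vmin, vmax = image.min(), image.max()
    if vmax == vmin:
        raise DegenerateInputError("constant image: no threshold exists")
    try:
        levels = threshold_multiotsu(image, classes=n_classes, nbins=OTSU_BINS)
    except ValueError as e:
        raise DegenerateInputError(
            f"image has too few distinct values for {n_classes} classes"
        ) from e
    return ThresholdSet(tuple(levels))


def segment_head(frame: np.ndarray, thresholds: ThresholdSet) -> np.ndarray:
    """Binary head mask: pixels above the top threshold, cleaned up.

    Bare thresholding leaves noise speckles and cold facial pits that
    would corrupt corner detection, so only the largest connected
    component is kept and its holes are filled.
    """
    frame = np.asarray(frame)
    raw = frame > thresholds.levels[-1]
    if not raw.any():
        raise SegmentationError("no pixels above the top threshold")
    labels, n = ndimage.label(raw)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        raw = labels == np.argmax(counts)
    return ndimage.binary_fill_holes(raw)


def contrast_stretch(frame: np.ndarray, mask: np.ndarray,
                     lo_pct: float = 1.0, hi_pct: float = 99.0) -> np.ndarray:
    """Linear stretch of in-mask gray levels to [0, 1].

    Values at/below the ``lo_pct`` percentile of in-mask pixels map to 0,
    at/above ``hi_pct`` to 1; out-of-mask pixels are set to 0 (background
    subtraction).
    """
    if not (lo_pct < hi_pct):
        raise ValueError("lo_pct must be < hi_pct")
    frame = np.asarray(frame, dtype=np.float64)
    inside = frame[mask]
    if inside.size == 0:
        raise DegenerateInputError("empty mask")
    lo, hi = np.percentile(inside, [lo_pct, hi_pct])
    if hi == lo:
        raise DegenerateInputError("zero in-mask dynamic range")
    out = np.clip((frame - lo) / (hi - lo), 0.0, 1.0)
    out[~mask] = 0.0
    return out


def preprocess_video(video: ThermalVideo, n_classes: int = 2,
                     lo_pct: float = 1.0, hi_pct: float = 99.0) -> np.ndarray:
    """Segment + stretch every frame; returns a float32 stack in [0, 1]."""
    out = np.empty(video.frames.shape, dtype=np.float32)
    for k in range(video.n_frames):
        frame = video.frames[k]
        thr = multilevel_otsu(frame, n_classes)
        mask = segment_head(frame, thr)
        out[k] = contrast_stretch(frame, mask, lo_pct, hi_pct)
    return out
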