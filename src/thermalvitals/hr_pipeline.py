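"""Heart-rate branch: sliding-window PCA over vertical feature
trajectories and periodicity-based component readout.

The cyclical ejection of blood toward the head produces a small vertical
head oscillation at the cardiac frequency.  Per analysis window (256
samples at 50 fps, ~5 s) the pruned vertical trajectories are band-pass
filtered to 0.65-5 Hz (wide enough to keep cardiac harmonics), the 15%
of columns with the largest L2 norms are excluded (gross motions —
posture shifts, swallowing — inflate variance and would dominate the
PCA), and the remaining columns are decomposed by PCA.  Among the first
six components the one with the highest peak-to-total periodicity score
is taken as the pulse signal, and its dominant frequency inside the
0.65-2 Hz fundamental band (39-120 beats/min) is the heart-rate readout
for that window.  Recomputing the PCA per window lets the decomposition
follow slow changes in which motion directions carry the pulse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (DegenerateInputError, FeatureScarcityError,
                     PipelineError, SegmentationError, TrackingFailureError)
from .features import (prune_erratic, select_features, shi_tomasi_score_map,
                       track_features, vertical_trajectories)
from .io_core import HR_PLAUSIBLE_BPM, RateSeries, RectROI, SignalTrace, ThermalVideo
from .preprocess import preprocess_video
from .signals import (amplitude_spectrum, dominant_frequency, filter_columns,
                      peak_to_total_ratio)

__all__ = ["HrConfig", "pca_components", "exclude_high_l2",
           "select_component", "estimate_hr_series"]


@dataclass(frozen=True)
class HrConfig:
    """Tunable parameters of the heart-rate branch (defaults are the
    validated operating point; see module docstring for meaning)."""

    band: tuple[float, float] = (0.65, 5.0)
    hr_search_band: tuple[float, float] = (0.65, 2.0)
    window_len: int = 256
    stride: int = 50
    n_components: int = 6
    l2_exclude_frac: float = 0.15
    max_features: int = 100
    prune_percentile: float = 95.0
    min_periodicity: float = 0.25
    quality: float = 0.01
    min_dist: float = 5.0
    pyramid_levels: int = 3
    patch: int = 21

    def __post_init__(self):
        if not (0 <= self.l2_exclude_frac < 1):
            raise ValueError("l2_exclude_frac must be in [0, 1)")
        if self.window_len < 2 or self.stride < 1:
            raise ValueError("window_len >= 2 and stride >= 1 required")
        lo, hi = self.hr_search_band
        if not (self.band[0] <= lo < hi <= self.band[1]):
            raise ValueError("hr_search_band must lie inside the filter band")


def pca_components(windowed: np.ndarray, k: int
                   ) -> tuple[list[np.ndarray], bool]:
    """Top-``k`` principal component score series of a (samples x
    channels) matrix, variance-descending.

    Columns are mean-centered internally.  Sign convention: each
    component's largest-magnitude loading is positive.  If the matrix
    rank is below ``k``, the available components are returned together
    with a ``rank_limited`` flag.
    """
    x = np.asarray(windowed, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("windowed must be 2-D (samples x channels)")
    if x.shape[1] < 1:
        raise DegenerateInputError("no channels")
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(np.float64).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    n_out = min(k, rank)
    comps = []
    for i in range(n_out):
        score = u[:, i] * s[i]
        lead = np.argmax(np.abs(vt[i]))
        if vt[i, lead] < 0:
            score = -score
        comps.append(score)
    return comps, n_out < k


def exclude_high_l2(windowed: np.ndarray, frac: float = 0.15) -> np.ndarray:
    """Drop the ``ceil(frac * n)`` columns with the largest L2 norms
    (ties: the higher column index goes first)."""
    x = np.asarray(windowed)
    n = x.shape[1]
    n_drop = int(np.ceil(frac * n)) if frac > 0 else 0
    if n_drop == 0:
        return x
    if n_drop >= n:
        raise DegenerateInputError("exclusion would drop every column")
    norms = np.linalg.norm(x, axis=0)
    # sort by (norm desc, index desc) so ties drop the higher index
    order = sorted(range(n), key=lambda j: (-norms[j], -j))
    drop = set(order[:n_drop])
    keep = [j for j in range(n) if j not in drop]
    return x[:, keep]


def select_component(components: list[np.ndarray], fs: float,
                     search_band: tuple[float, float],
                     half_width: float = 0.05) -> tuple[int, float]:
    """Pick the most periodic component; return (index, dominant Hz).

    Periodicity is the peak-to-total power ratio around the component's
    dominant in-band frequency and its first harmonic.  Ties keep the
    lower (higher-variance) index.
    """
    idx, hz, _ = _best_component(components, fs, search_band, half_width)
    return idx, hz


def _best_component(components, fs, search_band, half_width=0.05
                    ) -> tuple[int, float, float]:
    """As :func:`select_component` but also returning the winning
    peak-to-total ratio (the pipeline's confidence score)."""
    if not components:
        raise DegenerateInputError("no components to select from")
    best_idx, best_ratio, best_hz = -1, -np.inf, np.nan
    for i, comp in enumerate(components):
        if not np.any(comp):
            continue
        spec = amplitude_spectrum(SignalTrace(comp, fs))
        f_dom = dominant_frequency(spec, search_band)
        ratio = peak_to_total_ratio(spec, f_dom, half_width)
        if ratio > best_ratio:
            best_idx, best_ratio, best_hz = i, ratio, f_dom
    if best_idx < 0:
        raise DegenerateInputError("all components are identically zero")
    return best_idx, best_hz, best_ratio


def estimate_hr_series(video: ThermalVideo, roi: RectROI,
                       mouth_exclusion: RectROI | None = None,
                       cfg: HrConfig = HrConfig()) -> RateSeries:
    """Full heart-rate pipeline on a thermal video.

    Stages: per-frame preprocessing -> corner selection in ``roi`` (minus
    ``mouth_exclusion``) -> KLT tracking -> erratic-point pruning ->
    windowed filter/PCA/selection -> per-window beats-per-minute readout.
    Window estimates falling outside the 39-120 bpm plausibility band are
    dropped.  Stage failures surface as :class:`PipelineError` with the
    stage name.
    """
    if video.n_frames < cfg.window_len:
        raise PipelineError(
            f"video has {video.n_frames} frames; window needs {cfg.window_len}",
            stage="windowing")
    roi.require_inside(video.shape)
    try:
        stack = preprocess_video(video)
    except (DegenerateInputError, SegmentationError) as e:
        raise PipelineError(str(e), stage="preprocess") from e
    try:
        score = shi_tomasi_score_map(stack[0])
        seeds = select_features(score, roi, mouth_exclusion,
                                max_n=cfg.max_features, quality=cfg.quality,
                                min_dist=cfg.min_dist)
    except FeatureScarcityError as e:
        raise PipelineError(str(e), stage="feature-selection") from e
    try:
        tracks = track_features(stack, video.fps, seeds,
                                pyramid_levels=cfg.pyramid_levels,
                                patch=cfg.patch,
                                min_track_frames=cfg.window_len)
    except TrackingFailureError as e:
        raise PipelineError(str(e), stage="tracking") from e
    tracks = prune_erratic(tracks, cfg.prune_percentile)
    y, fs = vertical_trajectories(tracks)
    if y.shape[1] < 10:
        raise PipelineError(
            f"only {y.shape[1]} trajectories survive the full span (need 10)",
            stage="trajectories")

    times, rates = [], []
    n = y.shape[0]
    lo_bpm, hi_bpm = HR_PLAUSIBLE_BPM
    for start in range(0, n - cfg.window_len + 1, cfg.stride):
        win = y[start:start + cfg.window_len]
        filt = filter_columns(win, fs, *cfg.band)
        try:
            kept = exclude_high_l2(filt, cfg.l2_exclude_frac)
            comps, _ = pca_components(kept, cfg.n_components)
            _, hz, ratio = _best_component(comps, fs, cfg.hr_search_band)
        except DegenerateInputError:
            continue
        bpm = 60.0 * hz
        # a window whose best component is barely periodic (score in the
        # broadband-noise regime) yields no estimate rather than a wrong one
        if ratio < cfg.min_periodicity:
            continue
        if lo_bpm <= bpm <= hi_bpm:
            times.append(video.origin_time
                         + (start + (cfg.window_len - 1) / 2.0) / fs)
            rates.append(bpm)
    return RateSeries(np.asarray(times), np.asarray(rates), "heart")
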