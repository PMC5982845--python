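"""Respiratory-rate branch: nostril-region temperature waveform and
breath-to-breath interval estimation by three fused lag estimators.

Air inhaled from the room cools the nostril margin and exhaled air warms
it, so the mean temperature of a small measurement rectangle under the
nose oscillates at the respiratory frequency.  The branch:

1. tracks the user-supplied nose rectangle by normalized
   cross-correlation against its first-frame template (integer-pixel,
   "rough" motion compensation);
2. averages the centered region of measurement (ROM) per frame into a
   waveform and band-pass filters it to 0.1-0.85 Hz;
3. at stride-spaced window centers, evaluates three interval estimators
   for every candidate lag ``m`` (samples): adaptive-window
   autocorrelation, the reciprocal average magnitude difference
   function, and maximum amplitude pairs — each over the adaptive window
   spanning ``[-m, m]`` around the center;
4. converts each estimator profile to a probability mass over lags and
   fuses them by elementwise (naive-Bayes) product; the posterior argmax
   lag ``m_hat`` gives the local rate ``60 * fs / m_hat``.

Three estimators with different failure modes (correlation, waveform
distance, peak pairing) make the fused argmax far more robust to
non-sinusoidal breathing than any single one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template

from .errors import (ConfigurationError, DegenerateInputError, PipelineError,
                     FusionDegenerateWarning, TrackingLossError)
from .io_core import RR_PLAUSIBLE_BPM, RateSeries, RectROI, SignalTrace, ThermalVideo
from .signals import butter_bandpass

__all__ = [
    "RrConfig", "LagPosterior", "ROITrack",
    "track_roi", "rom_waveform",
    "estimator_ac", "estimator_amdf", "estimator_map",
    "to_posterior", "fuse_bayes", "estimate_rr_series",
]

_AMDF_EPS = 1e-12


@dataclass(frozen=True)
class RrConfig:
    """Respiratory-branch parameters.

    The candidate lag range is derived from the pass band: breathing at
    0.1-0.85 Hz corresponds to intervals of ``fs/0.85`` to ``fs/0.1``
    samples.  ``rom_frac`` is the ROM area as a fraction of the tracked
    ROI (centered, aspect preserved); averaging over the ROM trades
    spatial resolution for SNR.
    """

    band: tuple[float, float] = (0.1, 0.85)
    rom_frac: float = 0.5
    stride: int | None = None      # samples between estimates; default fs (1 s)
    search_radius: int = 20        # px, NCC search around previous position
    min_correlation: float = 0.3

    def __post_init__(self):
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError("band must satisfy 0 < f_lo < f_hi")
        if not (0 < self.rom_frac <= 1):
            raise ValueError("rom_frac must be in (0, 1]")

    def lag_range(self, fs: float) -> tuple[int, int]:
        m_min = int(np.ceil(fs / self.band[1]))
        m_max = int(np.floor(fs / self.band[0]))
        if m_min < 2 or m_max <= m_min:
            raise ConfigurationError(
                f"degenerate lag range [{m_min}, {m_max}] at fs={fs}")
        return m_min, m_max


@dataclass(frozen=True)
class LagPosterior:
    """Probability mass over candidate breath-interval lags (samples)."""

    lags: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=np.int64)
        probs = np.asarray(self.probs, dtype=np.float64)
        if lags.ndim != 1 or probs.shape != lags.shape:
            raise ValueError("lags and probs must be 1-D of equal length")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "probs", probs)


@dataclass(frozen=True)
class ROITrack:
    """A rectangle plus its per-frame integer offsets (n_frames, 2)."""

    roi: RectROI
    offsets: np.ndarray

    def roi_at(self, frame: int) -> RectROI:
        dr, dc = self.offsets[frame]
        return self.roi.shifted(int(dr), int(dc))


def track_roi(video: ThermalVideo, roi: RectROI,
              search_radius: int = 20,
              min_correlation: float = 0.3) -> ROITrack:
    """Integer-pixel template tracking of ``roi`` through the video.

    The first-frame ROI is the fixed template; per frame it is matched by
    normalized cross-correlation inside a ``search_radius`` neighborhood
    of the previous position.  A correlation peak below
    ``min_correlation`` raises :class:`TrackingLossError` with the frame
    index.
    """
    roi.require_inside(video.shape)
    rs, cs = roi.slices()
    template = video.frames[0][rs, cs].astype(np.float64)
    if template.std() < 1e-12:
        raise TrackingLossError("uniform ROI template: correlation undefined",
                                frame_index=0)
    rows, cols = video.shape
    offsets = np.zeros((video.n_frames, 2), dtype=np.int64)
    prev = np.array([0, 0], dtype=np.int64)
    for t in range(1, video.n_frames):
        r0 = max(0, roi.row0 + prev[0] - search_radius)
        c0 = max(0, roi.col0 + prev[1] - search_radius)
        r1 = min(rows, roi.row1 + prev[0] + search_radius)
        c1 = min(cols, roi.col1 + prev[1] + search_radius)
        region = video.frames[t][r0:r1, c0:c1].astype(np.float64)
        if region.shape[0] < roi.height or region.shape[1] < roi.width:
            raise TrackingLossError("ROI left the frame", frame_index=t)
        corr = match_template(region, template)
        peak = corr.max()
        if not np.isfinite(peak) or peak < min_correlation:
            raise TrackingLossError(
                f"correlation peak {peak:.3f} below {min_correlation}",
                frame_index=t)
        pr, pc = np.unravel_index(int(np.argmax(corr)), corr.shape)
        prev = np.array([r0 + pr - roi.row0, c0 + pc - roi.col0])
        offsets[t] = prev
    return ROITrack(roi, offsets)


def rom_waveform(video: ThermalVideo, track: ROITrack,
                 cfg: RrConfig = RrConfig()) -> SignalTrace:
    """Mean ROM temperature per frame.

    The ROM is the centered sub-rectangle of the tracked ROI with
    ``rom_frac`` of its area (aspect preserved); the waveform sample at
    frame ``t`` is the plain arithmetic mean of its temperatures.
    """
    scale = np.sqrt(cfg.rom_frac)
    h = max(1, int(round(track.roi.height * scale)))
    w = max(1, int(round(track.roi.width * scale)))
    dr0 = (track.roi.height - h) // 2
    dc0 = (track.roi.width - w) // 2
    rows, cols = video.shape
    values = np.empty(video.n_frames)
    for t in range(video.n_frames):
        r = track.roi_at(t)
        r0 = min(max(r.row0 + dr0, 0), rows - h)
        c0 = min(max(r.col0 + dc0, 0), cols - w)
        values[t] = video.frames[t][r0:r0 + h, c0:c0 + w].mean()
    return SignalTrace(values, video.fps, video.origin_time)


# ---------------------------------------------------------------------------
# Interval estimators.  ``window`` spans indices [-m, m] around its
# center (length 2m+1); maxima over candidate lags mark the local
# breath-to-breath interval.


def _check_window(window: np.ndarray, m: int) -> np.ndarray:
    w = np.asarray(window, dtype=np.float64)
    if m < 1:
        raise ValueError("lag m must be >= 1")
    if w.ndim != 1 or w.size < 2 * m + 1:
        raise DegenerateInputError(
            f"window of {w.size} samples cannot span [-{m}, {m}]")
    return w


def estimator_ac(window: np.ndarray, m: int) -> float:
    """Adaptive-window autocorrelation:
    ``(1/m) * sum_{v=0..m} w[v] * w[v-m]``."""
    w = _check_window(window, m)
    c = w.size // 2
    return float(np.dot(w[c:c + m + 1], w[c - m:c + 1]) / m)


def estimator_amdf(window: np.ndarray, m: int) -> float:
    """Reciprocal average magnitude difference function:
    ``[(1/m) * sum_{v=0..m} |w[v] - w[v-m]|]^-1`` (epsilon-guarded), so
    that maxima — not minima — mark the true interval."""
    w = _check_window(window, m)
    c = w.size // 2
    mad = np.abs(w[c:c + m + 1] - w[c - m:c + 1]).sum() / m
    return float(1.0 / (mad + _AMDF_EPS))


def estimator_map(window: np.ndarray, m: int) -> float:
    """Maximum amplitude pairs: ``max_{v in 0..m} (w[v] + w[v-m])`` — an
    indirect detector of two peaks separated by ``m`` samples."""
    w = _check_window(window, m)
    c = w.size // 2
    return float(np.max(w[c:c + m + 1] + w[c - m:c + 1]))


def to_posterior(values: np.ndarray, lags: np.ndarray) -> LagPosterior:
    """Shift-and-normalize an estimator profile into a probability mass.

    Values are shifted by their minimum to non-negativity and normalized
    to sum 1; an all-equal profile yields the uniform distribution.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 1 or not np.all(np.isfinite(values)):
        raise DegenerateInputError("estimator values must be finite")
    shifted = values - values.min()
    total = shifted.sum()
    if total <= 0:
        probs = np.full(values.size, 1.0 / values.size)
    else:
        probs = shifted / total
    return LagPosterior(np.asarray(lags), probs)


def fuse_bayes(p_ac: LagPosterior, p_amdf: LagPosterior,
               p_map: LagPosterior) -> tuple[LagPosterior, int]:
    """Naive-Bayes fusion: elementwise product of the three posteriors,
    renormalized; ``m_hat`` is the argmax lag (ties -> smaller lag).

    If the product is identically zero (the estimators fully disagree),
    the autocorrelation posterior is used as a fallback and a
    :class:`FusionDegenerateWarning` is emitted.
    """
    if not (np.array_equal(p_ac.lags, p_amdf.lags)
            and np.array_equal(p_ac.lags, p_map.lags)):
        raise ConfigurationError("posteriors must share one lag grid")
    prod = p_ac.probs * p_amdf.probs * p_map.probs
    total = prod.sum()
    if total <= 0:
        warnings.warn("all-zero posterior product; falling back to the "
                      "autocorrelation posterior", FusionDegenerateWarning)
        fused = p_ac
    else:
        fused = LagPosterior(p_ac.lags, prod / total)
    m_hat = int(fused.lags[int(np.argmax(fused.probs))])
    return fused, m_hat


def select_interval(posterior: LagPosterior, rel_threshold: float = 0.5) -> int:
    """Read the breath-to-breath interval off a fused posterior.

    A periodic waveform supports every integer multiple of its true
    interval equally well, so on near-stationary breathing the posterior
    carries comparable peaks at ``m``, ``2m``, ``3m`` and the plain
    argmax picks among them at random.  All those peaks are evidence for
    the *shortest* of them, so the readout is the smallest local
    posterior maximum whose mass reaches ``rel_threshold`` times the
    global maximum.  On a unimodal posterior this is exactly the argmax.
    """
    p = posterior.probs
    if p.size == 1:
        return int(posterior.lags[0])
    interior = (p[1:-1] >= p[:-2]) & (p[1:-1] >= p[2:])
    is_peak = np.zeros(p.size, dtype=bool)
    is_peak[1:-1] = interior
    is_peak[0] = p[0] >= p[1]
    is_peak[-1] = p[-1] >= p[-2]
    strong = is_peak & (p >= rel_threshold * p.max())
    return int(posterior.lags[np.flatnonzero(strong)[0]])


def interval_posterior(trace: np.ndarray, center: int, m_min: int,
                       m_max: int) -> tuple[LagPosterior, int]:
    """Fused lag posterior at one window center of a filtered trace."""
    lags = np.arange(m_min, m_max + 1)
    e_ac = np.empty(lags.size)
    e_amdf = np.empty(lags.size)
    e_map = np.empty(lags.size)
    for i, m in enumerate(lags):
        w = trace[center - m:center + m + 1]
        e_ac[i] = np.dot(w[m:], w[:m + 1]) / m
        e_amdf[i] = 1.0 / (np.abs(w[m:] - w[:m + 1]).sum() / m + _AMDF_EPS)
        e_map[i] = np.max(w[m:] + w[:m + 1])
    return fuse_bayes(to_posterior(e_ac, lags), to_posterior(e_amdf, lags),
                      to_posterior(e_map, lags))


def estimate_rr_series(video: ThermalVideo, roi: RectROI,
                       cfg: RrConfig = RrConfig()) -> RateSeries:
    """Full respiratory-rate pipeline on a thermal video.

    Estimates are produced at stride-spaced centers with full ``[-m_max,
    m_max]`` support and time-stamped at the center; values outside the
    6-51 breaths/min plausibility band are dropped.
    """
    m_min, m_max = cfg.lag_range(video.fps)
    if video.n_frames < 2 * m_max + 1:
        raise DegenerateInputError(
            f"video of {video.n_frames} frames shorter than the "
            f"2*m_max+1 = {2 * m_max + 1} samples the estimators need")
    try:
        track = track_roi(video, roi, cfg.search_radius, cfg.min_correlation)
    except TrackingLossError as e:
        raise PipelineError(str(e), stage="roi-tracking") from e
    raw = rom_waveform(video, track, cfg)
    filtered = butter_bandpass(raw, *cfg.band).values
    stride = cfg.stride if cfg.stride is not None else int(round(video.fps))
    lo, hi = RR_PLAUSIBLE_BPM
    times, rates = [], []
    for center in range(m_max, filtered.size - m_max, stride):
        posterior, _ = interval_posterior(filtered, center, m_min, m_max)
        m_hat = select_interval(posterior)
        rr = 60.0 * video.fps / m_hat
        if lo <= rr <= hi:
            times.append(video.origin_time + center / video.fps)
            rates.append(rr)
    return RateSeries(np.asarray(times), np.asarray(rates), "respiration")
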