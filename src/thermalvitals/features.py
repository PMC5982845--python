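"""Corner selection and sub-pixel point tracking.

The cardiac signal of interest is a vertical head oscillation that is a
fraction of a pixel at typical camera distances, so everything here is
built around sub-pixel accuracy:

* Shi-Tomasi cornerness ``R = min(lambda1, lambda2)`` of the 2x2
  gradient structure tensor, computed with a closed form for symmetric
  2x2 matrices;
* greedy best-first selection of at most ``max_n`` corners inside a
  manually supplied lower-face rectangle, with the mouth rectangle
  excluded (mouth motion — speech, swallowing — is an artifact source);
* a pyramidal Lucas-Kanade tracker (translation model, bilinear
  sampling, template gradients from the previous frame) that refines all
  points simultaneously per frame;
* pruning of erratic points by their maximum inter-frame jump against a
  percentile of the pooled jump distribution.

Points are seeded once in the first frame and never re-acquired: a lost
point stays lost, which keeps every surviving trajectory comparable over
the full analysis span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (DegenerateInputError, FeatureScarcityError,
                     TrackingFailureError)
from .io_core import RectROI

__all__ = [
    "FeaturePoint",
    "FeatureTrackSet",
    "shi_tomasi_score_map",
    "select_features",
    "track_features",
    "vertical_trajectories",
    "prune_erratic",
]


@dataclass(frozen=True)
class FeaturePoint:
    """A selected corner: ``(y, x)`` = (row, col) sub-pixel position and
    its cornerness score."""

    id: int
    x: float
    y: float
    score: float


@dataclass(frozen=True)
class FeatureTrackSet:
    """Per-point, per-frame positions.

    ``positions``: (n_points, n_frames, 2) with last axis (row, col);
    ``valid``: (n_points, n_frames) flags.  Once a point goes invalid it
    stays invalid for all later frames.
    """

    positions: np.ndarray
    valid: np.ndarray
    fps: float

    def __post_init__(self):
        positions = np.asarray(self.positions, dtype=np.float64)
        valid = np.asarray(self.valid, dtype=bool)
        if positions.ndim != 3 or positions.shape[2] != 2:
            raise ValueError("positions must be (n_points, n_frames, 2)")
        if valid.shape != positions.shape[:2]:
            raise ValueError("valid must be (n_points, n_frames)")
        # monotone validity: no re-acquisition after loss
        if np.any(np.diff(valid.astype(np.int8), axis=1) > 0):
            raise ValueError("a point may not become valid again after loss")
        if not (self.fps > 0):
            raise ValueError("fps must be positive")
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "valid", valid)

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def subset(self, indices) -> "FeatureTrackSet":
        return FeatureTrackSet(self.positions[indices], self.valid[indices],
                               self.fps)

    def to_table(self):
        """Long-form export: columns point_id, frame, x, y, valid."""
        import pandas as pd

        n_p, n_f = self.valid.shape
        return pd.DataFrame({
            "point_id": np.repeat(np.arange(n_p), n_f),
            "frame": np.tile(np.arange(n_f), n_p),
            "x": self.positions[:, :, 1].ravel(),
            "y": self.positions[:, :, 0].ravel(),
            "valid": self.valid.ravel(),
        })


# ---------------------------------------------------------------------------
# Cornerness


def shi_tomasi_score_map(image: np.ndarray, window: int = 5) -> np.ndarray:
    """Smaller structure-tensor eigenvalue at every pixel.

    Sobel gradients are summed over a ``window x window`` neighborhood to
    form the 2x2 tensor [[Sxx, Sxy], [Sxy, Syy]]; the score is its
    smaller eigenvalue via the symmetric closed form.  A half-window
    border is zeroed.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < window:
        raise DegenerateInputError("image smaller than the scoring window")
    gy = ndimage.sobel(image, axis=0, mode="nearest")
    gx = ndimage.sobel(image, axis=1, mode="nearest")
    size = (window, window)
    sxx = ndimage.uniform_filter(gx * gx, size=size, mode="constant")
    syy = ndimage.uniform_filter(gy * gy, size=size, mode="constant")
    sxy = ndimage.uniform_filter(gx * gy, size=size, mode="constant")
    # min eigenvalue of [[a, b], [b, c]] = (a+c)/2 - sqrt(((a-c)/2)^2 + b^2)
    half_tr = 0.5 * (sxx + syy)
    disc = np.sqrt((0.5 * (sxx - syy)) ** 2 + sxy ** 2)
    score = half_tr - disc
    score[score < 0] = 0.0  # numerical round-off only; tensor is PSD
    hw = window // 2
    score[:hw, :] = 0.0
    score[-hw:, :] = 0.0
    score[:, :hw] = 0.0
    score[:, -hw:] = 0.0
    return score


def select_features(score_map: np.ndarray, roi: RectROI,
                    exclusion: RectROI | None = None, max_n: int = 100,
                    quality: float = 0.01, min_dist: float = 5.0
                    ) -> list[FeaturePoint]:
    """Pick the strongest corners inside ``roi`` (minus ``exclusion``).

    Candidates scoring above ``quality`` times the ROI maximum are ranked
    by score; a greedy pass rejects any candidate closer than
    ``min_dist`` pixels to an already accepted one; at most ``max_n``
    points are returned.
    """
    score_map = np.asarray(score_map)
    roi.require_inside(score_map.shape)
    masked = np.zeros_like(score_map)
    rs, cs = roi.slices()
    masked[rs, cs] = score_map[rs, cs]
    if exclusion is not None:
        ers, ecs = exclusion.slices()
        masked[ers, ecs] = 0.0
    peak = masked.max()
    if peak <= 0:
        raise FeatureScarcityError("no corner response inside the ROI")
    rows, cols = np.nonzero(masked > quality * peak)
    if rows.size == 0:
        raise FeatureScarcityError("no candidates above the quality threshold")
    scores = masked[rows, cols]
    order = np.argsort(-scores, kind="stable")
    accepted: list[FeaturePoint] = []
    acc_pos = np.empty((0, 2))
    for idx in order:
        r, c = rows[idx], cols[idx]
        if acc_pos.shape[0]:
            d2 = (acc_pos[:, 0] - r) ** 2 + (acc_pos[:, 1] - c) ** 2
            if d2.min() < min_dist ** 2:
                continue
        accepted.append(FeaturePoint(len(accepted), float(c), float(r),
                                     float(scores[idx])))
        acc_pos = np.vstack([acc_pos, [r, c]])
        if len(accepted) >= max_n:
            break
    return accepted


# ---------------------------------------------------------------------------
# Pyramidal Lucas-Kanade tracking


def _build_pyramid(frame: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [frame]
    for _ in range(1, levels):
        smoothed = ndimage.gaussian_filter(pyr[-1], sigma=1.0, mode="nearest")
        pyr.append(smoothed[::2, ::2])
    return pyr


def _sample(img: np.ndarray, coords_rc: np.ndarray) -> np.ndarray:
    """Bilinear sampling at (2, N) row/col coordinates, borders clamped."""
    rows, cols = img.shape
    r = np.clip(coords_rc[0], 0.0, rows - 1.0)
    c = np.clip(coords_rc[1], 0.0, cols - 1.0)
    r0 = r.astype(np.intp)   # floor: r is non-negative after clipping
    c0 = c.astype(np.intp)
    fr = r - r0
    fc = c - c0
    r1 = np.minimum(r0 + 1, rows - 1)
    c1 = np.minimum(c0 + 1, cols - 1)
    flat = img.ravel()
    b0 = r0 * cols
    b1 = r1 * cols
    i00 = flat.take(b0 + c0)
    i01 = flat.take(b0 + c1)
    i10 = flat.take(b1 + c0)
    i11 = flat.take(b1 + c1)
    top = i00 + fc * (i01 - i00)
    bot = i10 + fc * (i11 - i10)
    return top + fr * (bot - top)


def track_features(frames: np.ndarray, fps: float, seeds: list[FeaturePoint],
                   pyramid_levels: int = 3, patch: int = 21,
                   max_iters: int = 30, eps: float = 0.01,
                   residual_tol: float = 0.25,
                   min_track_frames: int = 256) -> FeatureTrackSet:
    """Track seed points through a preprocessed frame stack.

    Frame-to-frame pyramidal Lucas-Kanade with a pure-translation model:
    per frame pair and pyramid level, the normal equations built from the
    previous frame's patch gradients are iterated until the update falls
    below ``eps`` pixels.  A point is invalidated (permanently) when its
    patch leaves the frame, its normal matrix becomes singular, or its
    final mean absolute residual exceeds ``residual_tol`` (frames are
    expected in [0, 1]).

    Raises :class:`TrackingFailureError` if every point is lost before
    ``min_track_frames`` frames have elapsed.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be (n_frames, rows, cols)")
    if not seeds:
        raise ValueError("no seed points")
    n_frames = frames.shape[0]
    n_pts = len(seeds)
    hw = patch // 2
    off = np.mgrid[-hw:hw + 1, -hw:hw + 1].reshape(2, -1)  # (2, K)
    k_px = off.shape[1]

    positions = np.zeros((n_pts, n_frames, 2))
    valid = np.zeros((n_pts, n_frames), dtype=bool)
    positions[:, 0, 0] = [p.y for p in seeds]
    positions[:, 0, 1] = [p.x for p in seeds]
    valid[:, 0] = True

    pyr_prev = _build_pyramid(np.ascontiguousarray(frames[0], dtype=np.float32),
                              pyramid_levels)

    for t in range(1, n_frames):
        pyr_cur = _build_pyramid(
            np.ascontiguousarray(frames[t], dtype=np.float32), pyramid_levels)
        live = np.flatnonzero(valid[:, t - 1])
        if live.size == 0:
            if t - 1 < min_track_frames:
                raise TrackingFailureError(
                    f"all points lost at frame {t - 1} (< {min_track_frames})")
            break
        p_prev = positions[live, t - 1, :]            # (L, 2) row/col
        disp = np.zeros_like(p_prev)
        alive = np.ones(live.size, dtype=bool)
        residual = np.zeros(live.size)

        for level in range(pyramid_levels - 1, -1, -1):
            scale = 2.0 ** level
            img_p, img_c = pyr_prev[level], pyr_cur[level]
            rows_l, cols_l = img_p.shape
            base = p_prev / scale                      # (L, 2)
            # template patches and gradients from the previous frame
            coords = base[:, :, None] + off[None, :, :]        # (L, 2, K)
            flat = coords.transpose(1, 0, 2).reshape(2, -1)
            inb = ((coords[:, 0, :].min(axis=1) >= 0)
                   & (coords[:, 0, :].max(axis=1) <= rows_l - 1)
                   & (coords[:, 1, :].min(axis=1) >= 0)
                   & (coords[:, 1, :].max(axis=1) <= cols_l - 1))
            if level == 0:
                alive &= inb
            templ = _sample(img_p, flat).reshape(-1, k_px)
            gr = _sample(ndimage.sobel(img_p, axis=0, mode="nearest") / 8.0,
                         flat).reshape(-1, k_px)
            gc = _sample(ndimage.sobel(img_p, axis=1, mode="nearest") / 8.0,
                         flat).reshape(-1, k_px)
            g_rr = (gr * gr).sum(axis=1)
            g_cc = (gc * gc).sum(axis=1)
            g_rc = (gr * gc).sum(axis=1)
            det = g_rr * g_cc - g_rc * g_rc
            singular = det < 1e-12
            alive &= ~singular
            det[singular] = 1.0
            d = disp / scale
            active = alive.copy()
            for _ in range(max_iters):
                if not active.any():
                    break
                cur_coords = (base + d)[:, :, None] + off[None, :, :]
                flat_c = cur_coords.transpose(1, 0, 2).reshape(2, -1)
                cur = _sample(img_c, flat_c).reshape(-1, k_px)
                err = templ - cur
                b_r = (gr * err).sum(axis=1)
                b_c = (gc * err).sum(axis=1)
                step_r = (g_cc * b_r - g_rc * b_c) / det
                step_c = (g_rr * b_c - g_rc * b_r) / det
                step = np.stack([step_r, step_c], axis=1)
                step[~active] = 0.0
                d = d + step
                active = active & (np.hypot(step_r, step_c) > eps)
            if level == 0:
                cur_coords = (base + d)[:, :, None] + off[None, :, :]
                flat_c = cur_coords.transpose(1, 0, 2).reshape(2, -1)
                cur = _sample(img_c, flat_c).reshape(-1, k_px)
                residual = np.abs(templ - cur).mean(axis=1)
            disp = d * scale

        new_pos = p_prev + disp
        rows0, cols0 = frames.shape[1], frames.shape[2]
        inside = ((new_pos[:, 0] >= 0) & (new_pos[:, 0] <= rows0 - 1)
                  & (new_pos[:, 1] >= 0) & (new_pos[:, 1] <= cols0 - 1))
        jump_ok = np.hypot(disp[:, 0], disp[:, 1]) <= patch
        ok = alive & inside & jump_ok & (residual <= residual_tol)
        positions[live, t, :] = new_pos
        valid[live, t] = ok
        pyr_prev = pyr_cur

    if not valid[:, min(min_track_frames, n_frames) - 1].any():
        raise TrackingFailureError(
            f"all points lost before {min(min_track_frames, n_frames)} frames")
    return FeatureTrackSet(positions, valid, fps)


# ---------------------------------------------------------------------------
# Trajectories


def vertical_trajectories(tracks: FeatureTrackSet,
                          require_full: bool = True) -> tuple[np.ndarray, float]:
    """(n_frames x n_points) matrix of mean-removed row coordinates.

    With ``require_full`` (default) only points valid on every frame are
    used, so every column covers the same span.
    """
    if require_full:
        keep = tracks.valid.all(axis=1)
    else:
        keep = tracks.valid.any(axis=1)
    y = tracks.positions[keep, :, 0].T.copy()     # (n_frames, n_kept)
    if y.size:
        y -= y.mean(axis=0, keepdims=True)
    return y, tracks.fps


def prune_erratic(tracks: FeatureTrackSet, percentile: float = 95.0,
                  min_keep: int = 10) -> FeatureTrackSet:
    """Drop points whose largest inter-frame jump exceeds the given
    percentile of the pooled jump distribution.

    The threshold is strict (``>``), so when every point moves identically
    nothing is dropped.  Never returns fewer than ``min_keep`` points: if
    pruning would, the ``min_keep`` steadiest points are kept instead.
    """
    if tracks.n_frames < 2:
        raise DegenerateInputError("need at least 2 frames to prune")
    steps = np.diff(tracks.positions, axis=1)                  # (P, F-1, 2)
    mags = np.hypot(steps[:, :, 0], steps[:, :, 1])
    pair_valid = tracks.valid[:, 1:] & tracks.valid[:, :-1]
    pooled = mags[pair_valid]
    if pooled.size == 0:
        return tracks
    thr = np.percentile(pooled, percentile)
    per_point = np.where(pair_valid, mags, -np.inf).max(axis=1)
    keep = per_point <= thr
    if keep.sum() < min(min_keep, tracks.n_points):
        order = np.argsort(per_point, kind="stable")
        keep = np.zeros(tracks.n_points, dtype=bool)
        keep[order[:min(min_keep, tracks.n_points)]] = True
    return tracks.subset(keep)
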