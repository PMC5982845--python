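"""Core containers and file I/O for thermal video and rate series.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)`` with row increasing
  downward; "vertical" always means the row coordinate.  A consistent
  convention keeps the polarity of the ballistocardiographic motion signal
  well defined (polarity is irrelevant to spectra but must not flip
  between stages).
* Temperatures are stored internally as degrees Celsius in floating
  point; the radiometric calibration (counts -> kelvin-scaled counts ->
  Celsius) lives only at the I/O boundary, because the method uses
  temperature *fluctuations*, not absolute accuracy.
* Canonical on-disk form is a multi-page 16-bit little-endian TIFF plus a
  JSON sidecar ``{"fps": ..., "scale": ..., "offset": ...}`` where
  ``temperature = counts * scale + offset``.  A single-file ``.npz``
  archive with ``frames``/``fps``/``origin_time`` entries is accepted as
  an alternative container.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigurationError, EmptySeriesError, FormatError

__all__ = [
    "ThermalVideo",
    "RectROI",
    "SignalTrace",
    "RateSeries",
    "read_video",
    "write_video",
    "read_rate_csv",
    "write_rate_csv",
    "HR_PLAUSIBLE_BPM",
    "RR_PLAUSIBLE_BPM",
]

#: Plausibility bands for rate values, per-minute units.  These are the
#: physiological pass bands of the two branches times 60 (0.65-2 Hz for
#: the cardiac readout, 0.1-0.85 Hz for respiration).
HR_PLAUSIBLE_BPM = (39.0, 120.0)
RR_PLAUSIBLE_BPM = (6.0, 51.0)


def _require_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} must be finite (no NaN/inf)")


@dataclass(frozen=True)
class ThermalVideo:
    """Calibrated temperature frame stack.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Per-pixel temperatures in degrees Celsius.
    fps : float
        Acquisition frame rate in Hz.
    origin_time : float
        Wall-clock time of the first frame, seconds (default 0).
    """

    frames: np.ndarray
    fps: float
    origin_time: float = 0.0

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if not np.issubdtype(frames.dtype, np.floating):
            frames = frames.astype(np.float64)
        if frames.ndim != 3:
            raise ValueError("frames must be 3-D (time, rows, cols)")
        if frames.shape[0] < 1 or frames.shape[1] < 1 or frames.shape[2] < 1:
            raise ValueError("frames must contain at least one 1x1 frame")
        _require_finite(frames, "frames")
        if not (self.fps > 0):
            raise ValueError("fps must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    def times(self) -> np.ndarray:
        return self.origin_time + np.arange(self.n_frames) / self.fps


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle, 0-based, half-open
    ``[row0, row0+height) x [col0, col0+width)``."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI height and width must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")

    @property
    def row1(self) -> int:
        return self.row0 + self.height

    @property
    def col1(self) -> int:
        return self.col0 + self.width

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def contains_point(self, row: float, col: float) -> bool:
        return self.row0 <= row < self.row1 and self.col0 <= col < self.col1

    def require_inside(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        if self.row1 > rows or self.col1 > cols:
            raise ValueError(
                f"ROI {self} does not fit inside a {rows}x{cols} frame"
            )

    def shifted(self, drow: int, dcol: int) -> "RectROI":
        return RectROI(self.row0 + drow, self.col0 + dcol, self.height, self.width)

    @classmethod
    def from_string(cls, text: str) -> "RectROI":
        """Parse ``"row0,col0,height,width"`` (CLI form)."""
        parts = text.split(",")
        if len(parts) != 4:
            raise ConfigurationError(
                f"ROI string must be 'row0,col0,height,width', got {text!r}"
            )
        try:
            r0, c0, h, w = (int(p) for p in parts)
        except ValueError as e:
            raise ConfigurationError(f"non-integer ROI component in {text!r}") from e
        try:
            return cls(r0, c0, h, w)
        except ValueError as e:
            raise ConfigurationError(str(e)) from e


@dataclass(frozen=True)
class SignalTrace:
    """Uniformly sampled 1-D series (temperature or displacement)."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("values must be a non-empty 1-D vector")
        _require_finite(values, "values")
        if not (self.fs > 0):
            raise ValueError("fs must be positive")
        object.__setattr__(self, "values", values)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


_KIND_BANDS = {"heart": HR_PLAUSIBLE_BPM, "respiration": RR_PLAUSIBLE_BPM}


@dataclass(frozen=True)
class RateSeries:
    """Time-stamped instantaneous rate estimates in per-minute units.

    ``kind`` is ``"heart"`` or ``"respiration"``; values must lie inside
    the kind's plausibility band (overridable via ``band``).  An empty
    series is allowed and represents "no confident estimate produced".
    """

    times: np.ndarray
    rates: np.ndarray
    kind: str
    band: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in _KIND_BANDS:
            raise ValueError(f"kind must be one of {sorted(_KIND_BANDS)}")
        times = np.asarray(self.times, dtype=np.float64)
        rates = np.asarray(self.rates, dtype=np.float64)
        if times.ndim != 1 or rates.ndim != 1 or times.size != rates.size:
            raise ValueError("times and rates must be 1-D and equally long")
        _require_finite(times, "times")
        _require_finite(rates, "rates")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        band = self.band if self.band is not None else _KIND_BANDS[self.kind]
        if rates.size and (np.any(rates < band[0]) or np.any(rates > band[1])):
            raise ValueError(
                f"{self.kind} rates outside plausibility band {band} per minute"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "band", band)

    def __len__(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# Video I/O


def _load_sidecar(sidecar) -> dict:
    try:
        with open(sidecar) as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as e:
        raise FormatError(f"sidecar {sidecar} is not valid JSON: {e}") from e
    missing = {"fps", "scale", "offset"} - meta.keys()
    if missing:
        raise ConfigurationError(f"sidecar missing keys: {sorted(missing)}")
    if not (float(meta["fps"]) > 0):
        raise ConfigurationError("sidecar fps must be positive")
    if not (float(meta["scale"]) > 0):
        raise ConfigurationError("sidecar scale must be positive")
    return meta


def read_video(path, sidecar=None) -> ThermalVideo:
    """Read a thermal video.

    ``path`` is either a multi-page 16-bit TIFF (``sidecar`` JSON required,
    supplying ``fps``, ``scale`` in K per count and ``offset`` in Celsius)
    or a ``.npz`` archive written by :func:`write_video`.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as npz:
            frames = npz["frames"]
            fps = float(npz["fps"])
            origin = float(npz["origin_time"]) if "origin_time" in npz else 0.0
        return ThermalVideo(frames, fps, origin)
    if sidecar is None:
        raise ConfigurationError("TIFF input requires a JSON sidecar")
    meta = _load_sidecar(sidecar)
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) != 1:
            raise FormatError(f"TIFF pages differ in shape: {sorted(shapes)}")
        raw = tif.asarray()
    if raw.ndim == 2:  # single-page file
        raw = raw[None]
    frames = raw.astype(np.float64) * float(meta["scale"]) + float(meta["offset"])
    return ThermalVideo(frames, float(meta["fps"]),
                        float(meta.get("origin_time", 0.0)))


def write_video(video: ThermalVideo, path, sidecar=None, scale: float = 0.01,
                offset: float | None = None) -> None:
    """Write a video as 16-bit TIFF + sidecar (or ``.npz`` if so suffixed).

    The affine map is the inverse of :func:`read_video`'s:
    ``counts = round((T - offset) / scale)`` clipped to [0, 65535].  The
    default scale of 0.01 K per count keeps the quantization step well
    below the sensor noise floor.  ``offset`` defaults to slightly below
    the video minimum so the full range is representable.
    """
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, frames=video.frames.astype(np.float32),
                            fps=video.fps, origin_time=video.origin_time)
        return
    if sidecar is None:
        raise ConfigurationError("TIFF output requires a sidecar path")
    if offset is None:
        offset = float(np.floor(video.frames.min()) - 1.0)
    counts = np.round((video.frames - offset) / scale)
    counts = np.clip(counts, 0, 65535).astype("<u2")
    tifffile.imwrite(path, counts, photometric="minisblack")
    meta = {"fps": video.fps, "scale": scale, "offset": offset,
            "origin_time": video.origin_time}
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2)


# ---------------------------------------------------------------------------
# Rate-series CSV


def read_rate_csv(path) -> RateSeries:
    """Read a rate CSV (``time_s,rate_per_min`` plus ``# kind:`` comment)."""
    kind = None
    rows: list[tuple[float, float]] = []
    header_seen = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("kind:"):
                    kind = body.split(":", 1)[1].strip()
                continue
            if not header_seen:
                if line.replace(" ", "") != "time_s,rate_per_min":
                    raise FormatError(
                        f"expected header 'time_s,rate_per_min', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"malformed data row: {line!r}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as e:
                raise FormatError(f"non-numeric data row: {line!r}") from e
    if kind is None:
        raise FormatError("missing '# kind:' comment line")
    if not header_seen:
        raise FormatError("missing CSV header")
    if not rows:
        raise EmptySeriesError(f"{path} contains no data rows")
    times = np.array([r[0] for r in rows])
    rates = np.array([r[1] for r in rows])
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise FormatError("times are not strictly increasing")
    try:
        return RateSeries(times, rates, kind)
    except ValueError as e:
        raise FormatError(str(e)) from e


def write_rate_csv(series: RateSeries, path) -> None:
    buf = io.StringIO()
    buf.write(f"# kind: {series.kind}\n")
    buf.write("time_s,rate_per_min\n")
    for t, r in zip(series.times, series.rates):
        buf.write(f"{t:.10g},{r:.10g}\n")
    Path(path).write_text(buf.getvalue())
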