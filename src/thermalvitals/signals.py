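"""Shared 1-D signal machinery: band-pass filtering, amplitude spectra,
dominant-frequency readout and the peak-to-total periodicity score.

Filtering is zero-phase (forward-backward second-order Butterworth by
default).  Zero-phase matters here because the heart-rate branch compares
signals across channels and windows inside a PCA; single-pass IIR phase
would bias the decomposition.  A consequence worth remembering: the
magnitude response is squared, so the nominal 3 dB cutoffs become 6 dB
points (gain 0.5) of the composite filter.

Spectra of 256-sample windows are Hann-tapered and zero-padded to 4096
points before the FFT.  The raw bin width at 50 Hz sampling and 256
samples is ~0.2 Hz (~12 beats/min), far coarser than the per-minute
errors this method is expected to deliver, so interpolation — zero
padding plus a final 3-point parabolic refinement of the peak — is part
of the readout, not a cosmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, DegenerateInputError
from .io_core import SignalTrace

__all__ = [
    "Spectrum",
    "butter_bandpass",
    "amplitude_spectrum",
    "dominant_frequency",
    "peak_to_total_ratio",
]


@dataclass(frozen=True)
class Spectrum:
    """One-sided amplitude spectrum on a uniform frequency grid."""

    freqs: np.ndarray
    amps: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=np.float64)
        amps = np.asarray(self.amps, dtype=np.float64)
        if freqs.ndim != 1 or amps.ndim != 1 or freqs.size != amps.size:
            raise ValueError("freqs and amps must be 1-D of equal length")
        if freqs.size > 1 and not np.all(np.diff(freqs) > 0):
            raise ValueError("freqs must be ascending")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "amps", amps)


def butter_bandpass(trace: SignalTrace, f_lo: float, f_hi: float,
                    order: int = 2) -> SignalTrace:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    nyq = trace.fs / 2.0
    if not (0 < f_lo < f_hi < nyq):
        raise ConfigurationError(
            f"need 0 < f_lo < f_hi < Nyquist ({nyq} Hz); got ({f_lo}, {f_hi})")
    settle = 3 * (2 * order + 1)
    if trace.values.size <= 3 * settle:
        raise DegenerateInputError(
            f"trace of {trace.values.size} samples too short to filter "
            f"(need > {3 * settle})")
    sos = sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=trace.fs,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, trace.values)
    return SignalTrace(filtered, trace.fs, trace.t0)


def filter_columns(matrix: np.ndarray, fs: float, f_lo: float, f_hi: float,
                   order: int = 2) -> np.ndarray:
    """Apply :func:`butter_bandpass` to each column of a (samples x
    channels) matrix in one vectorized pass."""
    nyq = fs / 2.0
    if not (0 < f_lo < f_hi < nyq):
        raise ConfigurationError(
            f"need 0 < f_lo < f_hi < Nyquist ({nyq} Hz); got ({f_lo}, {f_hi})")
    sos = sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, matrix, axis=0)


def amplitude_spectrum(window: SignalTrace, pad_to: int = 4096) -> Spectrum:
    """Hann-tapered, zero-padded FFT magnitude on the non-negative grid."""
    x = window.values
    if x.size < 2:
        raise DegenerateInputError("need at least 2 samples for a spectrum")
    n = max(int(pad_to), x.size)
    tapered = x * np.hanning(x.size)
    amps = np.abs(np.fft.rfft(tapered, n=n))
    freqs = np.fft.rfftfreq(n, d=1.0 / window.fs)
    return Spectrum(freqs, amps)


def dominant_frequency(spec: Spectrum, band: tuple[float, float]) -> float:
    """Argmax amplitude within ``band``, refined by 3-point parabolic
    interpolation; ties break toward the lower frequency."""
    f_min, f_max = band
    if not (f_min < f_max):
        raise ConfigurationError("band must satisfy f_min < f_max")
    in_band = np.flatnonzero((spec.freqs >= f_min) & (spec.freqs <= f_max))
    if in_band.size == 0:
        raise ConfigurationError(
            f"band ({f_min}, {f_max}) Hz does not intersect the grid")
    local = int(np.argmax(spec.amps[in_band]))  # first max -> lower frequency
    i = int(in_band[local])
    f = spec.freqs[i]
    # parabolic refinement on the full grid, only at a strict interior peak
    if 0 < i < spec.freqs.size - 1:
        a, b, c = spec.amps[i - 1], spec.amps[i], spec.amps[i + 1]
        denom = a - 2 * b + c
        if denom < 0 and b > a and b > c:
            delta = 0.5 * (a - c) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            df = spec.freqs[1] - spec.freqs[0]
            f = f + delta * df
    return float(f)


def peak_to_total_ratio(spec: Spectrum, f_dom: float,
                        half_width: float = 0.05) -> float:
    """Fraction of spectral power within ``half_width`` of the dominant
    frequency and of its first harmonic; power is amplitude squared.

    The score is scale invariant and lies in [0, 1]; harmonic bands that
    extend beyond Nyquist are simply clipped by the grid.
    """
    power = spec.amps ** 2
    total = power.sum()
    if total <= 0:
        raise DegenerateInputError("zero total spectral power")
    near = (np.abs(spec.freqs - f_dom) <= half_width) | \
           (np.abs(spec.freqs - 2 * f_dom) <= half_width)
    return float(power[near].sum() / total)
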