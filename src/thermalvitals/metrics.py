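"""Agreement statistics between estimated and reference rate series.

Two complementary views are provided, because method-comparison studies
report both:

* instantaneous agreement — estimates aligned to a reference series,
  summarized by RMSE, the mean relative error, its 90th percentile
  (``eps90``) and Bland-Altman bias/limits over the pooled pairs; and
* subject-level agreement — per-recording mean rates compared via the
  relative error and its complement CAND = 1 - |GT - TI| / GT.

A small set of published per-subject validation tables from a pilot
study of this method on healthy adults (frontal- and side-view thermal
recordings against PPG / piezoplethysmography references) is bundled as
CSV package data; see :func:`load_validation_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateInputError, DomainError
from .io_core import RateSeries

__all__ = [
    "ValidationRow", "align_series", "rmse", "relative_errors", "eps90",
    "cand", "bland_altman", "aggregate_validation",
    "mean_rate_relative_error", "load_validation_table", "summarize_pair",
]


@dataclass(frozen=True)
class ValidationRow:
    """One subject's validation summary (per-minute rates)."""

    subject_id: str
    mean_gt: float
    mean_irt: float
    rmse: float
    eps_mean: float
    eps90: float

    def __post_init__(self):
        if self.mean_gt <= 0:
            raise ValueError("mean_gt must be positive")
        for name in ("mean_irt", "rmse", "eps_mean", "eps90"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def align_series(est: RateSeries, ref: RateSeries
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pair the two series on the estimate's timestamps.

    The reference is linearly interpolated onto the estimate grid inside
    the overlapping span; estimate samples outside the overlap are
    dropped.  Returns ``(est_values, ref_values)``.
    """
    if len(est) == 0 or len(ref) == 0:
        raise AlignmentError("cannot align an empty series")
    t_lo = max(est.times[0], ref.times[0])
    t_hi = min(est.times[-1], ref.times[-1])
    keep = (est.times >= t_lo) & (est.times <= t_hi)
    if t_lo > t_hi or not keep.any():
        raise AlignmentError("series do not overlap in time")
    ref_on_est = np.interp(est.times[keep], ref.times, ref.rates)
    return est.rates[keep], ref_on_est


def _as_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    est, ref = pairs
    est = np.asarray(est, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if est.size == 0 or est.shape != ref.shape:
        raise DegenerateInputError("need equally long, non-empty pair vectors")
    return est, ref


def rmse(pairs) -> float:
    """Root-mean-square error of (est, ref) pairs, per-minute units."""
    est, ref = _as_pairs(pairs)
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def relative_errors(pairs) -> np.ndarray:
    """``|est - ref| / ref`` per pair (dimensionless)."""
    est, ref = _as_pairs(pairs)
    return np.abs(est - ref) / ref


def eps90(rel_errors: np.ndarray) -> float:
    """90th percentile of the relative errors (linear interpolation
    between order statistics)."""
    rel_errors = np.asarray(rel_errors, dtype=np.float64)
    if rel_errors.size == 0:
        raise DegenerateInputError("no errors to summarize")
    return float(np.percentile(rel_errors, 90))


def cand(gt: float, ti: float) -> float:
    """Complement of the absolute normalized difference,
    ``1 - |gt - ti| / gt``; equals 1 for perfect agreement."""
    if gt <= 0:
        raise DomainError("gt must be positive")
    return 1.0 - abs(gt - ti) / gt


def bland_altman(pairs) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement.

    Differences are ``est - ref``; limits are ``bias +/- 1.96 * sd`` with
    the sample (n-1) standard deviation.
    """
    est, ref = _as_pairs(pairs)
    if est.size < 2:
        raise DegenerateInputError("need >= 2 pairs for limits of agreement")
    diffs = est - ref
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


_COLUMNS = ("mean_gt", "mean_irt", "rmse", "eps_mean", "eps90")


def aggregate_validation(rows: list[ValidationRow]) -> dict[str, tuple[float, float]]:
    """Column-wise mean and sample SD over subjects (the "Mean +/- SD"
    bottom row of a validation table)."""
    if len(rows) < 2:
        raise DegenerateInputError("need >= 2 rows to aggregate")
    out = {}
    for col in _COLUMNS:
        vals = np.array([getattr(r, col) for r in rows], dtype=np.float64)
        out[col] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def mean_rate_relative_error(rows: list[ValidationRow]) -> float:
    """Mean over subjects of ``|mean_gt - mean_irt| / mean_gt``."""
    if not rows:
        raise DegenerateInputError("no rows")
    errs = [abs(r.mean_gt - r.mean_irt) / r.mean_gt for r in rows]
    return float(np.mean(errs))


def mean_cand(rows: list[ValidationRow]) -> float:
    """Mean CAND of the per-subject mean-rate pairs."""
    if not rows:
        raise DegenerateInputError("no rows")
    return float(np.mean([cand(r.mean_gt, r.mean_irt) for r in rows]))


_TABLE_FILES = {
    "rr_frontal": "rr_frontal.csv",
    "hr_frontal": "hr_frontal.csv",
    "hr_side": "hr_side.csv",
}


def load_validation_table(name: str) -> list[ValidationRow]:
    """Load a bundled validation table.

    Names: ``rr_frontal`` (16 subjects, respiration, frontal view),
    ``hr_frontal`` (18 subjects, heart, frontal view), ``hr_side``
    (16 subjects, heart, side view).
    """
    if name not in _TABLE_FILES:
        raise KeyError(f"unknown table {name!r}; choose from "
                       f"{sorted(_TABLE_FILES)}")
    ref = resources.files("thermalvitals.data") / _TABLE_FILES[name]
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    return [ValidationRow(str(r.subject_id), r.mean_gt, r.mean_irt, r.rmse,
                          r.eps_mean, r.eps90)
            for r in df.itertuples(index=False)]


def summarize_pair(est: RateSeries, ref: RateSeries) -> dict[str, float]:
    """Instantaneous-agreement summary of one (estimate, reference) pair."""
    pairs = align_series(est, ref)
    rel = relative_errors(pairs)
    bias, lo, hi = bland_altman(pairs) if pairs[0].size >= 2 else (
        float(pairs[0][0] - pairs[1][0]), np.nan, np.nan)
    return {
        "n_pairs": int(pairs[0].size),
        "mean_est": float(pairs[0].mean()),
        "mean_ref": float(pairs[1].mean()),
        "rmse": rmse(pairs),
        "eps_mean": float(rel.mean()),
        "eps90": eps90(rel),
        "bias": bias,
        "loa_low": lo,
        "loa_high": hi,
        "cand_mean_rate": cand(float(pairs[1].mean()), float(pairs[0].mean())),
    }
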