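"""Detrended Fluctuation Analysis (DFA-1) and Hurst-exponent estimation.

The mean-centered series is integrated; the profile is cut into
non-overlapping epochs of each scale, a least-squares line removed from every
epoch, and the root-mean-square residual over the covered points recorded per
scale.  The Hurst exponent H is the slope of log RMS vs log scale: H = 0.5 for
an uncorrelated series, H > 0.5 for long-range positive correlation, H < 0.5
for anti-correlation.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .containers import DFAResult
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "DetrendedFluctuation",
    "dfa_profile",
    "dfa_fluctuation",
    "hurst_exponent",
    "default_scales",
]


def dfa_profile(signal: Sequence[float]) -> np.ndarray:
    """Cumulative sum of the mean-centered series (the integrated profile).

    The profile telescopes back to ~0 at its last point; a constant input
    yields an all-zero profile (warned, since it carries no fluctuation).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise InvalidInputError("DFA needs a 1-D series of at least 4 points")
    if np.ptp(x) == 0:
        warnings.warn("constant series: DFA profile is identically zero")
    return np.cumsum(x - x.mean())


def _epoch_detrend_rms(profile: np.ndarray, scale: int, poly_order: int) -> float:
    """RMS residual of per-epoch polynomial detrending at one scale.

    The tail remainder (N mod scale) is not covered by any epoch and is
    excluded from the sum; the normalizer is the number of covered points.
    """
    n_ep = profile.size // scale
    seg = profile[: n_ep * scale].reshape(n_ep, scale)
    t = np.arange(scale, dtype=float)
    # one Vandermonde solve for all epochs at this scale
    design = np.vander(t, poly_order + 1)
    coef, *_ = np.linalg.lstsq(design, seg.T, rcond=None)
    resid = seg.T - design @ coef
    return float(np.sqrt(np.mean(resid * resid)))


def dfa_fluctuation(
    signal: Sequence[float], scales: Sequence[int], poly_order: int = 1
) -> DFAResult:
    """RMS fluctuation of the detrended profile at each scale, plus the H fit."""
    x = np.asarray(signal, dtype=float)
    scales = np.asarray(scales, dtype=int)
    if scales.size == 0 or np.any(np.diff(scales) <= 0):
        raise InvalidParameterError("scales must be a non-empty strictly increasing sequence")
    if scales[0] < poly_order + 2:
        raise InvalidParameterError(
            f"smallest scale {scales[0]} cannot fit a degree-{poly_order} polynomial"
        )
    if scales[-1] > x.size // 2:
        raise InvalidParameterError(
            f"largest scale {scales[-1]} exceeds half the series length ({x.size})"
        )
    profile = dfa_profile(x)
    rms = np.array([_epoch_detrend_rms(profile, int(s), poly_order) for s in scales])
    h, r2 = _loglog_fit(scales, rms)
    return DFAResult(scales_samples=scales, rms=rms, hurst=h, fit_r2=r2)


def _loglog_fit(scales: np.ndarray, rms: np.ndarray) -> Tuple[float, float]:
    keep = rms > 0
    if np.sum(~keep):
        warnings.warn(f"excluding {int(np.sum(~keep))} scale(s) with zero fluctuation from the fit")
    if np.sum(keep) < 3:
        return float("nan"), float("nan")
    lx, ly = np.log(scales[keep].astype(float)), np.log(rms[keep])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = np.sum((ly - pred) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(r2)


def hurst_exponent(result: DFAResult) -> float:
    """Least-squares slope of log RMS vs log scale.

    Scales with zero fluctuation are excluded with a warning; fewer than three
    usable scales leave the slope undefined.
    """
    keep = result.rms > 0
    if np.sum(keep) < 3:
        raise InvalidInputError("need at least 3 scales with positive RMS to fit H")
    h, _ = _loglog_fit(np.asarray(result.scales_samples), np.asarray(result.rms))
    return h


def default_scales(fs: float, n_samples: Optional[int] = None, n_scales: int = 15,
                   min_s: float = 60.0, max_s: float = 3600.0) -> np.ndarray:
    """15 logarithmically spaced epoch lengths spanning 1 to 60 minutes.

    Rounded to integer samples with duplicates removed.  When the series
    length is given and the recording is shorter than twice the longest
    scale, oversized scales are dropped with a warning.
    """
    if fs <= 0:
        raise InvalidParameterError(f"fs must be positive, got {fs}")
    scales = np.unique(np.round(np.geomspace(min_s * fs, max_s * fs, n_scales)).astype(int))
    if n_samples is not None:
        keep = scales <= n_samples // 2
        if not np.all(keep):
            warnings.warn(
                f"recording of {n_samples} samples is shorter than twice the largest "
                f"scale; truncating to {int(keep.sum())} scales"
            )
            scales = scales[keep]
    return scales


class DetrendedFluctuation(BaseEstimator):
    """Estimator-style DFA: ``fit(x)`` exposes ``rms_``, ``hurst_`` and ``fit_r2_``.

    Parameters
    ----------
    scales : sequence of int, optional
        Epoch lengths in samples.  When omitted, 15 log-spaced scales spanning
        1-60 minutes at ``fs`` are used (truncated to the series length).
    poly_order : int
        Detrending polynomial order per epoch (1 = classic DFA-1).
    fs : float
        Sampling rate used only to build default scales.
    """

    def __init__(self, scales: Optional[Sequence[int]] = None, poly_order: int = 1, fs: float = 1.0):
        self.scales = scales
        self.poly_order = poly_order
        self.fs = fs

    def fit(self, X, y=None) -> "DetrendedFluctuation":
        x = np.ravel(np.asarray(X, dtype=float))
        scales = (
            default_scales(self.fs, n_samples=x.size)
            if self.scales is None
            else np.asarray(self.scales, dtype=int)
        )
        res = dfa_fluctuation(x, scales, poly_order=self.poly_order)
        self.scales_ = res.scales_samples
        self.rms_ = res.rms
        self.hurst_ = res.hurst
        self.fit_r2_ = res.fit_r2
        return self

    def result(self) -> DFAResult:
        check_is_fitted(self, "rms_")
        return DFAResult(self.scales_, self.rms_, self.hurst_, self.fit_r2_)
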