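"""Per-second state classification of the motion envelope.

Each second of the max-normalized envelope is summarized by its mean-square
power sigma^2 and classified with two thresholds: below ``th_abs`` the bed is
empty (ABS), above ``th_di`` the subject is moving (DI).  The band in between
is quiet only if it lasts: maximal in-between runs of at least ``min_qs_s``
seconds become quiet sleep (QS), shorter ones disrupted sleep (DS).
"""

from __future__ import annotations

import warnings
from typing import List, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .containers import ABS, DI, DS, MID, QS, MotionSignal, PowerSeries, Run, SleepIndexes, StateLabels
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "SleepStateClassifier",
    "window_power",
    "classify_coarse",
    "refine_qs_ds",
    "summarize_states",
    "calibrate_abs_threshold",
    "runs_of",
]


def window_power(signal: MotionSignal, hop_s: float = 1.0) -> PowerSeries:
    """Mean-square power of the envelope over non-overlapping ``hop_s`` windows.

    A trailing partial window is dropped.  The thresholds are defined on the
    normalized envelope, so an unnormalized input is rejected.
    """
    if not signal.normalized:
        raise InvalidInputError("power thresholds are defined on the max-normalized envelope")
    n_per = int(round(signal.fs * hop_s))
    if n_per < 1:
        raise InvalidParameterError(f"hop of {hop_s} s at {signal.fs} Hz spans <1 sample")
    n_win = signal.values.size // n_per
    if n_win < 1:
        raise InvalidInputError("signal shorter than one power window")
    x = signal.values[: n_win * n_per].reshape(n_win, n_per)
    return PowerSeries(np.mean(x * x, axis=1), hop_s=hop_s)


def runs_of(labels: np.ndarray) -> List[Run]:
    """Maximal runs of equal labels, tiling the sequence without overlap."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [Run(str(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def classify_coarse(power: PowerSeries, th_abs: float, th_di: float) -> np.ndarray:
    """Label each second ABS / MID / DI by strict threshold comparisons.

    Equality with either threshold falls in the middle band (the in-bed,
    no-displacement state), matching the strict inequalities that define
    ABS and DI.
    """
    if not 0 <= th_abs < th_di:
        raise InvalidParameterError(f"need 0 <= th_abs < th_di, got ({th_abs}, {th_di})")
    labels = np.full(power.values.shape, MID, dtype="U3")
    labels[power.values < th_abs] = ABS
    labels[power.values > th_di] = DI
    return labels


def refine_qs_ds(
    coarse: np.ndarray,
    min_qs_s: float = 900.0,
    th_abs: float = np.nan,
    th_di: float = np.nan,
) -> StateLabels:
    """Split the middle band into QS/DS by run length.

    A maximal MID run of at least ``min_qs_s`` seconds becomes QS, shorter
    runs DS (a run of exactly ``min_qs_s`` counts as quiet).  Runs abutting
    the recording edges are judged by their observed length.
    """
    if min_qs_s <= 0:
        raise InvalidParameterError(f"min_qs_s must be positive, got {min_qs_s}")
    coarse = np.asarray(coarse, dtype="U3")
    out = coarse.copy()
    for run in runs_of(coarse):
        if run.state == MID:
            state = QS if run.duration_s >= min_qs_s else DS
            out[run.start_s : run.start_s + run.duration_s] = state
    return StateLabels(out, th_abs=th_abs, th_di=th_di, min_qs_s=min_qs_s)


def summarize_states(labels: StateLabels) -> SleepIndexes:
    """Percent of seconds per state plus displacement-event counts/durations."""
    arr = labels.labels
    total = arr.size
    pct = {s: 100.0 * int(np.sum(arr == s)) / total for s in (QS, DS, DI, ABS)}
    di_runs = [r for r in runs_of(arr) if r.state == DI]
    return SleepIndexes(
        qs_pct=pct[QS],
        ds_pct=pct[DS],
        di_pct=pct[DI],
        abs_pct=pct[ABS],
        n_di_events=len(di_runs),
        di_durations_s=np.array([r.duration_s for r in di_runs], dtype=int),
    )


def _as_values(x: Union[PowerSeries, Sequence[float], np.ndarray]) -> np.ndarray:
    vals = x.values if isinstance(x, PowerSeries) else np.asarray(x, dtype=float)
    if vals.size == 0:
        raise InvalidInputError("empty power series")
    return vals


def calibrate_abs_threshold(
    power_empty: Union[PowerSeries, np.ndarray],
    power_occupied: Union[PowerSeries, np.ndarray],
) -> float:
    """Absence threshold from a short empty-bed vs occupied-bed calibration.

    Candidate cuts are the midpoints between consecutive distinct values of the
    pooled samples; the one maximizing Youden's J = P(occupied > t) +
    P(empty <= t) - 1 is returned (ties: the lowest cut; perfect separation
    yields the midpoint of the gap between the two classes).  If no cut beats
    J = 0 the two distributions are indistinguishable: a warning is issued and
    the pooled median returned.
    """
    empty = _as_values(power_empty)
    occ = _as_values(power_occupied)
    pooled = np.unique(np.concatenate([empty, occ]))
    if pooled.size < 2:
        warnings.warn("empty and occupied powers are identical; returning pooled median")
        return float(np.median(np.concatenate([empty, occ])))
    cuts = 0.5 * (pooled[:-1] + pooled[1:])
    j = np.array(
        [np.mean(occ > c) + np.mean(empty <= c) - 1.0 for c in cuts]
    )
    best = int(np.argmax(j))  # argmax takes the first (lowest) cut on ties
    if j[best] <= 0:
        warnings.warn(
            "no threshold separates empty from occupied (J <= 0); returning pooled median"
        )
        return float(np.median(np.concatenate([empty, occ])))
    return float(cuts[best])


class SleepStateClassifier(BaseEstimator):
    """Threshold classifier mapping a per-second power series to ABS/QS/DS/DI.

    Parameters
    ----------
    th_abs : float
        Power below which the bed is considered empty (default 1e-3 on the
        normalized envelope; absence was never observed in the study cohorts,
        so this sits well below the smallest displacement threshold examined).
    th_di : float
        Power above which a displacement is detected (default 0.05, the
        grid-search optimum).
    min_qs_s : float
        Minimum duration of a movement-free interval to count as quiet sleep
        (default 900 s = 15 min, the grid-search optimum).

    ``predict`` returns the per-second label array; ``predict_labels`` wraps it
    in a :class:`StateLabels` carrying the parameters used.
    """

    def __init__(self, th_abs: float = 1e-3, th_di: float = 0.05, min_qs_s: float = 900.0):
        self.th_abs = th_abs
        self.th_di = th_di
        self.min_qs_s = min_qs_s

    def fit(self, X=None, y=None) -> "SleepStateClassifier":
        if not 0 <= self.th_abs < self.th_di:
            raise InvalidParameterError(
                f"need 0 <= th_abs < th_di, got ({self.th_abs}, {self.th_di})"
            )
        if self.min_qs_s <= 0:
            raise InvalidParameterError(f"min_qs_s must be positive, got {self.min_qs_s}")
        self.is_fitted_ = True
        return self

    def predict(self, X: Union[PowerSeries, np.ndarray]) -> np.ndarray:
        check_is_fitted(self, "is_fitted_")
        power = X if isinstance(X, PowerSeries) else PowerSeries(np.ravel(np.asarray(X, float)))
        return self.predict_labels(power).labels

    def predict_labels(self, power: PowerSeries) -> StateLabels:
        check_is_fitted(self, "is_fitted_")
        coarse = classify_coarse(power, self.th_abs, self.th_di)
        return refine_qs_ds(coarse, self.min_qs_s, th_abs=self.th_abs, th_di=self.th_di)

    @classmethod
    def from_calibration(
        cls,
        power_empty: Union[PowerSeries, np.ndarray],
        power_occupied: Union[PowerSeries, np.ndarray],
        th_di: float = 0.05,
        min_qs_s: float = 900.0,
    ) -> "SleepStateClassifier":
        """Build a classifier whose absence threshold comes from a ROC calibration."""
        return cls(
            th_abs=calibrate_abs_threshold(power_empty, power_occupied),
            th_di=th_di,
            min_qs_s=min_qs_s,
        )
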