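"""Multi-scale fragmentation analysis.

The cumulative histogram of quiet-sleep periods shows, for each duration d on
a 60 -> 1 min grid, the share of the recording spent in QS runs lasting at
least d.  Its maximum-slope point marks the characteristic period fragmenting
sleep; the DI and ABS shares complete the curve past the 1-min point.
"""

from __future__ import annotations

from collections import Counter
from typing import List, Optional, Sequence

import numpy as np

from .containers import ABS, DI, QS, DurationDistribution, PowerSeries, QSCumulativeCurve, StateLabels
from .errors import InvalidInputError
from .states import runs_of

__all__ = [
    "qs_cumulative_curve",
    "max_slope_point",
    "di_duration_pdf",
    "plot_qs_cumulative",
]

#: displacement thresholds examined on the normalized signal
DEFAULT_PDF_THRESHOLDS = (0.01, 0.05, 0.1, 0.2, 0.3, 0.35, 0.5)


def _true_run_lengths(mask: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a boolean mask."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0 or not m.any():
        return np.array([], dtype=int)
    change = np.flatnonzero(m[1:] != m[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [m.size]])
    return np.array([e - s for s, e in zip(starts, ends) if m[s]], dtype=int)


def qs_cumulative_curve(
    labels: StateLabels, grid_min: Optional[Sequence[float]] = None
) -> QSCumulativeCurve:
    """Cumulative share of the recording in QS runs of at least d minutes.

    Runs longer than the left edge of the grid contribute their full length at
    every grid point, so an occasional interruption of a long quiet period
    does not move the curve.  The denominator is the full recording length.
    """
    if len(labels) == 0:
        raise InvalidInputError("empty labels")
    grid = np.arange(60, 0, -1, dtype=float) if grid_min is None else np.asarray(grid_min, float)
    if grid.size < 1 or np.any(np.diff(grid) >= 0):
        raise InvalidInputError("duration grid must be strictly decreasing")
    total = len(labels)
    qs_lengths = np.array(
        [r.duration_s for r in runs_of(labels.labels) if r.state == QS], dtype=float
    )
    cum = np.array(
        [100.0 * qs_lengths[qs_lengths >= d * 60.0].sum() / total for d in grid]
    )
    di_pct = 100.0 * int(np.sum(labels.labels == DI)) / total
    abs_pct = 100.0 * int(np.sum(labels.labels == ABS)) / total
    return QSCumulativeCurve(grid, cum, di_pct=di_pct, abs_pct=abs_pct)


def max_slope_point(curve: QSCumulativeCurve) -> Optional[float]:
    """Grid duration with the largest step toward the next-shorter duration.

    Ties go to the longer duration; a flat curve has no characteristic
    fragmentation period and returns ``None``.
    """
    if curve.duration_grid_min.size < 2:
        raise InvalidInputError("curve needs at least 2 grid points")
    steps = np.diff(curve.cum_pct)  # increment toward shorter durations
    if np.all(steps <= 0):
        return None
    return float(curve.duration_grid_min[int(np.argmax(steps))])


def di_duration_pdf(
    power: PowerSeries, thresholds: Sequence[float] = DEFAULT_PDF_THRESHOLDS
) -> List[DurationDistribution]:
    """Probability mass of displacement-run durations at each power threshold.

    A displacement run is a maximal run of seconds with power strictly above
    the threshold.  An empty event set yields an empty distribution.
    """
    out = []
    for th in thresholds:
        lengths = _true_run_lengths(power.values > th)
        counts = Counter(int(round(l * power.hop_s)) for l in lengths)
        durations = np.array(sorted(counts), dtype=int)
        n = np.array([counts[d] for d in durations], dtype=int)
        pmf = n / n.sum() if n.size else np.array([])
        out.append(DurationDistribution(threshold=float(th), durations_s=durations, pmf=pmf, _counts=n))
    return out


def plot_qs_cumulative(curve: QSCumulativeCurve, ax=None, **plot_kw):
    """Plot the cumulative QS histogram with the DI/ABS completion steps.

    Requires matplotlib; returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.step(curve.duration_grid_min, curve.cum_pct, where="post", **plot_kw)
    right = curve.cum_pct[-1]
    ax.scatter([0.5], [right + curve.di_pct], marker="s", label="+DI")
    if curve.abs_pct > 0:
        ax.scatter([0.25], [right + curve.di_pct + curve.abs_pct], marker="^", label="+ABS")
    ax.set_xlim(curve.duration_grid_min[0] + 1, 0)
    ax.set_xlabel("QS period duration (min)")
    ax.set_ylabel("cumulative share of recording (%)")
    ms = max_slope_point(curve)
    if ms is not None:
        ax.axvline(ms, ls="--", lw=0.8, color="r", label=f"max slope @ {ms:g} min")
    ax.legend()
    return ax
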