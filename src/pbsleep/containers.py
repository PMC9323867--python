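"""Core data containers.

These are light dataclasses around numpy arrays; heavy numerics live in the
estimator classes and module functions that produce/consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError

#: canonical per-second state labels
ABS, QS, DS, DI = "ABS", "QS", "DS", "DI"
#: coarse label for the band between the two thresholds, before the
#: minimum-quiet-sleep refinement splits it into QS and DS
MID = "MID"

STATES = (ABS, QS, DS, DI)


@dataclass
class ChannelMatrix:
    """Raw multichannel pressure recording, ``values`` shaped (channels, samples)."""

    values: np.ndarray
    fs: float
    channel_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise InvalidInputError("channel matrix must be 2-D with >=1 channel and >=1 sample")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i}" for i in range(self.values.shape[0])]
        elif len(self.channel_ids) != self.values.shape[0]:
            raise InvalidInputError("channel_ids length does not match number of channels")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class MotionSignal:
    """Nonnegative motion envelope at sampling rate ``fs``.

    ``norm_max`` keeps the pre-normalization maximum so the absolute scale of a
    normalized recording can be recovered.
    """

    values: np.ndarray
    fs: float
    normalized: bool = False
    norm_max: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise InvalidInputError("motion signal must be a non-empty 1-D array")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        if np.any(self.values < 0):
            raise InvalidInputError("motion envelope must be nonnegative")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs


@dataclass
class PowerSeries:
    """Per-window mean-square power of the (normalized) envelope, one value per ``hop_s``."""

    values: np.ndarray
    hop_s: float = 1.0
    origin: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise InvalidInputError("power series must be a non-empty 1-D array")
        if np.any(self.values < 0):
            raise InvalidInputError("power values must be nonnegative")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class StateLabels:
    """Per-second labels over {ABS, QS, DS, DI} plus the parameters that produced them."""

    labels: np.ndarray
    th_abs: float
    th_di: float
    min_qs_s: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U3")
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise InvalidInputError("labels must be a non-empty 1-D array")
        bad = set(np.unique(self.labels)) - set(STATES)
        if bad:
            raise InvalidInputError(f"unknown state labels: {sorted(bad)}")

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class Run:
    """A maximal run of one state: ``duration_s`` seconds starting at ``start_s``."""

    state: str
    start_s: int
    duration_s: int


@dataclass
class SleepIndexes:
    """Percent of recording per state, plus displacement-event bookkeeping."""

    qs_pct: float
    ds_pct: float
    di_pct: float
    abs_pct: float
    n_di_events: int = 0
    di_durations_s: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def dsdi_pct(self) -> float:
        """Combined non-quiet share DS% + DI% (the index correlated with AHI)."""
        return self.ds_pct + self.di_pct


@dataclass
class QSCumulativeCurve:
    """Cumulative share of the recording in quiet-sleep runs of at least d minutes.

    The grid runs from long to short durations (default 60 -> 1 min); the DI and
    ABS shares complete the curve beyond its 1-min point.
    """

    duration_grid_min: np.ndarray
    cum_pct: np.ndarray
    di_pct: float
    abs_pct: float

    def __post_init__(self) -> None:
        self.duration_grid_min = np.asarray(self.duration_grid_min, dtype=float)
        self.cum_pct = np.asarray(self.cum_pct, dtype=float)
        if self.duration_grid_min.shape != self.cum_pct.shape:
            raise InvalidInputError("grid and cum_pct must have the same shape")


@dataclass
class DurationDistribution:
    """Probability mass over displacement-run durations at one power threshold."""

    threshold: float
    durations_s: np.ndarray
    pmf: np.ndarray

    @property
    def total_event_seconds(self) -> int:
        return int(np.sum(self.durations_s * self._counts)) if self.durations_s.size else 0

    # counts kept alongside the pmf so event-second totals stay exact
    _counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class DFAResult:
    """Detrended-fluctuation output: RMS fluctuation per scale and the Hurst slope."""

    scales_samples: np.ndarray
    rms: np.ndarray
    hurst: float
    fit_r2: float


@dataclass
class BlandAltmanStats:
    """Mean/SD of pairwise differences and the 1.96-SD limits of agreement."""

    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    outside_count: int
    n: int


@dataclass
class RecordingRecord:
    """One cohort row: clinical metrics and (optionally) the detected state shares."""

    rec_id: int
    subject_id: str
    dataset: str  # "apnea" | "shift_work"
    st_h: float
    se: float
    tib_h: Optional[float] = None
    tne: Optional[int] = None
    tr_h: Optional[float] = None
    ahi: Optional[float] = None
    timetable: Optional[str] = None  # "D" | "N"
    uncertain: bool = False
    indexes: Optional[SleepIndexes] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.se <= 1.0:
            raise InvalidInputError(f"SE must lie in [0, 1], got {self.se} (rec {self.rec_id})")
        if self.ahi is not None and self.ahi < 0:
            raise InvalidInputError(f"AHI must be nonnegative, got {self.ahi} (rec {self.rec_id})")
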