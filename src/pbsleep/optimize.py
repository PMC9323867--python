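"""Grid-search tuning of the displacement threshold and the minimum QS period.

Candidates are scored on a cohort of recordings: the detected QS% must
correlate with sleep efficiency and the detected DS%+DI% with the AHI (where
available), both at r >= 0.5; among feasible candidates the sum of the two
correlations is maximized.  Uncertain recordings are excluded throughout, as
in the evaluation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import pearson
from .containers import PowerSeries
from .errors import InvalidInputError
from .states import SleepStateClassifier, summarize_states

__all__ = [
    "CohortRecording",
    "GridSearchResult",
    "ThresholdGridSearch",
    "grid_search",
    "loocv_parameter_stability",
]

#: displacement-threshold candidates examined on the normalized signal
DEFAULT_TH_GRID = (0.01, 0.05, 0.1, 0.2, 0.3, 0.35, 0.5)
#: minimum-QS candidates in minutes
DEFAULT_MINQS_GRID_MIN = (5.0, 10.0, 15.0, 20.0, 30.0)


@dataclass
class CohortRecording:
    """One recording entering the grid search: its power series plus clinical metrics."""

    rec_id: str
    power: PowerSeries
    se: float
    ahi: Optional[float] = None
    uncertain: bool = False


@dataclass
class GridSearchResult:
    """Scores for every (th_di, min_qs_min) candidate and the feasible optimum."""

    candidates: List[Tuple[float, float]]
    corr_qs_se: np.ndarray
    corr_dsdi_ahi: np.ndarray
    feasible: np.ndarray
    best: Optional[Tuple[float, float]]

    @property
    def objective(self) -> np.ndarray:
        return self.corr_qs_se + self.corr_dsdi_ahi

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "th_di": [c[0] for c in self.candidates],
                "min_qs_min": [c[1] for c in self.candidates],
                "corr_qs_se": self.corr_qs_se,
                "corr_dsdi_ahi": self.corr_dsdi_ahi,
                "feasible": self.feasible,
                "objective": self.objective,
            }
        )


def _candidate_scores(
    cohort: Sequence[CohortRecording],
    th_di: float,
    min_qs_min: float,
    th_abs: float,
    min_corr: float,
) -> Tuple[float, float, bool]:
    clf = SleepStateClassifier(th_abs=th_abs, th_di=th_di, min_qs_s=min_qs_min * 60.0).fit()
    qs, se, dsdi, ahi = [], [], [], []
    for rec in cohort:
        if rec.uncertain:
            continue
        idx = summarize_states(clf.predict_labels(rec.power))
        qs.append(idx.qs_pct)
        se.append(rec.se)
        if rec.ahi is not None:
            dsdi.append(idx.dsdi_pct)
            ahi.append(rec.ahi)
    r_qs = pearson(qs, se)
    r_dsdi = pearson(dsdi, ahi)
    feasible = (
        np.isfinite(r_qs) and np.isfinite(r_dsdi) and r_qs >= min_corr and r_dsdi >= min_corr
    )
    return r_qs, r_dsdi, feasible


class ThresholdGridSearch(BaseEstimator):
    """Exhaustive search over (th_di, min_qs_min) candidates on a cohort.

    Parameters
    ----------
    th_grid, minqs_grid_min : sequences
        Candidate displacement thresholds (normalized power) and minimum quiet
        periods (minutes).  Defaults are the examined threshold list and a
        5-30 min sweep around the published optimum.
    th_abs : float
        Absence threshold held fixed during the search.
    min_corr : float
        Feasibility floor applied to both correlations (default 0.5).

    After ``fit(cohort)``: ``result_`` (full table), ``best_params_``
    (``(th_di, min_qs_min)`` or None when nothing is feasible).
    Ties are broken toward the smaller threshold, then the smaller minimum
    QS period.
    """

    def __init__(
        self,
        th_grid: Sequence[float] = DEFAULT_TH_GRID,
        minqs_grid_min: Sequence[float] = DEFAULT_MINQS_GRID_MIN,
        th_abs: float = 1e-3,
        min_corr: float = 0.5,
    ):
        self.th_grid = th_grid
        self.minqs_grid_min = minqs_grid_min
        self.th_abs = th_abs
        self.min_corr = min_corr

    def fit(self, X: Sequence[CohortRecording], y=None) -> "ThresholdGridSearch":
        cohort = list(X)
        usable = [r for r in cohort if not r.uncertain]
        if sum(1 for r in usable if r.se is not None) < 4:
            raise InvalidInputError("grid search needs >=4 non-uncertain recordings with SE")
        if sum(1 for r in usable if r.ahi is not None) < 4:
            raise InvalidInputError("grid search needs >=4 non-uncertain recordings with AHI")
        candidates = [
            (float(th), float(mq))
            for th in sorted(self.th_grid)
            for mq in sorted(self.minqs_grid_min)
        ]
        r_qs, r_dsdi, feas = [], [], []
        for th, mq in candidates:
            a, b, f = _candidate_scores(cohort, th, mq, self.th_abs, self.min_corr)
            r_qs.append(a)
            r_dsdi.append(b)
            feas.append(f)
        result = GridSearchResult(
            candidates=candidates,
            corr_qs_se=np.array(r_qs),
            corr_dsdi_ahi=np.array(r_dsdi),
            feasible=np.array(feas, dtype=bool),
            best=None,
        )
        if result.feasible.any():
            obj = np.where(result.feasible, result.objective, -np.inf)
            # candidates are sorted by (th, minqs); argmax returns the first
            # maximizer, which is the tie-break order we want
            result.best = candidates[int(np.argmax(obj))]
        self.result_ = result
        self.best_params_ = result.best
        return self


def grid_search(
    cohort: Sequence[CohortRecording],
    th_grid: Sequence[float] = DEFAULT_TH_GRID,
    minqs_grid_min: Sequence[float] = DEFAULT_MINQS_GRID_MIN,
    th_abs: float = 1e-3,
    min_corr: float = 0.5,
) -> GridSearchResult:
    """Score every candidate pair on the cohort; see :class:`ThresholdGridSearch`."""
    est = ThresholdGridSearch(th_grid, minqs_grid_min, th_abs, min_corr).fit(cohort)
    return est.result_


@dataclass
class FoldResult:
    left_out: str
    best: Optional[Tuple[float, float]]
    corr_qs_se: float
    corr_dsdi_ahi: float


def loocv_parameter_stability(
    cohort: Sequence[CohortRecording],
    th_grid: Sequence[float] = DEFAULT_TH_GRID,
    minqs_grid_min: Sequence[float] = DEFAULT_MINQS_GRID_MIN,
    th_abs: float = 1e-3,
    min_corr: float = 0.5,
) -> List[FoldResult]:
    """Repeat the grid search leaving one recording out per fold.

    Each fold reports the in-fold optimum and its two correlations; stable
    parameters across folds indicate the optimum is not driven by any single
    recording.
    """
    cohort = list(cohort)
    folds = []
    for i, rec in enumerate(cohort):
        sub = cohort[:i] + cohort[i + 1 :]
        res = grid_search(sub, th_grid, minqs_grid_min, th_abs, min_corr)
        if res.best is None:
            folds.append(FoldResult(rec.rec_id, None, float("nan"), float("nan")))
            continue
        k = res.candidates.index(res.best)
        folds.append(
            FoldResult(rec.rec_id, res.best, float(res.corr_qs_se[k]), float(res.corr_dsdi_ahi[k]))
        )
    return folds
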