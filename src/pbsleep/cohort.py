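"""Clinical metrics and the statistics used to evaluate the motion indexes.

Sleep efficiency SE = ST/TIB and the apnea-hypopnea index AHI = TNE/TR are the
clinical references; the detected QS% is evaluated against SE and the combined
DS%+DI% against AHI via Pearson correlation, leave-one-out cross-validation,
Bland-Altman agreement and Mann-Whitney group tests.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .containers import BlandAltmanStats, RecordingRecord
from .errors import InvalidInputError

__all__ = [
    "sleep_efficiency",
    "apnea_hypopnea_index",
    "ahi_category",
    "efficiency_group",
    "pearson",
    "loocv_correlation",
    "bland_altman",
    "mann_whitney",
    "uncertain_flags",
]

#: AHI severity cutpoints (events/hour), half-open on the left as printed
AHI_CATEGORIES = (("N", 5.0), ("Mi", 15.0), ("Mo", 30.0), ("S", math.inf))

#: sleep-efficiency threshold separating good (strictly above) from bad
SE_GOOD_THRESHOLD = 0.80


def sleep_efficiency(st_h: float, tib_h: float) -> float:
    """SE = sleep time / time in bed, a fraction in [0, 1]."""
    if tib_h <= 0:
        raise InvalidInputError(f"time in bed must be positive, got {tib_h}")
    if not 0 <= st_h <= tib_h:
        raise InvalidInputError(f"sleep time {st_h} h must lie in [0, TIB={tib_h} h]")
    return st_h / tib_h


def apnea_hypopnea_index(tne: float, tr_h: float) -> float:
    """AHI = total number of respiratory events / recording duration in hours."""
    if tr_h <= 0:
        raise InvalidInputError(f"recording duration must be positive, got {tr_h}")
    if tne < 0:
        raise InvalidInputError(f"event count must be nonnegative, got {tne}")
    return tne / tr_h


def ahi_category(ahi: float) -> str:
    """Severity band: N (<5), Mi (5-15), Mo (15-30), S (>=30 events/hour)."""
    if ahi < 0:
        raise InvalidInputError(f"AHI must be nonnegative, got {ahi}")
    for name, upper in AHI_CATEGORIES:
        if ahi < upper:
            return name
    raise AssertionError("unreachable")


def efficiency_group(se: float) -> str:
    """GSE for SE strictly above 0.80, BSE otherwise."""
    if not 0 <= se <= 1:
        raise InvalidInputError(f"SE must lie in [0, 1], got {se}")
    return "GSE" if se > SE_GOOD_THRESHOLD else "BSE"


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN when either argument has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InvalidInputError("pearson needs two equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def loocv_correlation(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Mean and population SD of the n leave-one-out Pearson correlations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise InvalidInputError("LOOCV needs two equal-length samples with n >= 4")
    folds = np.array(
        [pearson(np.delete(x, i), np.delete(y, i)) for i in range(x.size)]
    )
    return float(np.mean(folds)), float(np.std(folds))


def bland_altman(a: Sequence[float], b: Sequence[float]) -> BlandAltmanStats:
    """Mean difference, SD and 1.96-SD limits of agreement for paired values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise InvalidInputError("bland_altman needs two equal-length samples with n >= 3")
    diff = a - b
    mean = float(diff.mean())
    sd = float(diff.std())  # population SD, consistent with the LOOCV convention
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    outside = int(np.sum((diff < lo) | (diff > hi)))
    return BlandAltmanStats(mean, sd, lo, hi, outside, int(a.size))


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 12
) -> Tuple[float, float]:
    """Mann-Whitney U of sample ``a`` with a two-sided p-value.

    For pooled sizes up to ``exact_max_n`` the p-value is exact: every
    assignment of the pooled midranks to group ``a`` is enumerated and the
    probability of a U at least as far from its null mean is accumulated
    (correct under ties, which midranks handle).  Larger samples use the
    tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a)
    mu = n_a * n_b / 2.0

    if n_a + n_b <= exact_max_n:
        dev = abs(u_obs - mu) - 1e-12
        hits = total = 0
        for idx in combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks[list(idx)], n_a)
            hits += abs(u - mu) >= dev
            total += 1
        return u_obs, hits / total

    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def uncertain_flags(
    records: Iterable[RecordingRecord],
    hypopnea_fraction: Optional[Dict[int, float]] = None,
    se_high: float = 0.90,
    ahi_high: float = 30.0,
    hypopnea_max: float = 0.80,
) -> List[bool]:
    """Flag recordings whose clinical metrics the motion signal cannot reflect.

    Two rules: (i) an anomalous combination of high SE (>= ``se_high``) with
    severe AHI (>= ``ahi_high``) - quiet sleep and heavy event load should not
    coexist; (ii) hypopneas making up at least ``hypopnea_max`` of the events
    (hypopneas produce no motion, so fractions must be supplied externally).
    Records without AHI are never flagged by the SE/AHI rule.
    """
    hypopnea_fraction = hypopnea_fraction or {}
    flags = []
    for rec in records:
        rule_se_ahi = rec.ahi is not None and rec.se >= se_high and rec.ahi >= ahi_high
        rule_hyp = hypopnea_fraction.get(rec.rec_id, 0.0) >= hypopnea_max
        flags.append(bool(rule_se_ahi or rule_hyp))
    return flags
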