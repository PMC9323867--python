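"""End-to-end analysis: conditioning -> power -> states -> fragmentation -> DFA."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Any, Dict, Optional, Union

import numpy as np

from .containers import ChannelMatrix, MotionSignal, QSCumulativeCurve, SleepIndexes
from .dfa import DetrendedFluctuation, default_scales
from .envelope import normalize_max, pca_motion, sliding_std_envelope
from .errors import ComputationError, PbsleepError
from .multiscale import max_slope_point, qs_cumulative_curve
from .states import SleepStateClassifier, summarize_states, window_power

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analyze"]


@dataclass
class AnalysisConfig:
    """Parameters of the full pipeline; YAML config keys map 1:1 onto fields."""

    fs_hz: float = 50.0
    method: str = "channel_std"  # or "pca"
    window_s: float = 4.0
    th_abs: float = 1e-3
    th_di: float = 0.05
    min_qs_min: float = 15.0
    dfa_n_scales: int = 15
    dfa_min_scale_min: float = 1.0
    dfa_max_scale_min: float = 60.0
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: Dict[str, Any]) -> "AnalysisConfig":
        scales = mapping.pop("scales", None) or {}
        cfg = cls(**{k: v for k, v in mapping.items() if k in cls.__dataclass_fields__})
        if "n" in scales:
            cfg.dfa_n_scales = int(scales["n"])
        if "min_min" in scales:
            cfg.dfa_min_scale_min = float(scales["min_min"])
        if "max_min" in scales:
            cfg.dfa_max_scale_min = float(scales["max_min"])
        return cfg


@dataclass
class AnalysisReport:
    """One recording's full analysis output; parameters echo the config verbatim."""

    recording_id: str
    indexes: SleepIndexes
    curve: QSCumulativeCurve
    max_slope_min: Optional[float]
    hurst: float
    dfa_fit_r2: float
    parameters: Dict[str, Any]

    def summary(self) -> Dict[str, Any]:
        return {
            "recording_id": self.recording_id,
            "qs_pct": self.indexes.qs_pct,
            "ds_pct": self.indexes.ds_pct,
            "di_pct": self.indexes.di_pct,
            "abs_pct": self.indexes.abs_pct,
            "dsdi_pct": self.indexes.dsdi_pct,
            "n_di_events": self.indexes.n_di_events,
            "max_slope_min": self.max_slope_min,
            "hurst": self.hurst,
            "dfa_fit_r2": self.dfa_fit_r2,
            "parameters": self.parameters,
        }


def _stage(name: str):
    """Re-raise pipeline failures with the stage that produced them."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, PbsleepError):
                raise type(exc)(f"[{name}] {exc}") from exc
            if exc is not None and isinstance(exc, Exception):
                raise ComputationError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_analyze(
    source: Union[ChannelMatrix, MotionSignal],
    config: Optional[AnalysisConfig] = None,
    recording_id: str = "recording",
) -> AnalysisReport:
    """Run the full pipeline on a raw channel matrix (or a precomputed envelope).

    Deterministic given its inputs; every stage failure is tagged with the
    stage name.
    """
    cfg = config or AnalysisConfig()

    if isinstance(source, ChannelMatrix):
        with _stage("conditioning"):
            extract = pca_motion if cfg.method == "pca" else sliding_std_envelope
            signal = normalize_max(extract(source, window_s=cfg.window_s))
    else:
        signal = source if source.normalized else normalize_max(source)

    with _stage("power"):
        power = window_power(signal, hop_s=1.0)
    with _stage("classification"):
        clf = SleepStateClassifier(
            th_abs=cfg.th_abs, th_di=cfg.th_di, min_qs_s=cfg.min_qs_min * 60.0
        ).fit()
        labels = clf.predict_labels(power)
    with _stage("summary"):
        indexes = summarize_states(labels)
        curve = qs_cumulative_curve(labels)
        slope = max_slope_point(curve)
    with _stage("dfa"):
        scales = default_scales(
            fs=1.0,
            n_samples=len(power),
            n_scales=cfg.dfa_n_scales,
            min_s=cfg.dfa_min_scale_min * 60.0,
            max_s=cfg.dfa_max_scale_min * 60.0,
        )
        if scales.size >= 3 and np.ptp(power.values) > 0:
            est = DetrendedFluctuation(scales=scales).fit(power.values)
            hurst, r2 = est.hurst_, est.fit_r2_
        else:  # recording too short (or flat) for a meaningful log-log fit
            hurst, r2 = float("nan"), float("nan")

    return AnalysisReport(
        recording_id=recording_id,
        indexes=indexes,
        curve=curve,
        max_slope_min=slope,
        hurst=hurst,
        dfa_fit_r2=r2,
        parameters=asdict(cfg),
    )
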