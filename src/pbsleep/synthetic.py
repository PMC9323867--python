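"""Synthetic multichannel bed-sensor recordings with second-level ground truth.

The generator emulates the signal taxonomy the state thresholds rely on:

* an external noise floor present everywhere (traffic, electronics);
* a breathing oscillation (~0.25 Hz) while the subject occupies the bed, with
  per-channel coupling gains and occasional deeper-breathing (sigh) episodes;
* movement bursts - high-amplitude band noise, hard-clipped at a saturation
  level as real pressure sensors are - with log-normal durations (mode ~5 s);
  most movements are large, a fraction are low-amplitude twitches;
* optional apnea-like event trains at a configurable events/hour rate;
* absence intervals during which only the external noise remains;
* bed-entry and bed-exit movements that bracket the night, guaranteeing at
  least one saturating burst so per-recording max-normalization is anchored.

Amplitudes are expressed relative to a unit pressure scale.  With the default
saturation at 15 units, the max-normalized envelope power of quiet breathing
lands near 3e-3 (between the absence threshold 1e-3 and the smallest
displacement threshold 0.01), deep-breathing sighs inside (0.01, 0.05),
minor twitches inside (0.05, 0.1) and large movements above 0.35 - so every
candidate displacement threshold separates a physically different event
class, as the threshold sweep on the real recordings presumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .containers import ABS, DI, MID, ChannelMatrix, SleepIndexes
from .errors import InvalidParameterError
from .states import refine_qs_ds, summarize_states

__all__ = [
    "BreathingModel",
    "MovementModel",
    "ApneaModel",
    "SyntheticProtocol",
    "GroundTruth",
    "simulate_recording",
    "preset_healthy",
    "preset_apnea",
    "preset_insomnia",
    "preset_fragmented",
    "ground_truth_indexes",
]


@dataclass
class BreathingModel:
    """Respiratory oscillation while the bed is occupied."""

    amplitude: float = 1.2
    freq_hz: float = 0.25
    sigh_rate_per_hour: float = 4.0
    sigh_gain_range: Tuple[float, float] = (2.0, 2.6)
    sigh_duration_s: float = 15.0


@dataclass
class MovementModel:
    """Spontaneous body movements: bursts of clipped high-amplitude noise."""

    burst_amplitude_range: Tuple[float, float] = (10.0, 50.0)
    minor_amplitude_range: Tuple[float, float] = (3.7, 4.0)
    minor_fraction: float = 0.3
    duration_mode_s: float = 5.0
    duration_sigma: float = 0.5
    mean_interval_s: float = 5400.0  # one spontaneous movement per ~1.5 h


@dataclass
class ApneaModel:
    """Apnea-like event train: extra movement bursts at a clinical rate."""

    enabled: bool = False
    events_per_hour: float = 0.0
    duration_mode_s: float = 5.0
    duration_sigma: float = 0.35


@dataclass
class SyntheticProtocol:
    """Full description of one synthetic recording."""

    duration_s: float = 8 * 3600.0
    fs: float = 50.0
    n_channels: int = 8
    breathing: BreathingModel = field(default_factory=BreathingModel)
    external_noise_sd: float = 0.15
    movement: MovementModel = field(default_factory=MovementModel)
    apnea: ApneaModel = field(default_factory=ApneaModel)
    absence: List[Tuple[float, float]] = field(default_factory=list)  # (start_s, duration_s)
    saturation: float = 15.0
    channel_gain_range: Tuple[float, float] = (0.9, 1.1)
    entry_exit_movements: bool = True
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.duration_s <= 0:
            problems.append(f"duration_s must be positive, got {self.duration_s}")
        if self.fs < 2 * self.breathing.freq_hz:
            problems.append(
                f"fs={self.fs} Hz undersamples breathing at {self.breathing.freq_hz} Hz"
            )
        if self.n_channels < 1:
            problems.append(f"need >=1 channel, got {self.n_channels}")
        for start, dur in self.absence:
            if dur <= 0:
                problems.append(f"absence duration must be positive, got {dur}")
            if start < 0 or start + dur > self.duration_s:
                problems.append(f"absence ({start}, {dur}) falls outside the recording")
        if self.movement.mean_interval_s <= 0:
            problems.append("movement mean_interval_s must be positive")
        if self.apnea.enabled and self.apnea.events_per_hour <= 0:
            problems.append("apnea enabled but events_per_hour is not positive")
        if problems:
            raise InvalidParameterError("invalid protocol: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """Intended per-second coarse state {ABS, MID, DI} and the event log."""

    coarse: np.ndarray  # per-second labels
    events: List[Tuple[str, float, float]]  # (type, start_s, duration_s)


def _draw_events(
    rng: np.random.Generator,
    duration_s: float,
    mean_interval_s: float,
    dur_mode_s: float,
    dur_sigma: float,
) -> List[Tuple[float, float]]:
    """Poisson event train: exponential gaps, log-normal durations (given mode)."""
    mu = np.log(dur_mode_s) + dur_sigma**2
    events = []
    t = rng.exponential(mean_interval_s)
    while t < duration_s:
        d = float(rng.lognormal(mu, dur_sigma))
        d = min(max(d, 1.0), duration_s - t)
        events.append((float(t), d))
        t += d + rng.exponential(mean_interval_s)
    return events


def simulate_recording(
    protocol: SyntheticProtocol, seed: Optional[int] = None
) -> Tuple[ChannelMatrix, GroundTruth]:
    """Generate the multichannel pressure matrix and its aligned ground truth.

    A second is intended DI when movement bursts cover at least half of it,
    ABS when absence covers at least half of it, MID otherwise.  Output is
    bit-reproducible for a given (protocol, seed).
    """
    protocol.validate()
    rng = np.random.default_rng(protocol.seed if seed is None else seed)
    p = protocol
    n = int(round(p.duration_s * p.fs))
    n_sec = int(p.duration_s)
    t = np.arange(n) / p.fs

    occupied = np.ones(n, dtype=bool)
    events: List[Tuple[str, float, float]] = []
    for start, dur in p.absence:
        occupied[int(start * p.fs) : int((start + dur) * p.fs)] = False
        events.append(("absence", float(start), float(dur)))

    # breathing with slowly varying sigh gain
    gain = np.ones(n)
    occ_frac = occupied.mean()
    for start, dur in _draw_events(
        rng,
        p.duration_s,
        3600.0 / max(p.breathing.sigh_rate_per_hour * max(occ_frac, 1e-9), 1e-9),
        p.breathing.sigh_duration_s,
        0.2,
    ):
        gain[int(start * p.fs) : int((start + dur) * p.fs)] = rng.uniform(
            *p.breathing.sigh_gain_range
        )
        events.append(("sigh", start, dur))
    phase = rng.uniform(0, 2 * np.pi)
    breathing = p.breathing.amplitude * gain * np.sin(2 * np.pi * p.breathing.freq_hz * t + phase)
    breathing[~occupied] = 0.0

    # movement bursts: spontaneous train plus the optional apnea train
    bursts: List[Tuple[float, float, float]] = []  # (start, dur, amplitude)

    def _amplitude() -> float:
        if rng.uniform() < p.movement.minor_fraction:
            return float(rng.uniform(*p.movement.minor_amplitude_range))
        return float(rng.uniform(*p.movement.burst_amplitude_range))

    for start, dur in _draw_events(
        rng, p.duration_s, p.movement.mean_interval_s,
        p.movement.duration_mode_s, p.movement.duration_sigma,
    ):
        bursts.append((start, dur, _amplitude()))
        events.append(("movement", start, dur))
    if p.apnea.enabled:
        for start, dur in _draw_events(
            rng, p.duration_s, 3600.0 / p.apnea.events_per_hour,
            p.apnea.duration_mode_s, p.apnea.duration_sigma,
        ):
            bursts.append((start, dur, _amplitude()))
            events.append(("apnea_movement", start, dur))
    if p.entry_exit_movements:
        amp_hi = p.movement.burst_amplitude_range[1]
        for s0, tag in ((1.0, "bed_entry"), (p.duration_s - 9.0, "bed_exit")):
            if 0.0 <= s0 < p.duration_s - 1.0:
                bursts.append((s0, 8.0, amp_hi))
                events.append((tag, s0, 8.0))
    # drop bursts while the bed is empty
    bursts = [
        (s, d, a)
        for s, d, a in bursts
        if occupied[int(s * p.fs) : int((s + d) * p.fs)].mean() > 0.5
    ]

    burst_mask = np.zeros(n, dtype=bool)
    burst_amp = np.zeros(n)
    for s, d, a in bursts:
        i0, i1 = int(s * p.fs), int((s + d) * p.fs)
        burst_mask[i0:i1] = True
        burst_amp[i0:i1] = np.maximum(burst_amp[i0:i1], a)

    channels = np.empty((p.n_channels, n))
    ch_gain = rng.uniform(*p.channel_gain_range, size=p.n_channels)
    for c in range(p.n_channels):
        sig = ch_gain[c] * breathing.copy()
        if burst_mask.any():
            sig[burst_mask] += ch_gain[c] * burst_amp[burst_mask] * rng.standard_normal(
                int(burst_mask.sum())
            )
        if p.external_noise_sd > 0:
            sig += rng.normal(0.0, p.external_noise_sd, n)
        np.clip(sig, -p.saturation, p.saturation, out=sig)
        channels[c] = sig

    # ground truth on the 1-s grid: majority coverage decides the state
    sec_edges = (np.arange(n_sec + 1) * p.fs).astype(int)
    cover_burst = np.add.reduceat(burst_mask.astype(float), sec_edges[:-1]) / p.fs
    cover_absent = np.add.reduceat((~occupied).astype(float), sec_edges[:-1]) / p.fs
    coarse = np.full(n_sec, MID, dtype="U3")
    coarse[cover_absent >= 0.5] = ABS
    coarse[cover_burst >= 0.5] = DI
    truth = GroundTruth(coarse=coarse, events=sorted(events, key=lambda e: e[1]))
    matrix = ChannelMatrix(channels, fs=p.fs)
    return matrix, truth


def ground_truth_indexes(gt: GroundTruth, min_qs_s: float = 900.0) -> SleepIndexes:
    """Noise-free oracle: the QS/DS refinement applied to the intended states."""
    return summarize_states(refine_qs_ds(gt.coarse, min_qs_s))


# -- presets -----------------------------------------------------------------

#: apnea-like event rates (events/hour) placing each preset inside its
#: clinical severity band: Mild 5-15, Moderate 15-30, Severe >=30
APNEA_PRESET_RATES = {"Mi": 10.0, "Mo": 22.0, "S": 35.0}


def preset_healthy(duration_s: float = 8 * 3600.0, fs: float = 50.0, seed: int = 0,
                   n_channels: int = 8) -> SyntheticProtocol:
    """Consolidated sleep: one spontaneous movement per ~1.5 h, no apnea train."""
    return SyntheticProtocol(duration_s=duration_s, fs=fs, n_channels=n_channels, seed=seed)


def preset_apnea(severity: str, duration_s: float = 8 * 3600.0, fs: float = 50.0,
                 seed: int = 0, n_channels: int = 8) -> SyntheticProtocol:
    """Sleep fragmented by an apnea-like event train at the given severity."""
    if severity not in APNEA_PRESET_RATES:
        raise InvalidParameterError(
            f"severity must be one of {sorted(APNEA_PRESET_RATES)}, got {severity!r}"
        )
    return SyntheticProtocol(
        duration_s=duration_s,
        fs=fs,
        n_channels=n_channels,
        apnea=ApneaModel(enabled=True, events_per_hour=APNEA_PRESET_RATES[severity]),
        seed=seed,
    )


def preset_insomnia(duration_s: float = 8 * 3600.0, fs: float = 50.0, seed: int = 0,
                    n_channels: int = 8) -> SyntheticProtocol:
    """Restless sleep: frequent movements plus out-of-bed intervals."""
    absence = [(0.25 * duration_s, 600.0), (0.625 * duration_s, 900.0)]
    return SyntheticProtocol(
        duration_s=duration_s,
        fs=fs,
        n_channels=n_channels,
        movement=MovementModel(mean_interval_s=480.0),
        absence=absence,
        seed=seed,
    )


def preset_fragmented(mean_interval_min: float, duration_s: float = 8 * 3600.0,
                      fs: float = 50.0, seed: int = 0, n_channels: int = 8) -> SyntheticProtocol:
    """Movement-fragmented sleep with a configurable inter-movement interval."""
    return SyntheticProtocol(
        duration_s=duration_s,
        fs=fs,
        n_channels=n_channels,
        movement=MovementModel(mean_interval_s=mean_interval_min * 60.0),
        seed=seed,
    )
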