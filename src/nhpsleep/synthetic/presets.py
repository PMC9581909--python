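"""Condition presets for the synthetic polysomnography generator.

Three named disease states ship with the package (healthy, presymptomatic,
symptomatic).  Architecture presets parameterize a semi-Markov stage
process (mean bout durations, a between-stage transition propensity
matrix, time-of-night modulation that front-loads N3 and back-loads REM,
and a fragmentation scalar that inflates wake-intrusion hazard).  Signal
presets give per-stage EEG band powers, EMG tone and EOG behaviour; RR
presets give the REM-sleep heartbeat interval process.

The numeric values were tuned once (scripts/tune_presets.py) so that
cohorts of simulated nights reproduce the published group-level summary
statistics of the macaque study this toolkit models: e.g. healthy sleep
efficiency ~74%, ~11 sleep cycles per 12-h night, symptomatic nights
heavily fragmented with little N3/REM, and a 13-Hz low-beta EEG peak in
symptomatic active wake.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

from ..stages import Condition, StageLabel

A, W, N1, N2, N3, R = (
    StageLabel.A,
    StageLabel.W,
    StageLabel.N1,
    StageLabel.N2,
    StageLabel.N3,
    StageLabel.R,
)


@dataclasses.dataclass(frozen=True)
class ArchitecturePreset:
    """Semi-Markov sleep-architecture parameters for one condition."""

    condition: Condition
    #: Mean bout duration per stage, seconds.
    mean_bout_s: Mapping[StageLabel, float]
    #: Between-stage transition propensities; each row sums to 1, no self-loops.
    transition: Mapping[StageLabel, Mapping[StageLabel, float]]
    #: N3 weight = max(floor, a + b*frac) with frac = elapsed night fraction.
    n3_modulation: tuple[float, float] = (1.0, 0.0)
    #: REM weight = max(floor, a + b*frac).
    rem_modulation: tuple[float, float] = (1.0, 0.0)
    #: Multiplies propensity of sleep->wake transitions (wake-intrusion hazard).
    fragmentation: float = 0.0
    #: Mean latency from window start (lights off) to first sleep, minutes.
    target_sleep_latency_min: float = 13.4
    #: SD of the drawn latency, minutes (truncated at 0).
    sleep_latency_sd_min: float = 4.0
    modulation_floor: float = 0.15

    def __post_init__(self) -> None:
        for stage, dur in self.mean_bout_s.items():
            if dur <= 0:
                raise ValueError(f"mean bout for {stage} must be > 0")
        for stage, row in self.transition.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"transition row for {stage} sums to {total}, not 1")
            if row.get(stage, 0.0) != 0.0:
                raise ValueError(f"transition row for {stage} must not self-loop")
        if self.fragmentation < 0:
            raise ValueError("fragmentation must be non-negative")

    def n3_weight(self, frac: float) -> float:
        a, b = self.n3_modulation
        return max(self.modulation_floor, a + b * frac)

    def rem_weight(self, frac: float) -> float:
        a, b = self.rem_modulation
        return max(self.modulation_floor, a + b * frac)


@dataclasses.dataclass(frozen=True)
class StageSignal:
    """Per-stage signal content for the PSG synthesizer."""

    #: EEG band powers in uV^2: delta 0.3-4, theta 4-8, alpha 8-12, beta 13-35 Hz.
    band_powers: tuple[float, float, float, float]
    #: Optional narrowband EEG component (frequency Hz, amplitude uV).
    narrowband: tuple[float, float] | None = None
    #: EMG tone RMS, uV.
    emg_rms: float = 10.0
    #: Cardiac R-peak template amplitude embedded in the EMG channel, uV.
    r_peak_amp: float = 60.0
    #: EOG burst rate, events/min (rapid eye movements; high in R and A).
    eog_burst_rate: float = 0.0

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.band_powers):
            raise ValueError("band powers must be non-negative")
        if self.narrowband is not None and not (0.3 <= self.narrowband[0] <= 35.0):
            raise ValueError("narrowband frequency must lie in 0.3-35 Hz")


#: EEG analysis bands, Hz (half-open).
EEG_BANDS = {"delta": (0.3, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (13.0, 35.0)}

SignalPreset = Mapping[StageLabel, StageSignal]


@dataclasses.dataclass(frozen=True)
class RrPreset:
    """REM-sleep RR-interval process: lag-1 autoregressive Gaussian."""

    mean_nn: float       # seconds
    sd_nn: float         # seconds
    autocorr: float = 0.3  # lag-1 coefficient, in [0, 1)
    duration_s: float = 120.0

    def __post_init__(self) -> None:
        if self.mean_nn <= 0:
            raise ValueError("mean_nn must be positive")
        if self.sd_nn < 0:
            raise ValueError("sd_nn must be non-negative")
        if not (0.0 <= self.autocorr < 1.0):
            raise ValueError("autocorr must lie in [0, 1)")
        if self.mean_nn <= 0.2:
            raise ValueError("mean_nn must exceed the 0.2 s physiological floor")

    @property
    def cv_percent(self) -> float:
        return 100.0 * self.sd_nn / self.mean_nn


@dataclasses.dataclass(frozen=True)
class MsltPreset:
    """Latency process for one condition's lights-OFF sessions."""

    latency_mean_min: float
    latency_sd_min: float = 3.0
    sleep_run_min: float = 5.5
    #: Fractions of the post-onset sleep run spent in (N1, N2, N3, R).
    stage_mix: tuple[float, float, float, float] = (0.5, 0.5, 0.0, 0.0)


# ----------------------------------------------------------------------
# Shipped architecture presets (night).  Tuned against the published
# 12-h night summary table: healthy efficiency ~74%, ~11.4 cycles;
# presymptomatic N3-heavy; symptomatic fragmented, efficiency ~33%.

ARCHITECTURE_NIGHT: dict[Condition, ArchitecturePreset] = {
    Condition.HEALTHY: ArchitecturePreset(
        condition=Condition.HEALTHY,
        mean_bout_s={A: 150, W: 75, N1: 90, N2: 150, N3: 300, R: 210},
        transition={
            A: {W: 0.55, N1: 0.45},
            W: {A: 0.30, N1: 0.70},
            N1: {N2: 0.56, W: 0.17, A: 0.17, R: 0.10},
            N2: {N3: 0.55, N1: 0.14, W: 0.10, A: 0.05, R: 0.16},
            N3: {N2: 0.44, N1: 0.10, W: 0.15, A: 0.06, R: 0.25},
            R: {N1: 0.30, W: 0.40, A: 0.30},
        },
        n3_modulation=(1.7, -1.3),
        rem_modulation=(0.6, 0.9),
        fragmentation=0.0,
        target_sleep_latency_min=13.4,
        sleep_latency_sd_min=4.0,
    ),
    Condition.PRESYMPTOMATIC: ArchitecturePreset(
        condition=Condition.PRESYMPTOMATIC,
        mean_bout_s={A: 150, W: 90, N1: 60, N2: 60, N3: 480, R: 240},
        transition={
            A: {W: 0.55, N1: 0.45},
            W: {A: 0.25, N1: 0.75},
            N1: {N2: 0.55, W: 0.20, A: 0.15, R: 0.10},
            N2: {N3: 0.65, N1: 0.12, W: 0.09, A: 0.04, R: 0.10},
            N3: {N2: 0.35, N1: 0.12, W: 0.20, A: 0.06, R: 0.27},
            R: {N1: 0.30, W: 0.40, A: 0.30},
        },
        n3_modulation=(1.9, -1.8),
        rem_modulation=(0.25, 1.6),
        fragmentation=0.10,
        target_sleep_latency_min=22.2,
        sleep_latency_sd_min=5.0,
    ),
    Condition.SYMPTOMATIC: ArchitecturePreset(
        condition=Condition.SYMPTOMATIC,
        mean_bout_s={A: 180, W: 150, N1: 75, N2: 90, N3: 150, R: 150},
        transition={
            A: {W: 0.55, N1: 0.45},
            W: {A: 0.38, N1: 0.62},
            N1: {N2: 0.33, W: 0.32, A: 0.23, R: 0.12},
            N2: {N3: 0.40, N1: 0.10, W: 0.27, A: 0.13, R: 0.10},
            N3: {N2: 0.25, N1: 0.15, W: 0.35, A: 0.15, R: 0.10},
            R: {N1: 0.20, W: 0.45, A: 0.35},
        },
        n3_modulation=(1.2, -0.4),
        rem_modulation=(0.8, 0.4),
        fragmentation=0.6,
        target_sleep_latency_min=18.7,
        sleep_latency_sd_min=6.0,
    ),
}

# Daytime architecture: mostly active wake with a handful of naps.  The
# healthy preset yields 3-4 naps of 10-60 min and a first sleep ~40 min
# after 07:00; with disease the first nap arrives earlier and wakefulness
# fragments.

ARCHITECTURE_DAY: dict[Condition, ArchitecturePreset] = {
    Condition.HEALTHY: ArchitecturePreset(
        condition=Condition.HEALTHY,
        mean_bout_s={A: 2400, W: 240, N1: 180, N2: 480, N3: 180, R: 90},
        transition={
            A: {W: 0.75, N1: 0.25},
            W: {A: 0.75, N1: 0.25},
            N1: {N2: 0.55, W: 0.22, A: 0.21, R: 0.02},
            N2: {N3: 0.12, N1: 0.33, W: 0.30, A: 0.23, R: 0.02},
            N3: {N2: 0.40, N1: 0.20, W: 0.25, A: 0.15},
            R: {N1: 0.20, W: 0.40, A: 0.40},
        },
        fragmentation=0.0,
        target_sleep_latency_min=41.1,
        sleep_latency_sd_min=15.0,
    ),
    Condition.PRESYMPTOMATIC: ArchitecturePreset(
        condition=Condition.PRESYMPTOMATIC,
        mean_bout_s={A: 700, W: 180, N1: 150, N2: 240, N3: 180, R: 120},
        transition={
            A: {W: 0.70, N1: 0.30},
            W: {A: 0.70, N1: 0.30},
            N1: {N2: 0.45, W: 0.25, A: 0.25, R: 0.05},
            N2: {N3: 0.18, N1: 0.25, W: 0.28, A: 0.24, R: 0.05},
            N3: {N2: 0.40, N1: 0.20, W: 0.25, A: 0.15},
            R: {N1: 0.20, W: 0.40, A: 0.40},
        },
        fragmentation=0.15,
        target_sleep_latency_min=25.8,
        sleep_latency_sd_min=12.0,
    ),
    Condition.SYMPTOMATIC: ArchitecturePreset(
        condition=Condition.SYMPTOMATIC,
        mean_bout_s={A: 300, W: 240, N1: 120, N2: 150, N3: 60, R: 90},
        transition={
            A: {W: 0.60, N1: 0.40},
            W: {A: 0.55, N1: 0.45},
            N1: {N2: 0.35, W: 0.30, A: 0.28, R: 0.07},
            N2: {N3: 0.05, N1: 0.25, W: 0.35, A: 0.28, R: 0.07},
            N3: {N2: 0.40, N1: 0.20, W: 0.25, A: 0.15},
            R: {N1: 0.20, W: 0.45, A: 0.35},
        },
        fragmentation=0.5,
        target_sleep_latency_min=8.7,
        sleep_latency_sd_min=5.0,
    ),
}


def _healthy_signals() -> dict[StageLabel, StageSignal]:
    return {
        A: StageSignal((12, 12, 15, 28), emg_rms=60, eog_burst_rate=12),
        W: StageSignal((18, 18, 70, 14), emg_rms=30, eog_burst_rate=2),
        N1: StageSignal((30, 55, 32, 10), emg_rms=15, eog_burst_rate=0.5),
        N2: StageSignal((80, 110, 25, 14), narrowband=(13.0, 8.0), emg_rms=12),
        N3: StageSignal((400, 60, 20, 8), emg_rms=10),
        R: StageSignal((45, 85, 26, 20), emg_rms=5, eog_burst_rate=10),
    }


def _presymptomatic_signals() -> dict[StageLabel, StageSignal]:
    sig = _healthy_signals()
    # Less intense deep sleep despite more of it; mild REM atonia loss.
    sig[N3] = StageSignal((230, 60, 26, 9), emg_rms=10)
    sig[R] = StageSignal((45, 85, 26, 20), emg_rms=8, eog_burst_rate=10)
    sig[A] = StageSignal((12, 12, 15, 30), emg_rms=70, eog_burst_rate=12)
    return sig


def _symptomatic_signals() -> dict[StageLabel, StageSignal]:
    sig = _healthy_signals()
    # Low-beta (13 Hz) peak during active wake; shallow N3; REM atonia loss.
    sig[A] = StageSignal((12, 12, 15, 30), narrowband=(13.0, 9.0), emg_rms=90, eog_burst_rate=12)
    sig[N3] = StageSignal((150, 55, 40, 10), emg_rms=12)
    sig[R] = StageSignal((45, 85, 26, 20), emg_rms=14, eog_burst_rate=10)
    return sig


SIGNAL: dict[Condition, dict[StageLabel, StageSignal]] = {
    Condition.HEALTHY: _healthy_signals(),
    Condition.PRESYMPTOMATIC: _presymptomatic_signals(),
    Condition.SYMPTOMATIC: _symptomatic_signals(),
}

# RR presets: meanNN from the published REM-sleep values; SD derived from
# the published coefficient of variation (CV% = 100*sd/mean).

# Draws below the 0.2 s physiological floor are clipped at generation time;
# at these parameter values the clipped mass is negligible (< 1e-3).
RR: dict[Condition, RrPreset] = {
    Condition.HEALTHY: RrPreset(mean_nn=0.801, sd_nn=0.801 * 0.1443, autocorr=0.3),
    Condition.PRESYMPTOMATIC: RrPreset(mean_nn=0.795, sd_nn=0.795 * 0.2231, autocorr=0.3),
    Condition.SYMPTOMATIC: RrPreset(mean_nn=0.688, sd_nn=0.688 * 0.1567, autocorr=0.3),
}


MSLT: dict[Condition, MsltPreset] = {
    Condition.HEALTHY: MsltPreset(13.5, 3.0, sleep_run_min=5.5, stage_mix=(0.5, 0.5, 0.0, 0.0)),
    Condition.PRESYMPTOMATIC: MsltPreset(6.3, 3.0, sleep_run_min=9.5, stage_mix=(0.4, 0.37, 0.06, 0.17)),
    Condition.SYMPTOMATIC: MsltPreset(9.8, 3.0, sleep_run_min=5.5, stage_mix=(0.4, 0.4, 0.02, 0.18)),
}
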