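"""Seeded generators for hypnograms, PSG signals, RR series, mMSLT days
and actimetry.

Every generator is a pure function of (preset, seed): identical inputs give
identical outputs.  The hypnogram generator is a semi-Markov chain — draw a
stage, hold it for a geometrically distributed number of 30-s epochs with
the preset's mean bout length, then jump according to the transition
propensity row, reweighted by time-of-night modulation (front-loaded N3,
back-loaded REM) and by the fragmentation scalar (wake-intrusion hazard).

EEG is synthesized per epoch in the frequency domain: each analysis band is
band-limited Gaussian noise scaled so its realized variance matches the
preset band power (Parseval), plus an optional narrowband sinusoid.  EMG is
Gaussian tone at the stage RMS with an embedded cardiac R-peak template
train driven by the RR generator; EOG carries slow burst transients at the
stage's rapid-eye-movement rate.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np

from ..hypnogram import AnalysisWindow, Hypnogram, LightsSchedule, WindowKind
from ..psg import PsgRecording
from ..stages import SCORED_STAGES, StageLabel
from .presets import EEG_BANDS, ArchitecturePreset, MsltPreset, RrPreset, StageSignal

A, W, N1, N2, N3, R = (
    StageLabel.A,
    StageLabel.W,
    StageLabel.N1,
    StageLabel.N2,
    StageLabel.N3,
    StageLabel.R,
)

_WAKE = (A, W)
_RR_FLOOR_S = 0.2


# ----------------------------------------------------------------------
# Hypnograms


def _draw_bout_epochs(rng: np.random.Generator, mean_s: float, epoch_length: float) -> int:
    mean_epochs = max(mean_s / epoch_length, 1.0)
    return int(rng.geometric(1.0 / mean_epochs))


def _modulated_row(
    preset: ArchitecturePreset, stage: StageLabel, frac: float
) -> tuple[list[StageLabel], np.ndarray]:
    row = preset.transition[stage]
    targets = list(row)
    weights = np.array([row[t] for t in targets], dtype=float)
    for i, t in enumerate(targets):
        if t is N3:
            weights[i] *= preset.n3_weight(frac)
        elif t is R:
            weights[i] *= preset.rem_weight(frac)
        elif t in _WAKE and stage not in _WAKE:
            weights[i] *= 1.0 + preset.fragmentation
    weights /= weights.sum()
    return targets, weights


def generate_hypnogram(
    preset: ArchitecturePreset,
    window: AnalysisWindow,
    epoch_length: float = 30.0,
    seed: int = 0,
) -> Hypnogram:
    """Simulate a stage sequence that exactly fills ``window``.

    The window opens with a wake run whose length is drawn around the
    preset's target sleep latency (truncated normal, floor 0); thereafter
    the semi-Markov chain runs from N1.  For night windows a lights-off
    event is placed at the window start.
    """
    dur = window.duration_s
    n_epochs_f = dur / epoch_length
    n_epochs = int(round(n_epochs_f))
    if abs(n_epochs_f - n_epochs) > 1e-9:
        raise ValueError("window duration must be a multiple of epoch_length")

    rng = np.random.default_rng(seed)
    stages: list[StageLabel] = []

    # Initial wake run ~ target sleep latency.
    latency_min = max(0.0, rng.normal(preset.target_sleep_latency_min, preset.sleep_latency_sd_min))
    latency_epochs = min(int(round(latency_min * 60.0 / epoch_length)), n_epochs)
    wake_stage = W if window.kind is WindowKind.NIGHT else A
    while len(stages) < latency_epochs:
        bout = _draw_bout_epochs(rng, preset.mean_bout_s[wake_stage], epoch_length)
        stages.extend([wake_stage] * min(bout, latency_epochs - len(stages)))
        wake_stage = A if wake_stage is W else W

    current = N1
    while len(stages) < n_epochs:
        bout = _draw_bout_epochs(rng, preset.mean_bout_s[current], epoch_length)
        stages.extend([current] * min(bout, n_epochs - len(stages)))
        frac = len(stages) / n_epochs
        targets, weights = _modulated_row(preset, current, frac)
        current = targets[rng.choice(len(targets), p=weights)]

    state = "off" if window.kind in (WindowKind.NIGHT, WindowKind.MSLT_SESSION) else "on"
    lights = LightsSchedule(((window.start, state),))
    return Hypnogram(
        start_time=window.start,
        stages=tuple(stages),
        epoch_length=epoch_length,
        lights=lights,
    )


def night_window(date: dt.date | None = None) -> AnalysisWindow:
    """The standard 12-h night window, 19:00 to 07:00 (lights off)."""
    d = date or dt.date(2024, 1, 1)
    start = dt.datetime.combine(d, dt.time(19, 0))
    return AnalysisWindow(start, start + dt.timedelta(hours=12), WindowKind.NIGHT)


def day_window(date: dt.date | None = None) -> AnalysisWindow:
    """The standard 12-h day window, 07:00 to 19:00 (lights on)."""
    d = date or dt.date(2024, 1, 2)
    start = dt.datetime.combine(d, dt.time(7, 0))
    return AnalysisWindow(start, start + dt.timedelta(hours=12), WindowKind.DAY)


# ----------------------------------------------------------------------
# RR intervals


def generate_rr(preset: RrPreset, seed: int = 0, n: int | None = None) -> np.ndarray:
    """Lag-1 autoregressive Gaussian RR series, clipped at the 0.2 s floor.

    If ``n`` is None, intervals are drawn until their cumulative time fills
    ``preset.duration_s``.  Stationary mean and SD equal the preset values
    (before clipping, whose mass is negligible at shipped parameters).
    """
    rng = np.random.default_rng(seed)
    phi = preset.autocorr
    innov_sd = preset.sd_nn * math.sqrt(1.0 - phi * phi)

    if n is not None:
        x = np.empty(n)
        prev = preset.mean_nn + preset.sd_nn * rng.standard_normal()
        for i in range(n):
            prev = preset.mean_nn + phi * (prev - preset.mean_nn) + innov_sd * rng.standard_normal()
            x[i] = prev
        return np.maximum(x, _RR_FLOOR_S)

    out: list[float] = []
    t = 0.0
    prev = preset.mean_nn + preset.sd_nn * rng.standard_normal()
    while t < preset.duration_s:
        prev = preset.mean_nn + phi * (prev - preset.mean_nn) + innov_sd * rng.standard_normal()
        iv = max(prev, _RR_FLOOR_S)
        out.append(iv)
        t += iv
    return np.asarray(out)


# ----------------------------------------------------------------------
# PSG signals


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float, power: float) -> np.ndarray:
    """Band-limited Gaussian noise with expected variance ``power`` (uV^2)."""
    if power <= 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    band = (freqs >= lo) & (freqs < hi)
    k = int(band.sum())
    if k == 0:
        return np.zeros(n)
    spec = np.zeros(len(freqs), dtype=complex)
    # Each retained bin contributes 2*|X|^2/n^2 to the signal variance
    # (one-sided), so |X| = sqrt(power * n^2 / (2k)) gives total = power.
    amp = math.sqrt(power * n * n / (2.0 * k))
    phases = rng.uniform(0.0, 2.0 * np.pi, k)
    mags = rng.normal(size=k) ** 2 + rng.normal(size=k) ** 2  # chi2_2 ~ exponential energy
    mags = np.sqrt(mags / 2.0)
    spec[band] = amp * mags * np.exp(1j * phases)
    return np.fft.irfft(spec, n=n)


def _r_peak_template(fs: float, amp: float) -> np.ndarray:
    """Biphasic ~40 ms cardiac R-wave template."""
    n = max(int(round(0.04 * fs)), 3)
    t = np.linspace(-1.0, 1.0, n)
    return amp * (1.0 - t * t) * np.cos(1.5 * np.pi * t * 0.5)


def _eog_burst(fs: float) -> np.ndarray:
    """~300 ms saccadic deflection."""
    n = int(round(0.3 * fs))
    t = np.linspace(0, 1, n)
    return 80.0 * np.sin(np.pi * t) ** 2


def generate_stage_epochs(
    sig: StageSignal,
    n_epochs: int,
    fs: float = 500.0,
    epoch_length: float = 30.0,
    seed: int = 0,
    rr_preset: RrPreset | None = None,
) -> list[dict[str, np.ndarray]]:
    """Generate ``n_epochs`` stage-locked 3-channel epochs (uV).

    The workhorse behind :func:`generate_psg`; also useful on its own when
    an analysis only needs epochs of a single stage (e.g. spectral
    profiles), avoiding synthesis of a full night.
    """
    rng = np.random.default_rng(seed)
    n = int(round(epoch_length * fs))
    if fs < 2.0 * 35.0:
        raise ValueError(f"fs {fs} Hz too low for the 0.3-35 Hz EEG content")
    if sig.narrowband is not None and fs < 2.0 * sig.narrowband[0]:
        raise ValueError("fs too low for the requested narrowband component")

    template = _r_peak_template(fs, sig.r_peak_amp)
    burst = _eog_burst(fs)
    t = np.arange(n) / fs

    epochs = []
    for _ in range(n_epochs):
        eeg = np.zeros(n)
        for (lo, hi), power in zip(EEG_BANDS.values(), sig.band_powers):
            eeg += _band_noise(rng, n, fs, lo, hi, power)
        if sig.narrowband is not None:
            f0, a0 = sig.narrowband
            eeg += a0 * np.sin(2.0 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))

        emg = sig.emg_rms * rng.standard_normal(n)
        if rr_preset is not None and sig.r_peak_amp > 0:
            rr = generate_rr(rr_preset, seed=int(rng.integers(2**31)))
            beat_times = np.cumsum(rr)
            beat_times = beat_times[beat_times < epoch_length - 0.05]
            for bt in beat_times:
                i0 = int(round(bt * fs))
                emg[i0 : i0 + len(template)] += template[: n - i0]

        eog = 8.0 * rng.standard_normal(n)
        if sig.eog_burst_rate > 0:
            n_bursts = rng.poisson(sig.eog_burst_rate * epoch_length / 60.0)
            for _b in range(n_bursts):
                i0 = rng.integers(0, max(n - len(burst), 1))
                eog[i0 : i0 + len(burst)] += rng.choice([-1.0, 1.0]) * burst[: n - i0]

        epochs.append({"EEG": eeg, "EOG": eog, "EMG": emg})
    return epochs


def generate_psg(
    hyp: Hypnogram,
    preset: dict[StageLabel, StageSignal],
    fs: float = 500.0,
    seed: int = 0,
    rr_preset: RrPreset | None = None,
) -> PsgRecording:
    """Synthesize a full 3-channel recording aligned to a hypnogram.

    Each epoch's content is drawn from the signal preset of its stage.  If
    ``rr_preset`` is given, a single continuous cardiac R-peak template
    train (intervals from :func:`generate_rr`) is overlaid on the EMG
    channel for the whole recording, so RR intervals remain valid across
    epoch boundaries.
    """
    rng = np.random.default_rng(seed)
    n_per = int(round(hyp.epoch_length * fs))
    total = n_per * hyp.n_epochs
    channels = {name: np.zeros(total) for name in ("EEG", "EOG", "EMG")}

    for i, stage in enumerate(hyp.stages):
        if stage not in preset:
            continue
        ep = generate_stage_epochs(
            preset[stage],
            n_epochs=1,
            fs=fs,
            epoch_length=hyp.epoch_length,
            seed=int(rng.integers(2**31)),
            rr_preset=None,
        )[0]
        for name in channels:
            channels[name][i * n_per : (i + 1) * n_per] = ep[name]

    if rr_preset is not None:
        amp = max((s.r_peak_amp for s in preset.values()), default=60.0)
        template = _r_peak_template(fs, amp)
        import dataclasses as _dc

        long_rr = _dc.replace(rr_preset, duration_s=hyp.duration_s)
        beat_times = np.cumsum(generate_rr(long_rr, seed=int(rng.integers(2**31))))
        emg = channels["EMG"]
        for bt in beat_times[beat_times < hyp.duration_s - 0.05]:
            i0 = int(round(bt * fs))
            emg[i0 : i0 + len(template)] += template[: total - i0]

    return PsgRecording(channels=channels, sampling_rate=fs, start_time=hyp.start_time)


# ----------------------------------------------------------------------
# mMSLT days


def generate_mslt_day(
    latency_mean: float,
    latency_sd: float,
    sleep_run_length: float = 5.5,
    seed: int = 0,
    stage_mix: tuple[float, float, float, float] = (0.5, 0.5, 0.0, 0.0),
    session_starts: tuple[dt.datetime, ...] | None = None,
    epoch_length: float = 30.0,
) -> list[Hypnogram]:
    """Three 20-min lights-OFF session hypnograms (10:00, 11:00, 12:00).

    Per session a latency is drawn from a normal distribution (floored at
    0, in minutes); draws of 20 min or more yield an all-wake session
    (latency censored at session length).  Otherwise wake epochs fill the
    latency, then a sleep run of ``sleep_run_length`` minutes composed
    according to ``stage_mix`` (fractions of N1, N2, N3, R), then wake.
    """
    if latency_sd < 0:
        raise ValueError("latency_sd must be non-negative")
    if abs(sum(stage_mix) - 1.0) > 1e-9:
        raise ValueError("stage_mix must sum to 1")
    rng = np.random.default_rng(seed)
    if session_starts is None:
        d = dt.date(2024, 1, 2)
        session_starts = tuple(
            dt.datetime.combine(d, dt.time(h, 0)) for h in (10, 11, 12)
        )
    n_epochs = int(round(20.0 * 60.0 / epoch_length))
    sessions = []
    sleep_order = (N1, N2, N3, R)
    for start in session_starts:
        latency = max(0.0, rng.normal(latency_mean, latency_sd)) if latency_sd > 0 else latency_mean
        wake_epochs = min(int(round(latency * 60.0 / epoch_length)), n_epochs)
        stages: list[StageLabel] = [W] * wake_epochs
        if wake_epochs < n_epochs:
            run_epochs = min(
                int(round(sleep_run_length * 60.0 / epoch_length)), n_epochs - wake_epochs
            )
            counts = [int(round(frac * run_epochs)) for frac in stage_mix]
            while sum(counts) > run_epochs:
                counts[int(np.argmax(counts))] -= 1
            while sum(counts) < run_epochs:
                counts[int(np.argmax(stage_mix))] += 1
            for stage, c in zip(sleep_order, counts):
                stages.extend([stage] * c)
            stages.extend([W] * (n_epochs - len(stages)))
        lights = LightsSchedule(((start, "off"), (start + dt.timedelta(minutes=20), "on")))
        sessions.append(
            Hypnogram(start_time=start, stages=tuple(stages), epoch_length=epoch_length, lights=lights)
        )
    return sessions


# ----------------------------------------------------------------------
# Actimetry

#: Mean telemetric activity counts per 10-s bin, by stage.
ACTIMETRY_RATES = {
    A: 30.0,
    W: 4.0,
    N1: 0.3,
    N2: 0.05,
    N3: 0.01,
    R: 0.05,
    StageLabel.UNSCORED: 0.0,
}


def generate_actimetry(hyp: Hypnogram, seed: int = 0, bin_s: float = 10.0) -> np.ndarray:
    """Poisson activity counts per 10-s bin, rate set by the current stage."""
    rng = np.random.default_rng(seed)
    n_bins = int(round(hyp.duration_s / bin_s))
    rates = np.empty(n_bins)
    for b in range(n_bins):
        epoch = min(int(b * bin_s // hyp.epoch_length), hyp.n_epochs - 1)
        rates[b] = ACTIMETRY_RATES[hyp.stages[epoch]]
    return rng.poisson(rates).astype(int)
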