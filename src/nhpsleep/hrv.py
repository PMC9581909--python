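"""REM-sleep heart-rate variability from the EMG channel.

The neck EMG picks up the cardiac R wave, giving an ECG-like signal during
REM atonia.  Twelve 2-min windows are sampled from REM sleep, R peaks are
detected with an adaptive robust threshold, and beat-to-beat (RR)
intervals are summarized in the time domain: meanNN, StdNN and the
coefficient of variation CV = 100 * StdNN / meanNN, plus the Poincare
successor pairs (RR_n, RR_n+1).
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
from scipy import signal as sps

from .hypnogram import Hypnogram
from .psg import PsgRecording
from .stages import StageLabel

#: Physiological gate on plausible macaque RR intervals, seconds.
RR_GATE = (0.2, 3.0)


class InsufficientRemError(ValueError):
    """Not enough disjoint REM windows are available for sampling."""


@dataclasses.dataclass(frozen=True)
class RrSeries:
    """RR intervals grouped by the 2-min source window they came from."""

    intervals: np.ndarray                       # seconds, pooled, time order
    epoch_bounds: tuple[int, ...]               # cumulative interval count per window
    source_windows: tuple[tuple[dt.datetime, float], ...] = ()
    n_dropped: int = 0                          # intervals outside the gate

    def per_epoch(self) -> list[np.ndarray]:
        out, a = [], 0
        for b in self.epoch_bounds:
            out.append(self.intervals[a:b])
            a = b
        return out


@dataclasses.dataclass(frozen=True)
class HrvSummary:
    mean_nn: float   # seconds
    std_nn: float    # seconds (sample SD by default)
    cv: float        # percent, 100 * std_nn / mean_nn
    n_intervals: int


@dataclasses.dataclass(frozen=True)
class PoincarePairs:
    pairs: np.ndarray  # (n, 2): RR_n vs RR_n+1


def sample_rem_epochs(
    hyp: Hypnogram, n: int = 12, span_s: float = 120.0, seed: int = 0
) -> list[tuple[dt.datetime, float]]:
    """Sample ``n`` disjoint ``span_s``-second windows inside REM runs.

    Candidate windows are the non-overlapping span-length slots inside
    each maximal REM run; ``n`` of them are drawn uniformly without
    replacement (deterministic per seed, returned in time order).
    """
    L = hyp.epoch_length
    per = int(round(span_s / L))
    candidates: list[int] = []  # start epoch of each candidate slot
    run_start = None
    codes = [s is StageLabel.R for s in hyp.stages]
    for i, is_r in enumerate(codes + [False]):
        if is_r and run_start is None:
            run_start = i
        elif not is_r and run_start is not None:
            run_len = i - run_start
            candidates.extend(run_start + k * per for k in range(run_len // per))
            run_start = None
    if len(candidates) < n:
        raise InsufficientRemError(
            f"only {len(candidates)} disjoint {span_s:g}-s REM windows available, need {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(candidates), size=n, replace=False))
    return [(hyp.epoch_start(candidates[k]), span_s) for k in chosen]


def detect_r_peaks(
    emg: np.ndarray,
    fs: float,
    refractory: float = 0.25,
    k: float = 6.0,
    smooth_ms: float = 20.0,
) -> np.ndarray:
    """R-peak times (seconds) via an adaptive robust amplitude threshold.

    The signal is first smoothed with a ~20 ms moving average — the QRS
    complex is a 30-50 ms transient, so averaging suppresses broadband
    muscle noise far more than the R wave.  The threshold is ``k`` robust
    standard deviations (1.4826 * median absolute deviation) above the
    median of the smoothed signal; peaks are local maxima separated by at
    least the refractory period.
    """
    if fs < 100:
        raise ValueError(f"sampling rate {fs} Hz too low for R-peak detection")
    emg = np.asarray(emg, dtype=float)
    win = max(int(round(smooth_ms * 1e-3 * fs)), 1)
    smooth = np.convolve(emg, np.ones(win) / win, mode="same")
    med = np.median(smooth)
    mad = np.median(np.abs(smooth - med))
    if mad == 0 and np.all(smooth == med):
        return np.array([])
    thresh = med + k * 1.4826 * mad
    peaks, _ = sps.find_peaks(smooth, height=thresh, distance=max(int(refractory * fs), 1))
    return peaks / fs


def rr_from_recording(
    rec: PsgRecording,
    windows: list[tuple[dt.datetime, float]],
    refractory: float = 0.25,
    k: float = 6.0,
) -> RrSeries:
    """Detect beats inside each window and assemble the gated RR series.

    Intervals are never formed across window boundaries; intervals outside
    the physiological gate (0.2-3 s) are dropped and counted.
    """
    fs = rec.sampling_rate
    pooled: list[float] = []
    bounds: list[int] = []
    dropped = 0
    for start, span in windows:
        i0 = int(round((start - rec.start_time).total_seconds() * fs))
        seg = rec.channels["EMG"][i0 : i0 + int(round(span * fs))]
        times = detect_r_peaks(seg, fs, refractory=refractory, k=k)
        iv = np.diff(times)
        ok = (iv > RR_GATE[0]) & (iv < RR_GATE[1])
        dropped += int((~ok).sum())
        pooled.extend(iv[ok])
        bounds.append(len(pooled))
    return RrSeries(
        intervals=np.asarray(pooled),
        epoch_bounds=tuple(bounds),
        source_windows=tuple((s, sp) for s, sp in windows),
        n_dropped=dropped,
    )


def rr_series_from_intervals(per_epoch: list[np.ndarray]) -> RrSeries:
    """Build an :class:`RrSeries` directly from per-window interval arrays."""
    pooled = np.concatenate([np.asarray(x, dtype=float) for x in per_epoch])
    bounds = tuple(np.cumsum([len(x) for x in per_epoch]).tolist())
    return RrSeries(intervals=pooled, epoch_bounds=bounds)


def hrv_summary(rr: RrSeries, sample_sd: bool = True) -> HrvSummary:
    """Time-domain HRV over the pooled intervals.

    StdNN uses the sample (n-1) convention by default; set
    ``sample_sd=False`` for the population convention.
    """
    x = rr.intervals
    if len(x) < 2:
        raise ValueError("need at least 2 RR intervals")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1 if sample_sd else 0))
    return HrvSummary(mean_nn=mean, std_nn=sd, cv=100.0 * sd / mean, n_intervals=len(x))


def per_epoch_summaries(rr: RrSeries, sample_sd: bool = True) -> list[HrvSummary]:
    """One summary per source window (windows with < 2 intervals skipped)."""
    out = []
    for x in rr.per_epoch():
        if len(x) >= 2:
            out.append(hrv_summary(RrSeries(intervals=x, epoch_bounds=(len(x),)), sample_sd))
    return out


def poincare(rr: RrSeries) -> PoincarePairs:
    """Successor pairs (RR_n, RR_n+1); pairs never span window boundaries."""
    pairs = []
    for x in rr.per_epoch():
        if len(x) >= 2:
            pairs.append(np.column_stack([x[:-1], x[1:]]))
    if not pairs:
        return PoincarePairs(pairs=np.empty((0, 2)))
    return PoincarePairs(pairs=np.vstack(pairs))
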