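"""Modified multiple sleep latency test (mMSLT) analysis.

Daytime sleepiness is probed with three 20-min lights-OFF opportunities
(10:00, 11:00, 12:00), one hour apart.  Sleep latency is the time from
lights-off to the first 30-s epoch of scorable sleep; if no sleep occurs
the latency is censored at 20 min.  Stage time within each session is
reported with the two wake stages pooled (A+W) and the two light-sleep
stages pooled (N1+N2); REM occurring inside a session is flagged as a
sleep-attack-like REM intrusion.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .hypnogram import Hypnogram
from .stages import StageLabel

SESSION_MINUTES = 20.0


class SessionError(ValueError):
    """A lights-OFF session hypnogram does not span exactly 20 minutes."""


@dataclasses.dataclass(frozen=True)
class MsltSession:
    """One 20-min lights-OFF opportunity (index 1..3 within the day)."""

    index: int
    hyp: Hypnogram

    def __post_init__(self) -> None:
        if self.index not in (1, 2, 3):
            raise ValueError("session index must be 1, 2 or 3")
        if abs(self.hyp.duration_s - SESSION_MINUTES * 60.0) > 1e-6:
            raise SessionError(
                f"session span must be exactly {SESSION_MINUTES:g} min, "
                f"got {self.hyp.duration_s / 60.0:g} min"
            )


@dataclasses.dataclass(frozen=True)
class MsltResult:
    """Censored latency and pooled stage durations for one session."""

    sl: float          # minutes, in [0, 20]
    wake_min: float    # A + W
    n12_min: float     # N1 + N2
    n3_min: float
    rem_min: float
    rem_intrusion: bool  # any REM inside the session (sleep-attack marker)


def sessions_from_day(day: list[Hypnogram]) -> list[MsltSession]:
    """Wrap the three session hypnograms of one test day."""
    return [MsltSession(index=i + 1, hyp=h) for i, h in enumerate(day)]


def session_latency(session: MsltSession) -> float:
    """Minutes from session start to the first sleep epoch; 20 if none."""
    for i, s in enumerate(session.hyp.stages):
        if s.is_sleep:
            return i * session.hyp.epoch_length / 60.0
    return SESSION_MINUTES


def session_durations(session: MsltSession) -> MsltResult:
    """Pooled stage minutes; the four durations sum to the 20-min span."""
    L_min = session.hyp.epoch_length / 60.0
    mins = {stage: 0.0 for stage in StageLabel}
    for s in session.hyp.stages:
        mins[s] += L_min
    rem = mins[StageLabel.R]
    return MsltResult(
        sl=session_latency(session),
        wake_min=mins[StageLabel.A] + mins[StageLabel.W] + mins[StageLabel.UNSCORED],
        n12_min=mins[StageLabel.N1] + mins[StageLabel.N2],
        n3_min=mins[StageLabel.N3],
        rem_min=rem,
        rem_intrusion=rem > 0.0,
    )


def _mean_sem(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return mean, sem


def mslt_summarize(days: list[list[Hypnogram]], censored_as_20: bool = True) -> dict:
    """Per-session-index and pooled mean +/- SEM of latency and durations.

    ``days`` is a list of test days, each a list of three 20-min session
    hypnograms.  Censored (no-sleep) sessions contribute their 20-min
    latency to the means by default; with ``censored_as_20=False`` they are
    dropped from the latency average (survival-style handling) but still
    contribute durations.
    """
    by_index: dict[int, list[MsltResult]] = {1: [], 2: [], 3: []}
    for day in days:
        for sess in sessions_from_day(day):
            by_index[sess.index].append(session_durations(sess))

    def summarize(results: list[MsltResult]) -> dict:
        lat = [r.sl for r in results if censored_as_20 or r.sl < SESSION_MINUTES]
        if not lat:  # every session censored and censoring excluded
            lat = [SESSION_MINUTES]
        out = {"n": len(results)}
        out["sl"] = _mean_sem(lat)
        for field in ("wake_min", "n12_min", "n3_min", "rem_min"):
            out[field] = _mean_sem([getattr(r, field) for r in results])
        out["rem_intrusions"] = sum(r.rem_intrusion for r in results)
        return out

    pooled = [r for rs in by_index.values() for r in rs]
    if not pooled:
        raise ValueError("no sessions supplied")
    return {
        "by_session": {i: summarize(rs) for i, rs in by_index.items() if rs},
        "pooled": summarize(pooled),
    }
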