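"""Sleep-architecture metrics computed from a hypnogram.

All the night/day summary parameters of a standard polysomnographic
report: sleep latency (SL), total sleep time (TST), wake after sleep onset
(WASO), sleep efficiency, per-stage percentages of total scoring time,
N3 as a percentage of TST, wake<->sleep transition rate, sleep-cycle count,
daytime nap decomposition and day/night sleep proportion.

Conventions
-----------
* Epoch i covers the half-open interval [start + i*L, start + (i+1)*L);
  latencies are measured to the *start* of the qualifying epoch.
* UNSCORED epochs are excluded from every "total scoring time" denominator.
* The sleep period time (SPT) runs from sleep onset to the end of the
  analysis window, so SL + TST + WASO equals the scored window duration
  whenever any sleep occurs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np

from .hypnogram import AnalysisWindow, Hypnogram, WindowKind
from .stages import SCORED_STAGES, StageLabel


@dataclasses.dataclass(frozen=True)
class SleepSummary:
    """One recording's architecture metrics (one row of a summary table)."""

    sl: float | None                 # sleep latency, min (None if no sleep)
    tst: float                       # total sleep time, min
    waso: float                      # wake after sleep onset, min
    sleep_efficiency: float | None   # percent (None if no sleep)
    stage_pct: dict[StageLabel, float]
    n3_pct_of_tst: float | None
    transitions_per_hour: float
    sleep_cycles: int
    window: AnalysisWindow


@dataclasses.dataclass(frozen=True)
class NapRecord:
    """One daytime nap: a sleep run tolerating brief internal awakenings."""

    start: dt.datetime
    duration_min: float
    composition_min: dict[StageLabel, float]


# ----------------------------------------------------------------------
# Primitive quantities


def _first_sleep_index(hyp: Hypnogram) -> int | None:
    for i, s in enumerate(hyp.stages):
        if s.is_sleep:
            return i
    return None


def sleep_latency(hyp: Hypnogram) -> float | None:
    """Minutes from lights-off to the start of the first sleep epoch.

    Returns None when no sleep occurs (an undefined latency, distinct from
    the 20-min censored latency used in lights-OFF sessions).  Raises
    ``ValueError`` if the hypnogram has a lights schedule with no off event
    in its span.
    """
    if hyp.lights is not None:
        off = hyp.lights.first_off_at_or_after(hyp.start_time - dt.timedelta(seconds=1))
        if off is None or off >= hyp.end_time:
            raise ValueError("no lights-off event within the hypnogram span")
        anchor = max(off, hyp.start_time)
    else:
        anchor = hyp.start_time
    i = _first_sleep_index(hyp)
    if i is None:
        return None
    return (hyp.epoch_start(i) - anchor).total_seconds() / 60.0


def total_sleep_time(hyp: Hypnogram) -> float:
    """Minutes spent in any sleep stage (N1, N2, N3, R)."""
    return int(hyp.sleep_mask().sum()) * hyp.epoch_length / 60.0


def _spt_minutes(hyp: Hypnogram) -> float:
    """Sleep period time: from sleep onset to the end of the scored window."""
    i = _first_sleep_index(hyp)
    if i is None:
        return 0.0
    return (hyp.n_epochs - i) * hyp.epoch_length / 60.0


def waso(hyp: Hypnogram) -> float:
    """Wake after sleep onset: SPT minus TST, minutes (0 if no sleep)."""
    return _spt_minutes(hyp) - total_sleep_time(hyp)


def sleep_efficiency(hyp: Hypnogram) -> float | None:
    """100 * TST / SPT, percent; None when no sleep occurs."""
    spt = _spt_minutes(hyp)
    if spt == 0.0:
        return None
    return 100.0 * total_sleep_time(hyp) / spt


def efficiency_from_tst_waso(tst_min: float, waso_min: float) -> float:
    """Sleep efficiency from its two published building blocks.

    SPT = TST + WASO by definition, so efficiency = 100*TST/(TST+WASO);
    useful for checking tabulated group means against each other.
    """
    return 100.0 * tst_min / (tst_min + waso_min)


def stage_percentages(hyp: Hypnogram) -> dict[StageLabel, float]:
    """Per-stage percent of total scoring time; sums to 100 over the six stages."""
    scored = [s for s in hyp.stages if s.is_scored]
    n = len(scored)
    if n == 0:
        raise ValueError("hypnogram has no scored epochs")
    return {
        stage: 100.0 * sum(1 for s in scored if s is stage) / n for stage in SCORED_STAGES
    }


def n3_percent_of_tst(hyp: Hypnogram) -> float | None:
    """N3 minutes as a percentage of TST; None if TST is zero."""
    tst = total_sleep_time(hyp)
    if tst == 0.0:
        return None
    n3 = sum(1 for s in hyp.stages if s is StageLabel.N3) * hyp.epoch_length / 60.0
    return 100.0 * n3 / tst


def transitions_per_hour(hyp: Hypnogram, all_boundaries: bool = False) -> float:
    """Wake<->sleep stage transitions per scored hour.

    By default only crossings of the wake/sleep group boundary are counted;
    with ``all_boundaries=True`` every adjacent stage change counts.
    Epoch pairs involving UNSCORED are skipped.
    """
    count = 0
    scored_epochs = 0
    for a, b in zip(hyp.stages, hyp.stages[1:]):
        if not (a.is_scored and b.is_scored):
            continue
        if all_boundaries:
            count += a is not b
        else:
            count += a.is_wake != b.is_wake
    scored_epochs = sum(1 for s in hyp.stages if s.is_scored)
    hours = scored_epochs * hyp.epoch_length / 3600.0
    return count / hours if hours > 0 else 0.0


def count_sleep_cycles(
    hyp: Hypnogram,
    min_nrem: float = 10.0,
    min_rem_epochs: int = 1,
    rem_gap_end: float = 5.0,
    wake_break_min: float | None = None,
) -> int:
    """Count completed sleep cycles (NREM period followed by a REM episode).

    A cycle requires at least ``min_nrem`` minutes of {N2, N3} accumulated
    since the previous cycle, followed by a REM episode of at least
    ``min_rem_epochs`` epochs; the episode ends once ``rem_gap_end``
    minutes of non-R elapse.  An adapted Feinberg-Floyd rule with
    macaque-scaled defaults.  Macaque sleep is polyphasic, so by default
    brief awakenings do *not* reset the NREM accumulator; pass
    ``wake_break_min`` to make continuous wake of that length break the
    run.
    """
    if min_nrem <= 0 or min_rem_epochs <= 0 or rem_gap_end <= 0:
        raise ValueError("cycle-rule parameters must be positive")
    L_min = hyp.epoch_length / 60.0
    gap_epochs = int(np.ceil(rem_gap_end / L_min))
    break_epochs = (
        int(np.ceil(wake_break_min / L_min)) if wake_break_min is not None else None
    )

    count = 0
    nrem_min = 0.0
    in_rem = False
    rem_epochs = 0
    nonr_run = 0
    wake_run = 0

    def close_episode() -> None:
        nonlocal count, nrem_min, in_rem, rem_epochs
        if in_rem and rem_epochs >= min_rem_epochs and nrem_min >= min_nrem:
            count += 1
            nrem_min = 0.0
        in_rem = False
        rem_epochs = 0

    for s in hyp.stages:
        if s is StageLabel.R:
            if not in_rem:
                in_rem = True
                rem_epochs = 0
            rem_epochs += 1
            nonr_run = 0
            wake_run = 0
            continue
        if in_rem:
            nonr_run += 1
            if nonr_run >= gap_epochs:
                close_episode()
        if s.is_wake:
            wake_run += 1
            if break_epochs is not None and wake_run >= break_epochs and not in_rem:
                nrem_min = 0.0
        else:
            wake_run = 0
            if s in (StageLabel.N2, StageLabel.N3):
                nrem_min += L_min
    close_episode()
    return count


# ----------------------------------------------------------------------
# Summaries


def night_summary(hyp: Hypnogram, **cycle_kwargs) -> SleepSummary:
    """All nighttime architecture metrics for one 12-h recording."""
    return SleepSummary(
        sl=sleep_latency(hyp),
        tst=total_sleep_time(hyp),
        waso=waso(hyp),
        sleep_efficiency=sleep_efficiency(hyp),
        stage_pct=stage_percentages(hyp),
        n3_pct_of_tst=n3_percent_of_tst(hyp),
        transitions_per_hour=transitions_per_hour(hyp),
        sleep_cycles=count_sleep_cycles(hyp, **cycle_kwargs),
        window=hyp.window(WindowKind.NIGHT),
    )


def first_sleep_after_wake(hyp: Hypnogram) -> float | None:
    """Minutes from the day-window start (07:00) to the first sleep epoch."""
    i = _first_sleep_index(hyp)
    if i is None:
        return None
    return i * hyp.epoch_length / 60.0


def find_naps(
    hyp: Hypnogram, nap_min: float = 5.0, nap_gap: float = 2.5
) -> list[NapRecord]:
    """Daytime naps: maximal sleep runs tolerating wake gaps < ``nap_gap`` min.

    A nap's span runs from its first to its last sleep epoch (internal brief
    awakenings included in the span and in the stage composition); spans
    whose total *sleep* time is below ``nap_min`` minutes are discarded.
    """
    L_min = hyp.epoch_length / 60.0
    gap_epochs = int(np.ceil(nap_gap / L_min))
    sleep = hyp.sleep_mask()

    naps: list[NapRecord] = []
    i = 0
    n = hyp.n_epochs
    while i < n:
        if not sleep[i]:
            i += 1
            continue
        start = i
        last_sleep = i
        j = i + 1
        while j < n:
            if sleep[j]:
                last_sleep = j
                j += 1
            elif j - last_sleep < gap_epochs:
                j += 1
            else:
                break
        span = hyp.stages[start : last_sleep + 1]
        sleep_min = sum(1 for s in span if s.is_sleep) * L_min
        if sleep_min >= nap_min:
            comp = {
                stage: sum(1 for s in span if s is stage) * L_min
                for stage in SCORED_STAGES
            }
            naps.append(
                NapRecord(
                    start=hyp.epoch_start(start),
                    duration_min=len(span) * L_min,
                    composition_min=comp,
                )
            )
        i = last_sleep + 1
    return naps


def daytime_summary(
    hyp: Hypnogram, nap_min: float = 5.0, nap_gap: float = 2.5, **cycle_kwargs
) -> tuple[SleepSummary, list[NapRecord]]:
    """Daytime hypersomnia metrics plus the nap table.

    The summary's ``sl`` field holds the first sleep after wake, anchored at
    the day-window start rather than at a lights-off event.
    """
    summary = SleepSummary(
        sl=first_sleep_after_wake(hyp),
        tst=total_sleep_time(hyp),
        waso=waso(hyp),
        sleep_efficiency=sleep_efficiency(hyp),
        stage_pct=stage_percentages(hyp),
        n3_pct_of_tst=n3_percent_of_tst(hyp),
        transitions_per_hour=transitions_per_hour(hyp),
        sleep_cycles=count_sleep_cycles(hyp, **cycle_kwargs),
        window=hyp.window(WindowKind.DAY),
    )
    return summary, find_naps(hyp, nap_min=nap_min, nap_gap=nap_gap)


def day_night_proportion(day: SleepSummary, night: SleepSummary) -> tuple[float, float]:
    """Percent of 24-h total sleep time occurring in the day vs the night."""
    total = day.tst + night.tst
    if total == 0:
        raise ValueError("no sleep in either window")
    pct_day = 100.0 * day.tst / total
    return pct_day, 100.0 - pct_day


def actimetry_profile(counts: np.ndarray, window: AnalysisWindow, bin_s: float = 10.0) -> np.ndarray:
    """Counts/min series: sums of consecutive 1-min groups of 10-s bins."""
    counts = np.asarray(counts)
    per_min = int(round(60.0 / bin_s))
    n_min = int(round(window.duration_min))
    if len(counts) < n_min * per_min:
        raise ValueError(
            f"need {n_min * per_min} bins to cover {n_min} minutes, got {len(counts)}"
        )
    return counts[: n_min * per_min].reshape(n_min, per_min).sum(axis=1)
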