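"""Hypnograms, lights schedules and analysis windows, with CSV round-trip I/O.

A hypnogram is an ordered sequence of fixed-length (default 30 s) epochs,
each carrying a stage label and an artifact flag, anchored to an absolute
start time and optionally accompanied by a lights on/off schedule.

The CSV dialect is deliberately plain so files are greppable and round-trip
bit-exactly: ``#``-prefixed header lines carry ``start_time`` (ISO-8601),
``epoch_length`` (seconds) and one ``lights`` line per switching event,
followed by a ``epoch_index,stage,artifact`` table.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .stages import SCORED_STAGES, StageLabel, parse_stage


class WindowKind(enum.Enum):
    NIGHT = "night"          # 19:00 -> 07:00, lights off
    DAY = "day"              # 07:00 -> 19:00, lights on
    MSLT_SESSION = "mslt_session"  # 20-min lights-OFF opportunity

    def __str__(self) -> str:
        return self.value


@dataclasses.dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time interval [start, end) tagged with its role."""

    start: dt.datetime
    end: dt.datetime
    kind: WindowKind = WindowKind.NIGHT

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window end {self.end} must be after start {self.start}")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0


@dataclasses.dataclass(frozen=True)
class LightsSchedule:
    """Ordered lights switching events: ``(timestamp, "on"|"off")``.

    Timestamps must be strictly increasing and states must alternate after
    the first event.
    """

    events: tuple[tuple[dt.datetime, str], ...]

    def __post_init__(self) -> None:
        for _, state in self.events:
            if state not in ("on", "off"):
                raise ValueError(f"lights state must be 'on' or 'off', got {state!r}")
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("lights events must have strictly increasing timestamps")
        states = [s for _, s in self.events]
        if any(a == b for a, b in zip(states, states[1:])):
            raise ValueError("lights events must alternate on/off")

    def first_off_at_or_after(self, t: dt.datetime) -> dt.datetime | None:
        """Timestamp of the first lights-off event at or after ``t``."""
        for when, state in self.events:
            if state == "off" and when >= t:
                return when
        return None

    def off_events(self) -> list[dt.datetime]:
        return [when for when, state in self.events if state == "off"]


class HypnogramParseError(ValueError):
    """Raised when a hypnogram CSV is malformed."""


@dataclasses.dataclass(frozen=True)
class Hypnogram:
    """Stage-labelled 30-s epoch sequence anchored to wall-clock time."""

    start_time: dt.datetime
    stages: tuple[StageLabel, ...]
    epoch_length: float = 30.0
    artifact_flags: tuple[bool, ...] | None = None
    lights: LightsSchedule | None = None

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if len(self.stages) == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        if self.artifact_flags is None:
            object.__setattr__(self, "artifact_flags", (False,) * len(self.stages))
        elif len(self.artifact_flags) != len(self.stages):
            raise ValueError(
                f"artifact_flags length {len(self.artifact_flags)} != "
                f"number of epochs {len(self.stages)}"
            )

    # -- basic geometry -------------------------------------------------

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length

    @property
    def end_time(self) -> dt.datetime:
        return self.start_time + dt.timedelta(seconds=self.duration_s)

    def epoch_start(self, i: int) -> dt.datetime:
        """Start timestamp of epoch ``i`` (half-open [start, start+L))."""
        return self.start_time + dt.timedelta(seconds=i * self.epoch_length)

    def window(self, kind: WindowKind = WindowKind.NIGHT) -> AnalysisWindow:
        return AnalysisWindow(self.start_time, self.end_time, kind)

    # -- vector views ---------------------------------------------------

    def codes(self) -> np.ndarray:
        """Integer stage codes (index into ``SCORED_STAGES``; UNSCORED = -1)."""
        lut = {s: i for i, s in enumerate(SCORED_STAGES)}
        return np.array([lut.get(s, -1) for s in self.stages], dtype=np.int8)

    def scored_mask(self) -> np.ndarray:
        return np.array([s.is_scored for s in self.stages], dtype=bool)

    def sleep_mask(self) -> np.ndarray:
        return np.array([s.is_sleep for s in self.stages], dtype=bool)

    def wake_mask(self) -> np.ndarray:
        return np.array([s.is_wake for s in self.stages], dtype=bool)

    def slice(self, start_epoch: int, n_epochs: int) -> "Hypnogram":
        """Sub-hypnogram of ``n_epochs`` epochs starting at ``start_epoch``."""
        if start_epoch < 0 or start_epoch + n_epochs > self.n_epochs:
            raise IndexError("slice outside hypnogram")
        return Hypnogram(
            start_time=self.epoch_start(start_epoch),
            stages=self.stages[start_epoch : start_epoch + n_epochs],
            epoch_length=self.epoch_length,
            artifact_flags=self.artifact_flags[start_epoch : start_epoch + n_epochs],
            lights=self.lights,
        )


# ----------------------------------------------------------------------
# CSV I/O


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    """Write a hypnogram CSV that round-trips bit-exactly via read_hypnogram."""
    path = Path(path)
    lines = [
        f"# start_time: {hyp.start_time.isoformat()}",
        f"# epoch_length: {hyp.epoch_length:g}",
    ]
    if hyp.lights is not None:
        for when, state in hyp.lights.events:
            lines.append(f"# lights: {when.isoformat()} {state}")
    lines.append("epoch_index,stage,artifact")
    for i, (stage, flag) in enumerate(zip(hyp.stages, hyp.artifact_flags)):
        lines.append(f"{i},{stage},{int(flag)}")
    path.write_text("\n".join(lines) + "\n")


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a hypnogram CSV written by :func:`write_hypnogram`.

    Raises :class:`HypnogramParseError` on unknown stage tokens (naming the
    offending row) and on duplicate or missing epoch indices.
    """
    path = Path(path)
    start_time: dt.datetime | None = None
    epoch_length = 30.0
    lights_events: list[tuple[dt.datetime, str]] = []
    rows: list[tuple[int, StageLabel, bool]] = []
    header_seen = False

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("start_time:"):
                start_time = dt.datetime.fromisoformat(body.split(":", 1)[1].strip())
            elif body.startswith("epoch_length:"):
                epoch_length = float(body.split(":", 1)[1].strip())
            elif body.startswith("lights:"):
                payload = body.split(":", 1)[1].strip()
                when_str, state = payload.rsplit(" ", 1)
                lights_events.append((dt.datetime.fromisoformat(when_str.strip()), state))
            continue
        if not header_seen:
            if line.lower() != "epoch_index,stage,artifact":
                raise HypnogramParseError(
                    f"{path}:{lineno}: expected header 'epoch_index,stage,artifact', got {line!r}"
                )
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise HypnogramParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        try:
            idx = int(parts[0])
        except ValueError:
            raise HypnogramParseError(f"{path}:{lineno}: bad epoch index {parts[0]!r}") from None
        try:
            stage = parse_stage(parts[1])
        except ValueError as exc:
            raise HypnogramParseError(f"{path}:{lineno}: {exc}") from None
        rows.append((idx, stage, bool(int(parts[2]))))

    if start_time is None:
        raise HypnogramParseError(f"{path}: missing '# start_time:' header line")
    if not rows:
        raise HypnogramParseError(f"{path}: no epoch rows")
    indices = [r[0] for r in rows]
    if indices != list(range(len(rows))):
        seen: set[int] = set()
        for idx in indices:
            if idx in seen:
                raise HypnogramParseError(f"{path}: duplicate epoch index {idx}")
            seen.add(idx)
        missing = sorted(set(range(len(rows))) - seen)
        raise HypnogramParseError(f"{path}: missing/misordered epoch indices (first gap: {missing[:1] or indices[:1]})")

    return Hypnogram(
        start_time=start_time,
        stages=tuple(r[1] for r in rows),
        epoch_length=epoch_length,
        artifact_flags=tuple(r[2] for r in rows),
        lights=LightsSchedule(tuple(lights_events)) if lights_events else None,
    )


def hypnogram_from_tokens(
    tokens: Sequence[str] | Iterable[str],
    start_time: dt.datetime | None = None,
    epoch_length: float = 30.0,
    lights: LightsSchedule | None = None,
) -> Hypnogram:
    """Convenience constructor from stage tokens like ``["W","W","N1"]``."""
    if start_time is None:
        start_time = dt.datetime(2024, 1, 1, 19, 0, 0)
    stages = tuple(parse_stage(t) for t in tokens)
    if lights is None:
        lights = LightsSchedule(((start_time, "off"),))
    return Hypnogram(start_time=start_time, stages=stages, epoch_length=epoch_length, lights=lights)
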