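"""Polysomnography recordings: the in-memory container, EDF I/O, epoch slicing.

A recording holds the three telemetry channels (EEG, EOG, EMG) sampled at a
common rate (500 Hz by default) in microvolts.  Reading goes through MNE's
EDF reader; writing uses a small built-in EDF (16-bit) writer so synthetic
recordings can be exported and round-tripped.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path
from typing import Mapping

import numpy as np

from .hypnogram import Hypnogram
from .stages import StageLabel

#: Canonical channel names, in EDF write order.
CHANNELS = ("EEG", "EOG", "EMG")

# Highest frequency each channel is analysed at; the sampling rate must
# exceed twice the largest of these across the channels present.
_MAX_ANALYSIS_HZ = {"EEG": 35.0, "EOG": 35.0, "EMG": 100.0}


class ChannelError(ValueError):
    """A required channel is missing or channels are inconsistent."""


class CoverageError(ValueError):
    """A recording does not cover the span the hypnogram requires."""


@dataclasses.dataclass(frozen=True)
class PsgRecording:
    """Multichannel sampled signal set in microvolts, aligned to wall clock."""

    channels: dict[str, np.ndarray]
    sampling_rate: float
    start_time: dt.datetime

    def __post_init__(self) -> None:
        if not self.channels:
            raise ChannelError("recording must contain at least one channel")
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ChannelError(f"channels have unequal lengths: {lengths}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        needed = 2.0 * max(_MAX_ANALYSIS_HZ.get(name, 0.0) for name in self.channels)
        if self.sampling_rate <= needed:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz too low for channels "
                f"{sorted(self.channels)} (need > {needed} Hz)"
            )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def end_time(self) -> dt.datetime:
        return self.start_time + dt.timedelta(seconds=self.duration_s)


# ----------------------------------------------------------------------
# EDF writing (minimal, 16-bit, 1-second data records)


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw + b" " * (width - len(raw))


def write_edf(rec: PsgRecording, path: str | Path) -> None:
    """Write a recording as a plain EDF file (physical unit uV).

    Data are quantized to 16 bits over a symmetric per-channel physical
    range; the last data record is zero-padded if the recording length is
    not a whole number of seconds.
    """
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    names = [n for n in CHANNELS if n in rec.channels] + [
        n for n in rec.channels if n not in CHANNELS
    ]
    ns = len(names)
    n_records = int(np.ceil(rec.n_samples / fs))

    phys_ranges = {}
    for name in names:
        amp = float(np.max(np.abs(rec.channels[name]))) if rec.n_samples else 0.0
        phys_ranges[name] = max(amp * 1.001, 1.0)

    header = b""
    header += _pad("0", 8)
    header += _pad("X", 80)                      # patient id
    header += _pad("nhpsleep synthetic", 80)     # recording id
    header += _pad(rec.start_time.strftime("%d.%m.%y"), 8)
    header += _pad(rec.start_time.strftime("%H.%M.%S"), 8)
    header += _pad(str(256 * (ns + 1)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)                       # record duration, seconds
    header += _pad(str(ns), 4)
    header += b"".join(_pad(n, 16) for n in names)
    header += b"".join(_pad("", 80) for _ in names)          # transducer
    header += b"".join(_pad("uV", 8) for _ in names)
    header += b"".join(_pad(f"{-phys_ranges[n]:.6g}"[:8], 8) for n in names)
    header += b"".join(_pad(f"{phys_ranges[n]:.6g}"[:8], 8) for n in names)
    header += b"".join(_pad("-32768", 8) for _ in names)
    header += b"".join(_pad("32767", 8) for _ in names)
    header += b"".join(_pad("", 80) for _ in names)          # prefiltering
    header += b"".join(_pad(str(fs), 8) for _ in names)
    header += b"".join(_pad("", 32) for _ in names)

    with open(path, "wb") as fh:
        fh.write(header)
        total = n_records * fs
        digital = {}
        for name in names:
            x = np.zeros(total)
            x[: rec.n_samples] = rec.channels[name]
            scale = 32767.0 / phys_ranges[name]
            digital[name] = np.clip(np.round(x * scale), -32768, 32767).astype("<i2")
        for r in range(n_records):
            for name in names:
                fh.write(digital[name][r * fs : (r + 1) * fs].tobytes())


# ----------------------------------------------------------------------
# EDF reading (via MNE)


def read_psg(
    path: str | Path,
    channel_map: Mapping[str, str] | None = None,
) -> PsgRecording:
    """Read an EDF file into a :class:`PsgRecording` in microvolts.

    Parameters
    ----------
    path
        EDF file path.
    channel_map
        Maps canonical names (``EEG``, ``EOG``, ``EMG``) to the EDF channel
        labels in the file.  By default each canonical name is matched
        case-insensitively as a substring of the EDF labels.

    Raises
    ------
    ChannelError
        If a mapped channel is absent from the file.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = list(raw.ch_names)

    resolved: dict[str, str] = {}
    if channel_map is not None:
        for canon, label in channel_map.items():
            if label not in labels:
                raise ChannelError(f"channel {label!r} (mapped to {canon}) not in EDF: {labels}")
            resolved[canon] = label
    else:
        for canon in CHANNELS:
            hits = [lb for lb in labels if canon.lower() in lb.lower()]
            if not hits:
                raise ChannelError(f"no EDF channel matches {canon!r}; available: {labels}")
            resolved[canon] = hits[0]

    data = raw.get_data(picks=[resolved[c] for c in resolved])  # volts
    meas = raw.info["meas_date"]
    if meas is None:
        start = dt.datetime(2000, 1, 1)
    else:
        start = meas.replace(tzinfo=None) if meas.tzinfo else meas
    return PsgRecording(
        channels={canon: np.asarray(data[i], dtype=float) * 1e6 for i, canon in enumerate(resolved)},
        sampling_rate=float(raw.info["sfreq"]),
        start_time=start,
    )


# ----------------------------------------------------------------------
# Epoch slicing


def slice_epochs(
    rec: PsgRecording, hyp: Hypnogram
) -> list[tuple[StageLabel, dict[str, np.ndarray]]]:
    """Cut the recording into per-epoch slices aligned to the hypnogram.

    Returns one ``(stage, {channel: samples})`` pair per epoch, each slice
    being ``epoch_length * fs`` samples.  Raises :class:`CoverageError` if
    the recording does not span the hypnogram.
    """
    fs = rec.sampling_rate
    spe_f = hyp.epoch_length * fs
    spe = int(round(spe_f))
    if abs(spe_f - spe) > 1e-6:
        raise ValueError("epoch_length * sampling_rate must be an integer sample count")

    offset_s = (hyp.start_time - rec.start_time).total_seconds()
    if offset_s < -1e-9:
        raise CoverageError(
            f"recording starts {-offset_s:.1f} s after hypnogram start "
            f"(missing span {hyp.start_time} .. {rec.start_time})"
        )
    offset = int(round(offset_s * fs))
    needed = offset + hyp.n_epochs * spe
    if needed > rec.n_samples:
        missing = (needed - rec.n_samples) / fs
        raise CoverageError(
            f"recording ends {missing:.1f} s before the hypnogram does "
            f"(recording end {rec.end_time}, hypnogram end {hyp.end_time})"
        )

    out = []
    for i, stage in enumerate(hyp.stages):
        a = offset + i * spe
        out.append((stage, {name: x[a : a + spe] for name, x in rec.channels.items()}))
    return out
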