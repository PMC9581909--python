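"""Stage-conditioned EEG/EMG spectral analysis.

Per 30-s epoch, an absolute power spectrum is estimated Welch-style:
Hamming-windowed 5-s segments with 50% overlap (11 segments per epoch),
averaged, and reported as *integrated* power per 0.2-Hz bin (uV^2), so the
sum over a band is the signal variance contributed by that band (a
sinusoid of amplitude A integrates to A^2/2).  Epoch spectra are
aggregated into 1-Hz bins (half-open [k, k+1) Hz), averaged across the
artifact-free epochs of a stage with a Student-t 95% confidence interval,
and compared across disease conditions with a per-bin one-way ANOVA.

A deterministic rule-based auto-stager is included as plumbing for
round-trip tests against the synthetic generator; it is not a substitute
for expert scoring.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .hypnogram import Hypnogram
from .psg import PsgRecording, slice_epochs
from .stages import StageLabel


@dataclasses.dataclass(frozen=True)
class EpochPsd:
    """Integrated power per 0.2-Hz bin for one epoch."""

    frequencies: np.ndarray   # Hz, Welch grid (0 .. fs/2)
    power: np.ndarray         # uV^2 per bin (integrated, not density)
    epoch_index: int = 0
    stage: StageLabel = StageLabel.UNSCORED

    def total_power(self) -> float:
        return float(self.power[1:].sum())  # excluding DC


@dataclasses.dataclass(frozen=True)
class SpectralProfile:
    """Stage-conditioned mean power per 1-Hz bin with 95% CI."""

    bin_freqs: np.ndarray     # lower edge of each 1-Hz bin
    mean: np.ndarray          # uV^2 per bin
    ci_half: np.ndarray       # 95% CI half-width per bin
    n_epochs: int
    stage: StageLabel
    condition: str | None = None


@dataclasses.dataclass(frozen=True)
class BinComparison:
    """Per-1-Hz-bin one-way ANOVA across conditions."""

    bin_freqs: np.ndarray
    f_stat: np.ndarray
    p: np.ndarray
    significant: np.ndarray               # boolean mask at alpha
    runs: list[tuple[float, float]]       # contiguous significant [lo, hi) Hz
    conditions: tuple[str, ...]
    alpha: float = 0.05


SEGMENT_SECONDS = 5.0


def epoch_psd(
    x: np.ndarray,
    fs: float,
    epoch_index: int = 0,
    stage: StageLabel = StageLabel.UNSCORED,
) -> EpochPsd:
    """Welch PSD of one epoch: Hamming 5-s segments, 50% overlap.

    Raises ``ValueError`` if the epoch is shorter than one 5-s segment.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(SEGMENT_SECONDS * fs))
    if len(x) < nperseg:
        raise ValueError(
            f"epoch of {len(x) / fs:g} s is shorter than one {SEGMENT_SECONDS:g}-s segment"
        )
    freqs, density = sps.welch(
        x, fs=fs, window="hamming", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant", scaling="density",
    )
    df = freqs[1] - freqs[0]
    return EpochPsd(frequencies=freqs, power=density * df, epoch_index=epoch_index, stage=stage)


def psds_for_hypnogram(
    rec: PsgRecording, hyp: Hypnogram, channel: str = "EEG"
) -> list[EpochPsd]:
    """One :class:`EpochPsd` per epoch of the hypnogram, for one channel."""
    out = []
    for i, (stage, chans) in enumerate(slice_epochs(rec, hyp)):
        out.append(epoch_psd(chans[channel], rec.sampling_rate, epoch_index=i, stage=stage))
    return out


def detect_artifact_epochs(
    rec: PsgRecording,
    hyp: Hypnogram,
    amp_thresh: float = 500.0,
    flat_thresh: float = 1.0,
    channel: str = "EEG",
) -> np.ndarray:
    """Boolean mask of artifact epochs (amplitude spike or flatline).

    An epoch is flagged when its peak absolute amplitude exceeds
    ``amp_thresh`` uV or its range is below ``flat_thresh`` uV; manual
    flags carried by the hypnogram are OR-ed in.
    """
    mask = np.array(hyp.artifact_flags, dtype=bool).copy()
    for i, (_stage, chans) in enumerate(slice_epochs(rec, hyp)):
        x = chans[channel]
        if np.max(np.abs(x)) > amp_thresh or (np.max(x) - np.min(x)) < flat_thresh:
            mask[i] = True
    return mask


# ----------------------------------------------------------------------
# 1-Hz aggregation


def one_hz_bins(psd: EpochPsd, max_hz: float = 35.0) -> tuple[np.ndarray, np.ndarray]:
    """Sum 0.2-Hz powers into half-open 1-Hz bins [k, k+1); DC excluded."""
    kmax = int(np.floor(max_hz))
    edges = np.arange(kmax + 1, dtype=float)
    valid = psd.frequencies > 0
    idx = np.floor(psd.frequencies[valid]).astype(int)
    keep = idx < kmax
    sums = np.bincount(idx[keep], weights=psd.power[valid][keep], minlength=kmax)
    return edges[:-1], sums


def epoch_band_matrix(
    psds: list[EpochPsd],
    stage: StageLabel | None = None,
    artifact_mask: np.ndarray | None = None,
    max_hz: float = 35.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(bin_freqs, epochs x 1-Hz-bins power matrix) for qualifying epochs."""
    rows = []
    freqs = None
    for psd in psds:
        if stage is not None and psd.stage is not stage:
            continue
        if artifact_mask is not None and artifact_mask[psd.epoch_index]:
            continue
        freqs, row = one_hz_bins(psd, max_hz=max_hz)
        rows.append(row)
    if not rows:
        raise ValueError(
            f"no qualifying epochs for stage {stage} after artifact exclusion"
        )
    return freqs, np.vstack(rows)


def stage_profile(
    psds: list[EpochPsd],
    stage: StageLabel,
    artifact_mask: np.ndarray | None = None,
    max_hz: float = 35.0,
    condition: str | None = None,
) -> SpectralProfile:
    """Mean 1-Hz-bin power with t-based 95% CI over a stage's clean epochs."""
    freqs, mat = epoch_band_matrix(psds, stage=stage, artifact_mask=artifact_mask, max_hz=max_hz)
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    if n > 1:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(n)
        ci = sem * spstats.t.ppf(0.975, df=n - 1)
    else:
        ci = np.zeros_like(mean)
    return SpectralProfile(
        bin_freqs=freqs, mean=mean, ci_half=ci, n_epochs=n, stage=stage, condition=condition
    )


def band_power(profile: SpectralProfile, lo: float, hi: float) -> float:
    """Sum of 1-Hz bin means over [lo, hi); a partial first bin (e.g. the
    0.3-1 Hz start of the delta band) is included whole."""
    sel = (profile.bin_freqs >= np.floor(lo)) & (profile.bin_freqs < hi)
    return float(profile.mean[sel].sum())


def peak_frequency(profile: SpectralProfile, lo: float, hi: float) -> float:
    """Center of the argmax 1-Hz bin within [lo, hi); ties break low."""
    sel = np.where((profile.bin_freqs >= lo) & (profile.bin_freqs < hi))[0]
    if len(sel) == 0:
        raise ValueError(f"no 1-Hz bins inside [{lo}, {hi})")
    best = sel[int(np.argmax(profile.mean[sel]))]
    return float(profile.bin_freqs[best]) + 0.5


def compare_bins(
    matrices: dict[str, np.ndarray],
    bin_freqs: np.ndarray | None = None,
    alpha: float = 0.05,
) -> BinComparison:
    """Per-1-Hz-bin one-way fixed-effects ANOVA across conditions.

    ``matrices`` maps condition name to an (epochs x bins) power matrix;
    contiguous significant bins are reported as [lo, hi) Hz intervals.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two conditions to compare")
    names = tuple(matrices)
    n_bins = next(iter(matrices.values())).shape[1]
    if bin_freqs is None:
        bin_freqs = np.arange(n_bins, dtype=float)
    f_stat = np.empty(n_bins)
    p = np.empty(n_bins)
    for b in range(n_bins):
        groups = [matrices[name][:, b] for name in names]
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            f_stat[b], p[b] = 0.0, 1.0
            continue
        f_stat[b], p[b] = spstats.f_oneway(*groups)
    sig = p <= alpha

    runs: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((float(bin_freqs[start]), float(bin_freqs[i - 1]) + 1.0))
            start = None
    if start is not None:
        runs.append((float(bin_freqs[start]), float(bin_freqs[-1]) + 1.0))

    return BinComparison(
        bin_freqs=np.asarray(bin_freqs, dtype=float),
        f_stat=f_stat, p=p, significant=sig, runs=runs, conditions=names, alpha=alpha,
    )


# ----------------------------------------------------------------------
# Rule-based auto-stager (round-trip plumbing)

#: Decision thresholds; tuned against the shipped healthy signal preset.
STAGER_THRESHOLDS = {
    "emg_active": 45.0,    # uV RMS above which wake is 'active'
    "emg_wake": 22.0,      # uV RMS above which the epoch is wake
    "emg_atonia": 9.0,     # uV RMS below which REM atonia is assumed
    "delta_frac": 0.5,     # delta share of 0.3-35 Hz power defining N3
    "spindle_share": 0.11,  # 11-16 Hz share separating N2 from N1
}


def rule_based_stager(
    rec: PsgRecording,
    epoch_length: float = 30.0,
    thresholds: dict | None = None,
) -> Hypnogram:
    """Deterministic per-epoch decision tree on EMG tone, EOG and EEG bands.

    High EMG -> active wake; moderate EMG -> quiet wake; delta-dominant ->
    N3; EMG atonia -> R; remaining light sleep split N2/N1 by the 11-16 Hz
    (spindle-band) share.  Intended for round-trip testing against the
    synthetic generator, whose stage signatures it mirrors.
    """
    th = dict(STAGER_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    fs = rec.sampling_rate
    n_per = int(round(epoch_length * fs))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")

    stages: list[StageLabel] = []
    for i in range(n_epochs):
        sl = slice(i * n_per, (i + 1) * n_per)
        eeg = rec.channels["EEG"][sl]
        emg_rms = float(np.sqrt(np.mean(rec.channels["EMG"][sl] ** 2)))
        psd = epoch_psd(eeg, fs)
        freqs, bins = one_hz_bins(psd, max_hz=35.0)
        total = bins.sum()
        delta = bins[(freqs >= 0) & (freqs < 4)].sum()
        spindle = bins[(freqs >= 11) & (freqs < 16)].sum()

        if total <= 0:
            stages.append(StageLabel.UNSCORED)
        elif emg_rms > th["emg_active"]:
            stages.append(StageLabel.A)
        elif delta / total > th["delta_frac"] and emg_rms <= th["emg_wake"]:
            stages.append(StageLabel.N3)
        elif emg_rms > th["emg_wake"]:
            stages.append(StageLabel.W)
        elif emg_rms < th["emg_atonia"]:
            stages.append(StageLabel.R)
        elif spindle / total > th["spindle_share"]:
            stages.append(StageLabel.N2)
        else:
            stages.append(StageLabel.N1)

    return Hypnogram(start_time=rec.start_time, stages=tuple(stages), epoch_length=epoch_length)
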