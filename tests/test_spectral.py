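"""Welch PSD normalization, stage profiles, per-bin ANOVA and the stager."""

import datetime as dt

import numpy as np
import pytest

from nhpsleep import Condition, PsgRecording, StageLabel, spectral as spec
from nhpsleep.hypnogram import AnalysisWindow, WindowKind
from nhpsleep.synthetic import (
    ARCHITECTURE_NIGHT,
    SIGNAL,
    generate_hypnogram,
    generate_psg,
    generate_stage_epochs,
)

from .conftest import NIGHT_START, make_hypnogram

FS = 500.0


def _sinusoid(f_hz, amp=50.0, seconds=30.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * f_hz * t)


class TestEpochPsd:
    def test_sinusoid_integrates_to_half_amplitude_squared(self):
        psd = spec.epoch_psd(_sinusoid(10.0, amp=50.0), FS)
        freqs, bins = spec.one_hz_bins(psd)
        assert bins[8:12].sum() == pytest.approx(1250.0, rel=0.05)

    def test_zero_epoch_zero_psd(self):
        psd = spec.epoch_psd(np.zeros(int(30 * FS)), FS)
        assert np.allclose(psd.power, 0.0)

    def test_white_noise_parseval(self):
        x = np.random.default_rng(0).standard_normal(int(30 * FS))
        psd = spec.epoch_psd(x, FS)
        assert psd.total_power() == pytest.approx(x.var(), rel=0.10)

    def test_too_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            spec.epoch_psd(np.zeros(int(2 * FS)), FS)

    def test_amplitude_equivariance(self):
        x = np.random.default_rng(1).standard_normal(int(30 * FS))
        p1 = spec.epoch_psd(x, FS).power
        p3 = spec.epoch_psd(3.0 * x, FS).power
        assert np.allclose(p3, 9.0 * p1, rtol=1e-9, atol=1e-12)

    def test_parseval_across_generated_stage_epochs(self):
        # property over the shipped presets
        for cond in Condition:
            for stage in (StageLabel.W, StageLabel.N3, StageLabel.R):
                ep = generate_stage_epochs(SIGNAL[cond][stage], 1, seed=hash(cond.value) % 1000)[0]
                psd = spec.epoch_psd(ep["EEG"], FS)
                assert psd.total_power() == pytest.approx(ep["EEG"].var(), rel=0.10)


class TestArtifacts:
    def _rec_with_epochs(self, epochs):
        eeg = np.concatenate(epochs)
        n = len(eeg)
        return PsgRecording(
            channels={"EEG": eeg, "EOG": np.zeros(n), "EMG": np.zeros(n)},
            sampling_rate=250.0,
            start_time=NIGHT_START,
        )

    def test_spike_flatline_and_clean(self):
        rng = np.random.default_rng(0)
        clean = rng.normal(0, 20, 7500)
        spike = clean.copy()
        spike[1000] = 2000.0
        flat = np.zeros(7500)
        rec = self._rec_with_epochs([clean, spike, flat])
        hyp = make_hypnogram(["N3", "N3", "N3"])
        mask = spec.detect_artifact_epochs(rec, hyp, amp_thresh=500.0, flat_thresh=1.0)
        assert list(mask) == [False, True, True]

    def test_manual_flags_unioned(self):
        rng = np.random.default_rng(0)
        rec = self._rec_with_epochs([rng.normal(0, 20, 7500)] * 2)
        from nhpsleep import Hypnogram, LightsSchedule

        hyp = Hypnogram(
            start_time=NIGHT_START,
            stages=(StageLabel.N3, StageLabel.N3),
            artifact_flags=(True, False),
        )
        mask = spec.detect_artifact_epochs(rec, hyp)
        assert list(mask) == [True, False]


class TestStageProfile:
    def _psds(self, epochs, stage):
        return [
            spec.epoch_psd(e, FS, epoch_index=i, stage=stage)
            for i, e in enumerate(epochs)
        ]

    def test_identical_epochs_zero_ci(self):
        x = _sinusoid(6.0)
        profile = spec.stage_profile(self._psds([x] * 10, StageLabel.N2), StageLabel.N2)
        assert np.allclose(profile.ci_half, 0.0)
        assert profile.n_epochs == 10

    def test_synthetic_n3_delta_dominates(self):
        eps = generate_stage_epochs(SIGNAL[Condition.HEALTHY][StageLabel.N3], 10, seed=4)
        profile = spec.stage_profile(
            self._psds([e["EEG"] for e in eps], StageLabel.N3), StageLabel.N3
        )
        delta_max = profile.mean[(profile.bin_freqs >= 1) & (profile.bin_freqs < 4)].max()
        assert np.all(delta_max > profile.mean[profile.bin_freqs >= 8])

    def test_empty_selection_raises(self):
        x = _sinusoid(6.0)
        psds = self._psds([x] * 3, StageLabel.N2)
        with pytest.raises(ValueError, match="no qualifying"):
            spec.stage_profile(psds, StageLabel.N2, artifact_mask=np.ones(3, bool))

    def test_white_noise_profile_is_flat(self):
        rng = np.random.default_rng(2)
        psds = self._psds([rng.standard_normal(int(30 * FS)) for _ in range(100)],
                          StageLabel.W)
        profile = spec.stage_profile(psds, StageLabel.W)
        inner = profile.mean[1:]  # first bin lacks its DC-adjacent share
        assert inner.max() / inner.min() < 2.0


class TestBandsAndPeaks:
    def _profile(self, x):
        psd = spec.epoch_psd(x, FS, stage=StageLabel.W)
        return spec.stage_profile([psd], StageLabel.W)

    def test_band_power_selects_band(self):
        profile = self._profile(_sinusoid(10.0, amp=50.0))
        assert spec.band_power(profile, 8, 12) == pytest.approx(1250.0, rel=0.05)
        assert spec.band_power(profile, 0.3, 4.0) < 5.0

    def test_band_partition_conserves_total(self):
        profile = self._profile(np.random.default_rng(3).standard_normal(int(30 * FS)))
        total = profile.mean.sum()
        parts = sum(spec.band_power(profile, lo, hi)
                    for lo, hi in ((0.3, 4), (4, 8), (8, 12), (12, 13), (13, 35)))
        assert parts == pytest.approx(total, rel=1e-9)

    def test_peak_frequency_injected_component(self):
        profile = self._profile(_sinusoid(20.0))
        assert spec.peak_frequency(profile, 12, 35) == 20.5

    def test_flat_profile_tie_breaks_low(self):
        flat = spec.SpectralProfile(
            bin_freqs=np.arange(35.0), mean=np.ones(35), ci_half=np.zeros(35),
            n_epochs=2, stage=StageLabel.W,
        )
        assert spec.peak_frequency(flat, 12, 35) == 12.5


class TestCompareBins:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, size=(30, 10))
        comp = spec.compare_bins({"a": base, "b": base.copy(), "c": base.copy()})
        assert not comp.significant.any()
        assert comp.runs == []

    def test_delta_only_difference_confined_to_low_bins(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10, 1, size=(40, 12))
        b = rng.normal(10, 1, size=(40, 12))
        b[:, :4] += 5.0  # boost bins 0-3 only
        comp = spec.compare_bins({"a": a, "b": b})
        assert comp.significant[:4].all()
        assert not comp.significant[5:].any()
        assert all(hi <= 5.0 for _, hi in comp.runs)

    def test_f_matches_closed_form(self):
        # brute-force F from group means/variances on a 3x10 toy matrix
        rng = np.random.default_rng(2)
        mats = {name: rng.normal(loc, 1, size=(10, 3))
                for name, loc in (("a", 0.0), ("b", 0.5), ("c", 1.5))}
        comp = spec.compare_bins(mats)
        for bin_i in range(3):
            groups = [mats[k][:, bin_i] for k in mats]
            ns = [len(g) for g in groups]
            grand = np.concatenate(groups).mean()
            ssb = sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups))
            ssw = sum((n - 1) * g.var(ddof=1) for n, g in zip(ns, groups))
            f_ref = (ssb / 2) / (ssw / (sum(ns) - 3))
            assert comp.f_stat[bin_i] == pytest.approx(f_ref, abs=1e-10)

    def test_null_type_one_error_rate(self):
        # 3 identical-distribution groups, n=30 epochs, 200 replicates:
        # per-bin rejection rate at alpha=0.05 should sit near 0.05
        rng = np.random.default_rng(42)
        n_bins, rejections, total = 20, 0, 0
        for _ in range(200):
            mats = {name: rng.normal(0, 1, size=(30, n_bins)) for name in "abc"}
            comp = spec.compare_bins(mats)
            rejections += int(comp.significant.sum())
            total += n_bins
        rate = rejections / total
        assert 0.02 <= rate <= 0.09


class TestRuleBasedStager:
    def test_round_trip_agreement_on_healthy_night(self, two_hour_window):
        hyp = generate_hypnogram(
            ARCHITECTURE_NIGHT[Condition.HEALTHY], two_hour_window, seed=11
        )
        rec = generate_psg(hyp, SIGNAL[Condition.HEALTHY], fs=250.0, seed=12)
        guess = spec.rule_based_stager(rec)
        agreement = np.mean([a is b for a, b in zip(hyp.stages, guess.stages)])
        assert agreement >= 0.80

    def test_high_emg_epochs_stage_as_active_wake(self):
        rng = np.random.default_rng(0)
        n = int(30 * 250)
        rec = PsgRecording(
            channels={"EEG": rng.normal(0, 5, n), "EOG": np.zeros(n),
                      "EMG": rng.normal(0, 90, n)},
            sampling_rate=250.0, start_time=NIGHT_START,
        )
        assert spec.rule_based_stager(rec).stages == (StageLabel.A,)

    def test_delta_epochs_with_low_emg_stage_as_n3(self):
        eps = generate_stage_epochs(SIGNAL[Condition.HEALTHY][StageLabel.N3], 2,
                                    fs=250.0, seed=5)
        eeg = np.concatenate([e["EEG"] for e in eps])
        n = len(eeg)
        rec = PsgRecording(
            channels={"EEG": eeg, "EOG": np.zeros(n),
                      "EMG": np.random.default_rng(1).normal(0, 10, n)},
            sampling_rate=250.0, start_time=NIGHT_START,
        )
        assert spec.rule_based_stager(rec).stages == (StageLabel.N3, StageLabel.N3)
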