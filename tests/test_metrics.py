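"""Sleep-architecture metrics: worked examples, identities and oracle
equivalence against a brute-force epoch recount."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nhpsleep import AnalysisWindow, StageLabel, metrics as met
from nhpsleep.hypnogram import WindowKind

from .conftest import NIGHT_START, make_hypnogram, random_hypnogram


class TestSleepLatency:
    def test_three_wake_epochs_give_90_seconds(self, make_hyp):
        hyp = make_hyp(["W", "W", "W", "N1", "N2"])
        assert met.sleep_latency(hyp) == pytest.approx(1.5)

    def test_immediate_sleep_gives_zero(self, make_hyp):
        assert met.sleep_latency(make_hyp(["N1", "N2"])) == 0.0

    def test_all_wake_is_undefined_not_zero(self, make_hyp):
        assert met.sleep_latency(make_hyp(["W"] * 10)) is None

    def test_missing_lights_off_raises(self, make_hyp):
        import datetime as dt
        from nhpsleep import Hypnogram, LightsSchedule

        # lights-on-only schedule: no off event to anchor the latency
        lights = LightsSchedule(((NIGHT_START + dt.timedelta(hours=13), "off"),))
        hyp = Hypnogram(start_time=NIGHT_START,
                        stages=(StageLabel.W, StageLabel.N1), lights=lights)
        with pytest.raises(ValueError, match="lights-off"):
            met.sleep_latency(hyp)


class TestTstWasoEfficiency:
    def test_tst_counts_sleep_epochs(self, make_hyp):
        hyp = make_hyp(["W"] * 4 + ["N2"] * 80 + ["W"] * 36)
        assert met.total_sleep_time(hyp) == 40.0

    def test_all_wake_tst_zero(self, make_hyp):
        assert met.total_sleep_time(make_hyp(["A"] * 20)) == 0.0

    def test_all_n3_hour(self, make_hyp):
        assert met.total_sleep_time(make_hyp(["N3"] * 120)) == 60.0

    def test_waso_worked_example(self, make_hyp):
        # 60-min window, SL 1.5 min, TST 40 min -> WASO = 58.5 - 40 = 18.5
        hyp = make_hyp(["W"] * 3 + ["N2"] * 80 + ["W"] * 37)
        assert met.sleep_latency(hyp) == 1.5
        assert met.total_sleep_time(hyp) == 40.0
        assert met.waso(hyp) == pytest.approx(18.5)
        assert met.sleep_efficiency(hyp) == pytest.approx(100 * 40 / 58.5)

    def test_sleep_filling_window_has_zero_waso(self, make_hyp):
        hyp = make_hyp(["W", "W", "N3", "N3", "R"])
        assert met.waso(hyp) == 0.0
        assert met.sleep_efficiency(hyp) == 100.0

    def test_published_means_reproduce_efficiency(self):
        # TST 523.1 / WASO 182.3 are the published healthy-state means
        assert round(met.efficiency_from_tst_waso(523.1, 182.3), 1) == 74.2
        assert round(met.efficiency_from_tst_waso(589.4, 120.1), 1) == 83.1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_sl_tst_waso_conservation(self, seed):
        # SL + TST + WASO = scored window duration whenever sleep occurs
        hyp = random_hypnogram(np.random.default_rng(seed), n_epochs=48)
        if met.sleep_latency(hyp) is None:
            return
        total = met.sleep_latency(hyp) + met.total_sleep_time(hyp) + met.waso(hyp)
        assert total == pytest.approx(hyp.duration_s / 60.0)


class TestStagePercentages:
    def test_equal_sixths(self, make_hyp):
        tokens = ["A", "W", "N1", "N2", "N3", "R"] * 10
        pct = met.stage_percentages(make_hyp(tokens))
        for v in pct.values():
            assert v == pytest.approx(100 / 6)

    def test_all_rem(self, make_hyp):
        pct = met.stage_percentages(make_hyp(["R"] * 8))
        assert pct[StageLabel.R] == 100.0
        assert sum(v for k, v in pct.items() if k is not StageLabel.R) == 0.0

    def test_unscored_excluded_from_denominator(self, make_hyp):
        pct = met.stage_percentages(make_hyp(["N3", "N3", "UNSCORED", "W"]))
        assert pct[StageLabel.N3] == pytest.approx(200 / 3)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_normalization_to_100(self, seed):
        hyp = random_hypnogram(np.random.default_rng(seed))
        assert sum(met.stage_percentages(hyp).values()) == pytest.approx(100.0, abs=1e-9)

    def test_n3_percent_of_tst(self, make_hyp):
        hyp = make_hyp(["N3"] * 40 + ["N1"] * 40)
        assert met.n3_percent_of_tst(hyp) == 50.0
        assert met.n3_percent_of_tst(make_hyp(["N1"] * 4)) == 0.0
        assert met.n3_percent_of_tst(make_hyp(["N3"] * 4)) == 100.0
        assert met.n3_percent_of_tst(make_hyp(["W"] * 4)) is None


class TestTransitions:
    def test_alternating_worked_example(self, make_hyp):
        # [W,N1,W,N1] over 2 min: 3 boundary crossings -> 90/h
        assert met.transitions_per_hour(make_hyp(["W", "N1", "W", "N1"])) == pytest.approx(90.0)

    def test_constant_stage_zero(self, make_hyp):
        assert met.transitions_per_hour(make_hyp(["N2"] * 100)) == 0.0

    def test_reversal_symmetry(self, make_hyp):
        tokens = ["W", "W", "N1", "N2", "W", "N3", "R", "A"]
        fwd = met.transitions_per_hour(make_hyp(tokens))
        rev = met.transitions_per_hour(make_hyp(tokens[::-1]))
        assert fwd == rev

    def test_within_group_changes_not_counted_by_default(self, make_hyp):
        hyp = make_hyp(["A", "W", "A", "W"])  # all wake: no group crossing
        assert met.transitions_per_hour(hyp) == 0.0
        assert met.transitions_per_hour(hyp, all_boundaries=True) == pytest.approx(90.0)


class TestSleepCycles:
    def test_three_canonical_cycles(self, make_hyp):
        # each cycle: 20 N2 epochs (10 min) then 4 R epochs, separated by wake
        cycle = ["N2"] * 20 + ["R"] * 4 + ["W"] * 12
        hyp = make_hyp(cycle * 3)
        assert met.count_sleep_cycles(hyp) == 3

    def test_no_rem_no_cycles(self, make_hyp):
        hyp = make_hyp((["N2"] * 30 + ["N3"] * 30) * 4)
        assert met.count_sleep_cycles(hyp) == 0

    def test_insufficient_nrem_not_counted(self, make_hyp):
        hyp = make_hyp(["N2"] * 10 + ["R"] * 4)  # only 5 min of N2
        assert met.count_sleep_cycles(hyp) == 0

    def test_brief_non_rem_gap_does_not_split_episode(self, make_hyp):
        # two R runs separated by < 5 min of N1 form one episode -> one cycle
        hyp = make_hyp(["N2"] * 20 + ["R"] * 2 + ["N1"] * 4 + ["R"] * 2)
        assert met.count_sleep_cycles(hyp) == 1

    def test_invalid_parameters_rejected(self, make_hyp):
        with pytest.raises(ValueError):
            met.count_sleep_cycles(make_hyp(["N2"] * 4), min_nrem=0)


class TestDaytime:
    def test_first_sleep_after_wake(self, make_hyp):
        hyp = make_hyp(["A"] * 20 + ["N1", "N2"] + ["A"] * 20)
        assert met.first_sleep_after_wake(hyp) == 10.0

    def test_all_wake_day_has_no_naps(self, make_hyp):
        summary, naps = met.daytime_summary(make_hyp(["A"] * 100))
        assert naps == []
        assert summary.tst == 0.0

    def test_three_disjoint_naps(self, make_hyp):
        nap = ["N1"] * 10 + ["N2"] * 50
        gap = ["A"] * 20  # 10-min wake gaps
        hyp = make_hyp(["A"] * 10 + nap + gap + nap + gap + nap)
        _, naps = met.daytime_summary(hyp)
        assert len(naps) == 3
        assert all(n.duration_min == 30.0 for n in naps)

    def test_brief_awakening_merges_nap(self, make_hyp):
        # 2-min wake gap (< 2.5-min tolerance) keeps one nap together
        hyp = make_hyp(["N2"] * 20 + ["W"] * 4 + ["N2"] * 20)
        _, naps = met.daytime_summary(hyp)
        assert len(naps) == 1
        assert naps[0].duration_min == 22.0
        assert naps[0].composition_min[StageLabel.W] == 2.0

    def test_nap_composition_sums_to_duration(self, make_hyp):
        hyp = make_hyp(["N1"] * 6 + ["N3"] * 10 + ["R"] * 4)
        _, naps = met.daytime_summary(hyp)
        (nap,) = naps
        assert sum(nap.composition_min.values()) == pytest.approx(nap.duration_min)


class TestDayNightProportion:
    def _summary(self, tst, make):
        hyp = make(["N2"] * max(int(tst * 2), 1) + ["W"])
        return met.night_summary(hyp)

    def test_no_day_sleep(self, make_hyp):
        day = self._summary(0.0, make_hyp)
        night = self._summary(250.0, make_hyp)
        day = met.SleepSummary(**{**day.__dict__, "tst": 0.0})
        assert met.day_night_proportion(day, night) == (0.0, 100.0)

    def test_published_day_night_split(self, make_hyp):
        # day TST 107.4 / night TST 523.1 -> (17.0, 83.0)
        day = self._summary(107.4, make_hyp)
        night = self._summary(523.1, make_hyp)
        pct_day, pct_night = met.day_night_proportion(day, night)
        assert round(pct_day, 1) == 17.0
        assert round(pct_night, 1) == 83.0
        assert pct_day + pct_night == 100.0

    def test_equal_split(self, make_hyp):
        s = self._summary(60.0, make_hyp)
        assert met.day_night_proportion(s, s) == (50.0, 50.0)


class TestActimetryProfile:
    def _window(self, minutes):
        import datetime as dt

        return AnalysisWindow(NIGHT_START, NIGHT_START + dt.timedelta(minutes=minutes),
                              WindowKind.DAY)

    def test_constant_bins(self):
        out = met.actimetry_profile(np.full(360, 5), self._window(60))
        assert len(out) == 60
        assert np.all(out == 30)

    def test_all_zero(self):
        assert np.all(met.actimetry_profile(np.zeros(360), self._window(60)) == 0)

    def test_insufficient_bins_raise(self):
        with pytest.raises(ValueError):
            met.actimetry_profile(np.zeros(10), self._window(60))


class TestOracleEquivalence:
    """Every metric equals an independent brute-force epoch recount."""

    @staticmethod
    def _brute_force(hyp):
        L = hyp.epoch_length / 60.0
        stages = list(hyp.stages)
        sleep = {StageLabel.N1, StageLabel.N2, StageLabel.N3, StageLabel.R}
        onset = next((i for i, s in enumerate(stages) if s in sleep), None)
        tst = sum(1 for s in stages if s in sleep) * L
        spt = (len(stages) - onset) * L if onset is not None else 0.0
        trans = sum(
            1 for a, b in zip(stages, stages[1:])
            if (a in sleep) != (b in sleep)
        )
        hours = len(stages) * L / 60.0
        return {
            "sl": None if onset is None else onset * L,
            "tst": tst,
            "waso": spt - tst,
            "eff": None if spt == 0 else 100.0 * tst / spt,
            "trans": trans / hours,
        }

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_metrics_match_recount(self, seed):
        hyp = random_hypnogram(np.random.default_rng(seed), n_epochs=50)
        ref = self._brute_force(hyp)
        assert met.sleep_latency(hyp) == ref["sl"]
        assert met.total_sleep_time(hyp) == ref["tst"]
        assert met.waso(hyp) == pytest.approx(ref["waso"])
        if ref["eff"] is None:
            assert met.sleep_efficiency(hyp) is None
        else:
            assert met.sleep_efficiency(hyp) == pytest.approx(ref["eff"])
        assert met.transitions_per_hour(hyp) == pytest.approx(ref["trans"])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_efficiency_invariant_to_within_group_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        hyp = random_hypnogram(rng, n_epochs=50)
        remap = {
            StageLabel.A: StageLabel.W, StageLabel.W: StageLabel.A,
            StageLabel.N1: StageLabel.N3, StageLabel.N2: StageLabel.R,
            StageLabel.N3: StageLabel.N2, StageLabel.R: StageLabel.N1,
        }
        relabeled = make_hypnogram([remap[s].value for s in hyp.stages])
        assert met.sleep_efficiency(hyp) == met.sleep_efficiency(relabeled)
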