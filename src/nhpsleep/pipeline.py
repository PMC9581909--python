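"""End-to-end synthetic study runner.

Generates a three-condition cohort (healthy / presymptomatic /
symptomatic) of nights, days and mMSLT test days with the shipped
presets, runs every analysis stage, and writes the summary tables a
polysomnographic study reports: per-recording night and day architecture
rows, the mMSLT latency table, stage-conditioned spectral profiles with
per-bin condition comparisons, REM-sleep HRV summaries, and a statistics
table with Kruskal-Wallis/Dunn markers per metric.

Everything is deterministic per (config, seed): per-recording seeds are
drawn from one root generator.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import hrv as hrvmod
from . import metrics as met
from . import mslt as msltmod
from . import spectral as spec
from .stages import Condition, StageLabel
from .stats import GroupedSamples, kruskal_dunn
from .synthetic import (
    ARCHITECTURE_DAY,
    ARCHITECTURE_NIGHT,
    MSLT,
    RR,
    SIGNAL,
    day_window,
    generate_hypnogram,
    generate_mslt_day,
    generate_rr,
    generate_stage_epochs,
    night_window,
)

log = logging.getLogger("nhpsleep")

#: Table-row order for the architecture metrics.
NIGHT_METRICS = [
    "sl", "pct_A", "pct_W", "pct_N1", "pct_N2", "pct_N3", "pct_R",
    "tst", "waso", "sleep_efficiency", "sleep_cycles", "transitions_per_hour",
]


@dataclasses.dataclass
class StudyConfig:
    """Cohort sizes and analysis options for one synthetic study run."""

    conditions: tuple[Condition, ...] = (
        Condition.HEALTHY, Condition.PRESYMPTOMATIC, Condition.SYMPTOMATIC
    )
    nights_per_condition: int = 10
    days_per_condition: int = 10
    mslt_days_per_condition: int = 10
    spectra_epochs_per_stage: int = 30
    spectra_stages: tuple[StageLabel, ...] = (StageLabel.A, StageLabel.N3)
    hrv_windows: int = 12
    hrv_span_s: float = 120.0
    sampling_rate: float = 500.0
    seed: int = 0
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if min(self.nights_per_condition, self.days_per_condition,
               self.mslt_days_per_condition) < 1:
            raise ValueError("need at least one recording per condition")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        """Load a config from a YAML mapping of the dataclass fields.

        ``conditions`` may be given as names (e.g. ``[healthy, symptomatic]``)
        and ``spectra_stages`` as stage tokens (e.g. ``[A, N3]``).
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "conditions" in raw:
            raw["conditions"] = tuple(Condition(c) for c in raw["conditions"])
        if "spectra_stages" in raw:
            raw["spectra_stages"] = tuple(StageLabel(s) for s in raw["spectra_stages"])
        if "out_dir" in raw and raw["out_dir"] is not None:
            raw["out_dir"] = Path(raw["out_dir"])
        return cls(**raw)


def _summary_row(s: met.SleepSummary) -> dict:
    row = {"sl": s.sl, "tst": s.tst, "waso": s.waso,
           "sleep_efficiency": s.sleep_efficiency,
           "sleep_cycles": s.sleep_cycles,
           "transitions_per_hour": s.transitions_per_hour}
    for stage in (StageLabel.A, StageLabel.W, StageLabel.N1,
                  StageLabel.N2, StageLabel.N3, StageLabel.R):
        row[f"pct_{stage.value}"] = s.stage_pct[stage]
    return row


def _with_mean_sem(df: pd.DataFrame, group_cols: list[str]) -> pd.DataFrame:
    numeric = df.select_dtypes("number").columns.difference(["recording"])
    rows = [df]
    for label, agg in (("mean", "mean"), ("sem", "sem")):
        stat = df.groupby(group_cols, sort=False)[list(numeric)].agg(agg).reset_index()
        stat["recording"] = label
        rows.append(stat)
    return pd.concat(rows, ignore_index=True)


def run_study(config: StudyConfig) -> dict:
    """Run the full synthetic study; returns the result tables in memory
    and writes TSVs to ``config.out_dir`` if set."""
    rng = np.random.default_rng(config.seed)

    def child_seed() -> int:
        return int(rng.integers(2**31))

    night_rows, day_rows, nap_rows, mslt_rows, hrv_rows = [], [], [], [], []
    spectra_frames = []
    matrices: dict[StageLabel, dict[str, np.ndarray]] = {
        st: {} for st in config.spectra_stages
    }

    for cond in config.conditions:
        log.info("condition %s: simulating %d nights / %d days / %d mMSLT days",
                 cond, config.nights_per_condition, config.days_per_condition,
                 config.mslt_days_per_condition)
        # Nights -------------------------------------------------------
        for i in range(config.nights_per_condition):
            hyp = generate_hypnogram(ARCHITECTURE_NIGHT[cond], night_window(), seed=child_seed())
            row = _summary_row(met.night_summary(hyp))
            row.update(condition=str(cond), recording=f"night{i:02d}")
            night_rows.append(row)
        # Days ---------------------------------------------------------
        for i in range(config.days_per_condition):
            hyp = generate_hypnogram(ARCHITECTURE_DAY[cond], day_window(), seed=child_seed())
            summary, naps = met.daytime_summary(hyp)
            row = _summary_row(summary)
            row.update(condition=str(cond), recording=f"day{i:02d}", n_naps=len(naps))
            day_rows.append(row)
            for j, nap in enumerate(naps):
                nap_rows.append({
                    "condition": str(cond), "recording": f"day{i:02d}", "nap": j,
                    "start": nap.start.isoformat(), "duration_min": nap.duration_min,
                    **{f"min_{st.value}": v for st, v in nap.composition_min.items()},
                })
        # mMSLT --------------------------------------------------------
        preset = MSLT[cond]
        days = [
            generate_mslt_day(preset.latency_mean_min, preset.latency_sd_min,
                              preset.sleep_run_min, seed=child_seed(),
                              stage_mix=preset.stage_mix)
            for _ in range(config.mslt_days_per_condition)
        ]
        summary = msltmod.mslt_summarize(days)
        for scope, cell in [("pooled", summary["pooled"])] + [
            (f"session{i}", s) for i, s in summary["by_session"].items()
        ]:
            mslt_rows.append({
                "condition": str(cond), "scope": scope, "n": cell["n"],
                "sl_mean": cell["sl"][0], "sl_sem": cell["sl"][1],
                "wake_mean": cell["wake_min"][0], "n12_mean": cell["n12_min"][0],
                "n3_mean": cell["n3_min"][0], "rem_mean": cell["rem_min"][0],
                "rem_intrusions": cell["rem_intrusions"],
            })
        # Spectra ------------------------------------------------------
        for stage in config.spectra_stages:
            epochs = generate_stage_epochs(
                SIGNAL[cond][stage], config.spectra_epochs_per_stage,
                fs=config.sampling_rate, seed=child_seed(),
            )
            psds = [
                spec.epoch_psd(ep["EEG"], config.sampling_rate, epoch_index=i, stage=stage)
                for i, ep in enumerate(epochs)
            ]
            freqs, mat = spec.epoch_band_matrix(psds, stage=stage)
            matrices[stage][str(cond)] = mat
            profile = spec.stage_profile(psds, stage, condition=str(cond))
            spectra_frames.append(pd.DataFrame({
                "condition": str(cond), "stage": stage.value,
                "bin_hz": profile.bin_freqs, "mean_uv2": profile.mean,
                "ci95_half": profile.ci_half, "n_epochs": profile.n_epochs,
            }))
        # HRV ----------------------------------------------------------
        per_epoch = [
            generate_rr(RR[cond], seed=child_seed())
            for _ in range(config.hrv_windows)
        ]
        series = hrvmod.rr_series_from_intervals(per_epoch)
        hs = hrvmod.hrv_summary(series)
        hrv_rows.append({
            "condition": str(cond), "mean_nn_s": hs.mean_nn, "std_nn_s": hs.std_nn,
            "cv_pct": hs.cv, "n_intervals": hs.n_intervals,
        })

    night_df = pd.DataFrame(night_rows)
    day_df = pd.DataFrame(day_rows)

    # Statistics across conditions ------------------------------------
    stat_rows = []
    marker = {str(Condition.HEALTHY): "*", str(Condition.PRESYMPTOMATIC): "#"}
    for table, which in ((night_df, "night"), (day_df, "day")):
        for metric in NIGHT_METRICS:
            groups = {
                str(c): table.loc[table.condition == str(c), metric].dropna().to_numpy()
                for c in config.conditions
            }
            groups = {k: v for k, v in groups.items() if len(v) > 0}
            if len(groups) < 2:
                continue
            res = kruskal_dunn(GroupedSamples(groups, metric=metric))
            annot = "".join(
                marker.get(pr.pair[0], "") if pr.significant else ""
                for pr in res.pairwise
            )
            stat_rows.append({
                "window": which, "metric": metric, "H": res.statistic, "p": res.p,
                **{f"p_{pr.pair[0]}_vs_{pr.pair[1]}": pr.p_adjusted for pr in res.pairwise},
                "markers": annot,
            })
    stats_df = pd.DataFrame(stat_rows)

    comparisons = {}
    for stage in config.spectra_stages:
        if len(matrices[stage]) >= 2:
            comparisons[stage] = spec.compare_bins(
                matrices[stage], bin_freqs=np.arange(35, dtype=float)
            )

    out = {
        "night": _with_mean_sem(night_df, ["condition"]),
        "day": _with_mean_sem(day_df, ["condition"]),
        "naps": pd.DataFrame(nap_rows),
        "mslt": pd.DataFrame(mslt_rows),
        "spectra": pd.concat(spectra_frames, ignore_index=True),
        "hrv": pd.DataFrame(hrv_rows),
        "stats": stats_df,
        "spectral_comparisons": comparisons,
    }

    if config.out_dir is not None:
        outdir = Path(config.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("night", "day", "naps", "mslt", "spectra", "hrv", "stats"):
            df = out[name]
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
        comp_rows = []
        for stage, comp in comparisons.items():
            for b in range(len(comp.bin_freqs)):
                comp_rows.append({
                    "stage": stage.value, "bin_hz": comp.bin_freqs[b],
                    "F": comp.f_stat[b], "p": comp.p[b],
                    "significant": bool(comp.significant[b]),
                })
        pd.DataFrame(comp_rows).to_csv(outdir / "spectral_comparison.tsv",
                                       sep="\t", index=False, float_format="%.6g")
        (outdir / "run_log.txt").write_text(
            f"nhpsleep study run\nseed: {config.seed}\n"
            f"generated: {dt.datetime.now().isoformat()}\n"
            f"nights/days/mslt per condition: {config.nights_per_condition}/"
            f"{config.days_per_condition}/{config.mslt_days_per_condition}\n"
        )
    return out
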