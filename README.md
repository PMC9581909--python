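# nhpsleep

Sleep/wake analysis for non-human primate polysomnography, built around the
progressive (chronic low-dose MPTP) macaque model of Parkinson's disease.
Parkinsonian patients — and parkinsonian macaques — develop sleep/wake
disturbances early, often before motor signs: lighter and less stable deep
sleep, fragmented nights, and excessive daytime sleepiness.  Characterizing
those disturbances quantitatively requires a full polysomnographic pipeline,
and that pipeline is what this package provides, for researchers analyzing
telemetric EEG/EOG/EMG recordings scored in 30-s epochs (stages A, W, N1,
N2, N3, R).

The package covers five analysis stages plus the synthetic data needed to
test all of them without animal recordings:

- **Sleep architecture** (`nhpsleep.metrics`) — from a hypnogram: sleep
  latency SL, total sleep time TST, wake after sleep onset
  WASO = SPT − TST (SPT runs from sleep onset to the end of the 12-h
  window), sleep efficiency 100·TST/SPT, per-stage percentages of total
  scoring time, N3 as % of TST, wake↔sleep transitions per hour, sleep
  cycles (≥10 min of N2/N3 followed by a REM episode), daytime naps and
  the day/night split of 24-h TST.
- **Modified multiple sleep latency test** (`nhpsleep.mslt`) — three 20-min
  lights-OFF sessions per day; SL measured to the first 30-s sleep epoch
  and censored at 20 min when no sleep occurs; stage durations with A+W and
  N1+N2 pooled; REM inside a session flagged as a sleep-attack-like event.
- **Stage-conditioned spectra** (`nhpsleep.spectral`) — per-epoch Welch PSD
  (Hamming 5-s segments, 50% overlap) reported as absolute integrated power
  (µV²), aggregated into 1-Hz bins with t-based 95% CIs, artifact-epoch
  exclusion, band powers (δ 0.3–4, θ 4–8, α 8–12, β 13–35 Hz), peak
  localization, and a per-1-Hz-bin one-way ANOVA across disease states.
- **REM-sleep heart-rate variability** (`nhpsleep.hrv`) — the neck EMG
  carries the cardiac R wave; 12 randomly sampled 2-min REM windows are
  beat-detected (adaptive robust threshold, 250-ms refractory) and
  summarized as meanNN, StdNN, CV = 100·StdNN/meanNN and Poincaré pairs
  (RRₙ, RRₙ₊₁).
- **Statistics** (`nhpsleep.stats`) — Shapiro–Wilk, Kruskal–Wallis with
  tie correction followed by Dunn's Bonferroni-adjusted pairwise z tests,
  exact/asymptotic Mann–Whitney, one-way ANOVA, mean ± SEM summaries.

The synthetic module (`nhpsleep.synthetic`) is first-class: a semi-Markov
hypnogram generator (geometric bout lengths, stage-transition propensities,
time-of-night modulation that front-loads N3 and back-loads REM, a
fragmentation scalar), a stage-locked signal synthesizer (band-limited
Gaussian EEG matched to per-stage band powers, EMG tone with embedded
cardiac R-peak trains, EOG bursts), an AR(1) RR-interval generator, mMSLT
day and actimetry generators.  Three shipped presets (healthy,
presymptomatic, symptomatic) are calibrated so seeded cohorts reproduce the
published group-level summary statistics of the macaque study.

## Worked example

```bash
python examples/01_simulate_and_score_night.py
```

```
epochs scored:        1440
sleep latency:        15.0 min   (lights-off to first sleep epoch)
total sleep time:     544.0 min
WASO:                 161.0 min   (wake after sleep onset)
sleep efficiency:     77.2 %    (100*TST/SPT)
sleep cycles:         12        (NREM->REM alternations)
transitions:          8.1 /h   (wake<->sleep boundary)
stage % of scoring time: A:15.8  W:8.6  N1:14.4  N2:21.8  N3:28.3  R:11.0
```

One seeded healthy night: efficiency near the published healthy mean
(74.2%), ~11–12 NREM→REM cycles, and a quarter of scoring time in deep
sleep.  `examples/04_rem_hrv.py` pushes synthetic REM EMG through peak
detection and prints, per condition, meanNN/CV pairs within a whisker of
the generator parameters (healthy 0.799 s / 14.42%, presymptomatic
0.793 s / 22.23%, symptomatic 0.686 s / 15.61%); `examples/06_full_study.py`
runs the whole three-condition study and writes its tables.

A thin CLI mirrors the library: `nhpsleep simulate|metrics|mslt|spectra|hrv|compare|study`
(see `nhpsleep --help`).

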