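# Methods

This note documents the models, conventions and numerical choices behind
`nhpsleep`, and what the synthetic generator does and does not emulate.

## Scoring conventions

Epochs are 30 s and half-open: epoch *i* covers
[start + i·L, start + (i+1)·L).  Every latency (nighttime SL, daytime
first-sleep-after-wake, mMSLT session latency) is measured to the *start*
of the first qualifying epoch, matching the granularity of epoch-based
scoring.  `UNSCORED` epochs are excluded from all "total scoring time"
denominators.  Stage groups are wake = {A, W} and sleep = {N1, N2, N3, R}.

Sleep period time (SPT) runs from sleep onset to the end of the analysis
window, not to the final awakening.  This choice is forced by the
arithmetic of the summary statistics the package is calibrated against
(SL + TST + WASO must reconstruct the 720-min window), and it makes
SL + TST + WASO = scored window duration an exact identity whenever any
sleep occurs — a property the tests exercise on random hypnograms.

**Transitions.** "Wake↔sleep transitions per hour" counts adjacent-epoch
crossings of the wake/sleep *group* boundary only; changes within a group
(A↔W, N2↔N3) are not transitions under the default rule.  An
`all_boundaries=True` flag switches to counting every stage change, since
published transition counts do not always state which convention they use.

**Sleep cycles.** No standard macaque cycle definition exists, so the
counter is an adapted Feinberg–Floyd rule with macaque-scaled defaults: a
completed cycle requires ≥ `min_nrem` = 10 min of accumulated N2/N3
followed by a REM episode of ≥ 1 epoch, the episode ending once
`rem_gap_end` = 5 min of non-R elapse.  Macaque sleep is polyphasic —
healthy nights carry ~25% wake — so by default brief awakenings do *not*
reset the NREM accumulator (a `wake_break_min` parameter restores a strict
run-break rule).  With the tolerant default, the healthy preset recovers
~11 cycles per night; with a strict 5-min wake break it loses roughly two
cycles per night to ordinary wake intrusions.

**Naps.** A daytime nap is a maximal sleep run tolerating internal wake
gaps < `nap_gap` = 2.5 min, kept when its total sleep time is ≥
`nap_min` = 5 min.  The nap span includes internal brief awakenings, and
the per-stage composition therefore sums to the span duration.  These two
boundary parameters are design choices (published nap descriptions give
durations, not boundary rules) and both are exposed.

## mMSLT

Sessions are exactly 40 epochs (20 min).  Latency is censored at 20 min —
SL = 20 if and only if the session contains no sleep epoch — and censored
sessions contribute their 20 min to group means by default
(`censored_as_20=False` drops them instead, survival-style).  The session
is analyzed over its full 20 min regardless of when sleep starts, so the
four pooled durations (A+W, N1+N2, N3, R) always sum to 20 min.  Any REM
inside a session is flagged as a REM intrusion (sleep-attack marker).

## Spectral analysis

Per-epoch PSDs are Welch estimates: Hamming-windowed 5-s segments at 50%
overlap (11 segments per 30-s epoch), one-sided, window-power corrected,
reported as *integrated* power per 0.2-Hz bin in µV² rather than density —
so a sinusoid of amplitude A integrates to A²/2 and the sum over all bins
equals the epoch variance (Parseval; tests require agreement within 10%).
1-Hz aggregation sums 0.2-Hz bins over half-open [k, k+1) Hz with DC
excluded; the delta band starts at 0.3 Hz, so its first bin is the partial
0.3–1 Hz bin.  `peak_frequency` returns the *center* (k + 0.5) of the
argmax bin, ties broken toward lower frequency.

Stage profiles average the artifact-free epochs of one stage and attach
Student-t 95% CIs computed across epochs (whether published CIs are across
epochs or sessions is ambiguous; epochs is the default and the unit is a
parameter).  Artifact epochs are flagged at peak |EEG| > 500 µV or range
< 1 µV — values chosen as conservative defaults, both configurable — and
manual flags carried by the hypnogram are OR-ed in.  Condition comparison
is a per-1-Hz-bin one-way fixed-effects ANOVA with contiguous significant
bins reported as intervals; no normality screening is applied before it.

The rule-based auto-stager is plumbing for round-trip tests, not a scoring
substitute: a deterministic decision tree on EMG RMS, delta fraction,
EMG atonia and the 11–16 Hz spindle-band share (the classical spindle band,
a labeled choice over the slower 8–12 Hz reading).  Its thresholds are
tuned to the shipped healthy signal preset, on which it recovers ≥ 80%
(in practice ~100%) of epochs.

## Heart-rate variability

Twelve disjoint 2-min windows are sampled uniformly (seeded) from within
maximal REM runs.  R peaks are detected on the EMG after a 20-ms moving
average — the QRS complex is a 30–50 ms transient, so short averaging
suppresses broadband muscle tone (important in parkinsonian REM, where
atonia is lost and tone approaches the R-wave amplitude) far more than the
peak.  The threshold is 6 robust SDs (1.4826·MAD) above the median, with a
250-ms refractory.  Intervals are gated to 0.2–3 s; drops are counted.
Summary statistics (meanNN, StdNN, CV = 100·StdNN/meanNN) are computed on
the intervals *pooled* across the 12 windows — matching a single reported
CV per state — with per-window summaries also available; StdNN uses the
sample (n−1) convention by default, flag-switchable.  Poincaré pairs are
never formed across window boundaries.

## Statistics

Kruskal–Wallis H uses the tie-corrected chi-square approximation (k−1 df).
Dunn's pairwise z uses mean ranks with the pooled tie-corrected variance
S² = N(N+1)/12 − Σ(t³−t)/(12(N−1)), two-sided normal p-values and
Bonferroni adjustment over all k(k−1)/2 pairs — the common
commercial-software default; exact tie handling differs subtly across
implementations, so correctness is established against a brute-force rank
oracle in the tests rather than against any one program.  Pairwise results
are reported whether or not the omnibus rejects (flag-gated).
Mann–Whitney uses exact enumeration when both groups have n ≤ 8 and no
ties, else the tie-corrected normal approximation.

## Synthetic generator

Every generator is a pure function of (preset, seed).  The hypnogram
process is semi-Markov: bout lengths geometric in epochs (memoryless) with
per-stage means, transitions drawn from a propensity matrix reweighted by
(i) linear time-of-night modulation on the N3 and R columns (front-loaded
N3, back-loaded REM), and (ii) a fragmentation scalar multiplying
sleep→wake propensities.  Nights open with a wake run drawn around the
preset sleep latency (truncated normal).  EEG is synthesized per epoch in
the frequency domain: each analysis band is band-limited Gaussian noise
with random spectral phases and chi-squared bin energies scaled so the
expected band variance equals the preset band power, plus an optional
narrowband sinusoid (the symptomatic active-wake preset carries a 13-Hz,
9-µV component; the N2 preset a 13-Hz spindle-band component).  EMG is
Gaussian tone at the stage RMS; when RR parameters are supplied, a
continuous biphasic ~40-ms R-wave template train is overlaid across the
whole recording so RR intervals remain valid across epoch boundaries.  RR
intervals follow a lag-1 autoregressive Gaussian process (φ = 0.3) with
the stationary mean/SD of the preset, clipped at a 0.2-s physiological
floor (negligible clipped mass at shipped parameters).  Actimetry is
Poisson per 10-s bin with stage-dependent rates (active wake ≫ quiet
wake ≫ sleep).

The three shipped condition presets were calibrated once, against the
published group means of the macaque study (animal M1's columns), by
iterating `scripts/tune_presets.py`: healthy nights average ~74%
efficiency and ~11–12 cycles; presymptomatic nights are N3-heavy (~37% of
scoring time) with longer latencies; symptomatic nights are fragmented
(~33% efficiency, transition rate ~1.6× healthy, minimal N3/REM).  RR
presets take the published meanNN values with SD derived from the
published CVs; mMSLT latency presets take the published per-state latency
means with SD 3 min.  The published dispersion of the presymptomatic RR
state (CV 22.31%) is wide enough that a conservative "mean − 4·SD above
floor" prior cannot hold; the generator instead clips at the floor, which
at these parameters affects < 0.1% of draws.

**What the generator does not emulate.**  No biophysical EEG (no cortical
dynamics, no spindle/K-complex morphology beyond band and narrowband
power, no sawtooth waveshape); no respiration or movement artifact unless
injected; stage bouts are memoryless, whereas real bout-length
distributions are heavier-tailed; between-night variability comes only
from seed-to-seed sampling noise, not from true animal-level variance
(published SEMs constrain the means, not the within-state process).
Passing recovery tests therefore demonstrates that the *analysis* is
correct and well-calibrated on data with the stated statistical structure —
not that it would be robust to every artifact of real telemetry.

## Problem sizes and determinism

Cohort sizes follow the study design where stated: ≥10 recordings per
state per window, 30 mMSLT sessions per state, 12×2-min REM windows, 2000
RR intervals for dispersion recovery, ≥10–30 epochs per spectral profile.
Tests that need full PSG time series use 2-h nights at 250 Hz — enough for
240-epoch round-trips at a quarter of the sample volume; all analysis code
is rate-agnostic above the Nyquist guard (> 2× the 100-Hz EMG analysis
edge).  Every stochastic step takes an explicit seed, and derived seeds are
drawn from a single root generator, so studies, tests and the acceptance
script are exactly reproducible.
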