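"""Stage-conditioned EEG spectra and the symptomatic low-beta peak.

Thirty 30-s active-wake epochs are synthesized per condition; each epoch
gets a Welch PSD (Hamming 5-s segments, 50% overlap), aggregated into
1-Hz bins.  The symptomatic preset carries a 13-Hz narrowband component,
which shows up as the 12-35 Hz argmax; a per-bin one-way ANOVA localizes
where the conditions differ.
"""

import numpy as np

from nhpsleep import Condition, StageLabel, spectral as spec
from nhpsleep.synthetic import SIGNAL, generate_stage_epochs

matrices = {}
for cond in Condition:
    epochs = generate_stage_epochs(SIGNAL[cond][StageLabel.A], 30, seed=10)
    psds = [spec.epoch_psd(e["EEG"], 500.0, epoch_index=i, stage=StageLabel.A)
            for i, e in enumerate(epochs)]
    profile = spec.stage_profile(psds, StageLabel.A, condition=cond.value)
    freqs, mat = spec.epoch_band_matrix(psds, stage=StageLabel.A)
    matrices[cond.value] = mat
    peak = spec.peak_frequency(profile, 12.0, 35.0)
    beta = spec.band_power(profile, 13.0, 35.0)
    print(f"{cond.value:>15}: beta power {beta:6.1f} uV^2, "
          f"12-35 Hz peak bin center {peak:.1f} Hz")

comp = spec.compare_bins(matrices, bin_freqs=np.arange(35.0))
print(f"\nper-1-Hz-bin ANOVA: {int(comp.significant.sum())} significant bins "
      f"at alpha=0.05; intervals: {comp.runs}")
print("The symptomatic peak sits in the [13,14) Hz bin - the low-beta "
      "signature that emerges with the parkinsonian syndrome.")
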