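"""REM-sleep heart-rate variability from the EMG channel, end to end.

Twelve 2-min REM EMG windows are synthesized per condition with cardiac
R-peak templates embedded at the condition's RR-interval statistics.  The
detector (20-ms smoothing, adaptive robust threshold, 250-ms refractory)
recovers the beat train; the pooled intervals give meanNN, StdNN and the
coefficient of variation, plus Poincare successor pairs.
"""

import numpy as np

from nhpsleep import Condition, StageLabel, hrv
from nhpsleep.synthetic import RR, SIGNAL, generate_stage_epochs

for cond in Condition:
    per = []
    for i in range(12):
        ep = generate_stage_epochs(SIGNAL[cond][StageLabel.R], 1, epoch_length=120.0,
                                   seed=500 + i, rr_preset=RR[cond])[0]
        times = hrv.detect_r_peaks(ep["EMG"], 500.0)
        iv = np.diff(times)
        per.append(iv[(iv > hrv.RR_GATE[0]) & (iv < hrv.RR_GATE[1])])
    series = hrv.rr_series_from_intervals(per)
    s = hrv.hrv_summary(series)
    pairs = hrv.poincare(series).pairs
    print(f"{cond.value:>15}: meanNN {s.mean_nn:.3f} s  StdNN {s.std_nn:.3f} s  "
          f"CV {s.cv:5.2f} %  ({s.n_intervals} beats, {len(pairs)} Poincare pairs; "
          f"preset meanNN {RR[cond].mean_nn:.3f}, CV {RR[cond].cv_percent:.2f})")

print("\nThe presymptomatic state keeps a normal mean heart period but a "
      "visibly wider Poincare cloud (higher CV) - an early autonomic marker.")
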