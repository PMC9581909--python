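"""Calibration report for the shipped architecture presets.

Simulates seeded cohorts of nights and days per condition and prints the
cohort means next to the published group means the presets were tuned
against.  Run after editing presets:

    python scripts/tune_presets.py [--nights 20] [--seed 0]
"""

from __future__ import annotations

import argparse

import numpy as np

from nhpsleep import Condition, metrics as met
from nhpsleep.synthetic import (
    ARCHITECTURE_DAY,
    ARCHITECTURE_NIGHT,
    day_window,
    generate_hypnogram,
    night_window,
)

# Published 12-h group means (animal M1) used as calibration targets.
NIGHT_TARGETS = {
    Condition.HEALTHY: dict(sl=13.4, eff=74.2, cycles=11.4, tst=523.1,
                            pct=dict(A=17.2, W=10.0, N1=18.2, N2=17.0, N3=25.2, R=12.4)),
    Condition.PRESYMPTOMATIC: dict(sl=22.2, eff=71.8, cycles=10.3, tst=498.8,
                                   pct=dict(A=19.0, W=11.8, N1=10.2, N2=5.2, N3=39.6, R=14.3)),
    Condition.SYMPTOMATIC: dict(sl=18.7, eff=33.4, cycles=0.8, tst=230.4,
                                pct=dict(A=38.0, W=29.0, N1=13.3, N2=8.2, N3=5.4, R=5.1)),
}
DAY_TARGETS = {
    Condition.HEALTHY: dict(first_sleep=41.1, tst=107.4, naps="3-4"),
    Condition.PRESYMPTOMATIC: dict(first_sleep=25.8, tst=112.1, naps="?"),
    Condition.SYMPTOMATIC: dict(first_sleep=8.7, tst=115.0, naps="?"),
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--nights", type=int, default=20)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    for cond in Condition:
        rows = []
        for _ in range(args.nights):
            hyp = generate_hypnogram(ARCHITECTURE_NIGHT[cond], night_window(),
                                     seed=int(rng.integers(2**31)))
            s = met.night_summary(hyp)
            rows.append((s.sl, s.sleep_efficiency, s.sleep_cycles, s.tst,
                         s.transitions_per_hour,
                         [s.stage_pct[k] for k in s.stage_pct]))
        sl, eff, cyc, tst, trans = (np.mean([r[i] for r in rows]) for i in range(5))
        pct = np.mean([r[5] for r in rows], axis=0)
        t = NIGHT_TARGETS[cond]
        print(f"== {cond.value} (night, n={args.nights}) ==")
        print(f"  SL      {sl:6.1f}  target {t['sl']}")
        print(f"  eff     {eff:6.1f}  target {t['eff']}")
        print(f"  cycles  {cyc:6.1f}  target {t['cycles']}")
        print(f"  TST     {tst:6.1f}  target {t['tst']}")
        print(f"  trans/h {trans:6.1f}")
        labels = ["A", "W", "N1", "N2", "N3", "R"]
        tgt = t["pct"]
        print("  pct     " + "  ".join(f"{lb}:{p:.1f}/{tgt[lb]}" for lb, p in zip(labels, pct)))

    for cond in Condition:
        fs, tsts, naps, trans = [], [], [], []
        for _ in range(args.nights):
            hyp = generate_hypnogram(ARCHITECTURE_DAY[cond], day_window(),
                                     seed=int(rng.integers(2**31)))
            s, nap_list = met.daytime_summary(hyp)
            fs.append(s.sl if s.sl is not None else 720.0)
            tsts.append(s.tst)
            naps.append(len(nap_list))
            trans.append(s.transitions_per_hour)
        t = DAY_TARGETS[cond]
        print(f"== {cond.value} (day) == first_sleep {np.mean(fs):.1f}/{t['first_sleep']}"
              f"  TST {np.mean(tsts):.1f}/{t['tst']}  naps {np.mean(naps):.1f} ({t['naps']})"
              f"  trans/h {np.mean(trans):.1f}")


if __name__ == "__main__":
    main()
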