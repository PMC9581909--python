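"""Simulate one healthy 12-h night and compute its architecture metrics.

The generator draws a semi-Markov stage sequence (30-s epochs, 19:00-07:00)
from the healthy preset; the metrics module then reports the standard
summary row: sleep latency, TST, WASO, efficiency, stage percentages,
wake<->sleep transition rate and sleep-cycle count.
"""

from nhpsleep import Condition, metrics
from nhpsleep.synthetic import ARCHITECTURE_NIGHT, generate_hypnogram, night_window

hyp = generate_hypnogram(ARCHITECTURE_NIGHT[Condition.HEALTHY], night_window(), seed=1)
s = metrics.night_summary(hyp)

print(f"epochs scored:        {hyp.n_epochs}")
print(f"sleep latency:        {s.sl:.1f} min   (lights-off to first sleep epoch)")
print(f"total sleep time:     {s.tst:.1f} min")
print(f"WASO:                 {s.waso:.1f} min   (wake after sleep onset)")
print(f"sleep efficiency:     {s.sleep_efficiency:.1f} %    (100*TST/SPT)")
print(f"sleep cycles:         {s.sleep_cycles}        (NREM->REM alternations)")
print(f"transitions:          {s.transitions_per_hour:.1f} /h   (wake<->sleep boundary)")
print("stage % of scoring time: "
      + "  ".join(f"{st.value}:{pct:.1f}" for st, pct in s.stage_pct.items()))
print("\nA healthy macaque night shows ~74% efficiency and ~11 cycles; "
      "identical seed + preset always reproduces this hypnogram.")
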