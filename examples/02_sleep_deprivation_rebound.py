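"""Sleep-deprivation rebound metrics.

Simulates three basal days plus one day with total sleep deprivation
during ZT0-6 followed by an exponentially decaying rebound (sleep onset
doubled, sleep fragmentation halved at deprivation end, decaying with a
6-h constant).  Prints cumulative sleep loss, the dark-phase rebound ratio
(SD/basal, ZT12-24), the paired deltas and the detected rebound onset.
"""

from sleepmap import homeostasis as ho
from sleepmap import synthetic as syn

exp, scenario = syn.simulate_sd_experiment(seed=0)

loss = ho.cumulative_difference(exp)
print(f"cumulative sleep loss at ZT6:  {loss.loc[6.0]:7.1f} min")
print(f"cumulative sleep loss at ZT24: {loss.iloc[-1]:7.1f} min")
print(f"rebound ratio (duration, ZT12-24): {ho.rebound_ratio(exp):.3f}")
print(f"rebound ratio (P_WS, ZT12-24):     {ho.rebound_ratio(exp, metric='p_ws'):.3f}")
print(f"rebound ratio (P_SW, ZT12-24):     {ho.rebound_ratio(exp, metric='p_sw'):.3f}")
print(f"delta sleep duration (ZT12-15):    {ho.paired_delta(exp):+.1f} min")
print(f"rebound onset (package convention): ZT{ho.rebound_onset(exp):.0f}")
print("(a ratio > 1 for duration and P_WS with P_SW < 1 is the rebound signature)")
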