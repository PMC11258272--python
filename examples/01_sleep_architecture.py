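"""Sleep architecture from an epoch-based hypnogram.

Simulates one day of the two-state sleep/wake chain and computes the core
architecture statistics: sleep duration, the wake->sleep and sleep->wake
transition probabilities (P_WS, P_SW) per light/dark phase, and mean bout
durations.  High P_WS means fragmented wake; high P_SW means fragmented
sleep; mean bout length is approximately the inverse of the leaving
probability.
"""

from sleepmap import hypnogram as hg
from sleepmap import synthetic as syn

hyp, truth = syn.simulate_hypnogram(seed=0)

for name, lo, hi in [("light (ZT0-12)", 0.0, 12.0), ("dark (ZT12-24)", 12.0, 24.0)]:
    win = hg.Window(lo, hi)
    counts = hg.count_transitions(hyp, win)
    p_ws = hg.transition_probability(counts, "W")
    p_sw = hg.transition_probability(counts, "S")
    sleep_min = hg.state_duration(hyp, win, "S")
    bouts = hg.episodes(hyp, win)
    print(f"{name}:")
    print(f"  sleep duration      {sleep_min:6.1f} min")
    print(f"  P_WS (est/true)     {p_ws:.4f} / {truth['p_ws_' + name.split()[0]]:.4f}")
    print(f"  P_SW (est/true)     {p_sw:.4f} / {truth['p_sw_' + name.split()[0]]:.4f}")
    print(f"  mean sleep bout     {bouts.mean_duration_minutes('S'):.2f} min "
          f"(~ epoch_length / (60 * P_SW) = {8 / 60 / p_sw:.2f})")
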