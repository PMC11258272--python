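"""Automatic statistical-test selection with an auditable branch trace.

The dispatcher checks normality (Shapiro for two samples, KS for more)
and homoscedasticity (F-test / Bartlett) at 0.05, then routes to
Student's t, Welch's t, the two-sample Wilcoxon test, or — for many
groups against a control — the Steel many-one rank test.
"""

import numpy as np

from sleepmap import statdispatch as sd

rng = np.random.default_rng(0)

x, y = rng.normal(0, 1, 30), rng.normal(0.8, 1, 30)
r = sd.compare_two(x, y)
print(f"normal, equal variance -> {r.test_name}, p={r.p_value:.4f}")
print("  trace:", "; ".join(r.branch_trace))

r = sd.compare_two(rng.normal(0, 1, 50), rng.normal(0, 4, 50))
print(f"normal, unequal variance -> {r.test_name}, p={r.p_value:.4f}")

r = sd.compare_two(rng.exponential(1, 30), rng.exponential(2, 30))
print(f"skewed samples -> {r.test_name}, p={r.p_value:.4f}")

control = rng.exponential(1, 60)
groups = [control, rng.exponential(1, 60) + 1.0, rng.exponential(1, 60)]
for res in sd.compare_many(groups, reference_index=0):
    print(f"group {res.comparison[1]} vs control -> {res.test_name}, "
          f"familywise p={res.p_value:.4f}")
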