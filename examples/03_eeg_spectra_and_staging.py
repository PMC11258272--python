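"""EEG spectra and rule-based vigilance staging.

Simulates a three-state (wake/NREM/REM) day, synthesizes a matching
128-Hz EEG/EMG recording, stages it back with the rule-based scorer, and
computes state-conditioned band fractions.  The NREM delta fraction is
compared with the generator's closed-form value.
"""

import numpy as np

from sleepmap import spectral as sp
from sleepmap import staging as st
from sleepmap import synthetic as syn

hyp3, _ = syn.simulate_three_state(n_epochs=2700, seed=0)  # 6 h of 8-s epochs
rec, manifest = syn.simulate_recording(hyp3, seed=1)

staged = st.stage_recording(rec)
accuracy = np.mean(staged.stages == hyp3.stages)
print(f"staging accuracy vs generating hypnogram: {100 * accuracy:.1f}%")

mask = sp.flag_artifact_epochs(rec, hyp3)
print(f"artifact epochs flagged: {mask.sum()} of {hyp3.n_epochs}")

for state in "WNR":
    result = sp.state_psd_percent(rec, hyp3, state, mask=mask)
    delta = sp.band_fraction_percent(result, sp.DELTA)
    theta = sp.band_fraction_percent(result, sp.THETA)
    print(f"state {state}: delta {delta:5.1f}%  theta {theta:5.1f}%  "
          f"({result.n_epochs_used} epochs)")

planted = 100 * manifest["analytic_delta_fraction"]["N"]
print(f"NREM delta fraction, closed form from the recipe: {planted:.1f}%")
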