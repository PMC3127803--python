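"""Learn ten stimulus-response associations with delayed reinforcement.

Twenty population neurons see frozen Poisson patterns (80 afferents, 6 Hz,
500 ms) and must learn, for each of ten stimuli, which binary decision earns
reward +1 (the wrong one earns -1).  Reinforcement arrives 1000 ms after the
decision -- a full intervening stimulus later -- so the synapses must bridge
the gap with their eligibility-trace cascade: no weight may change at decision
time, only when the delayed reward transmitter washes over the traces.

Takes about half a minute.  Expect the smoothed accuracy to rise from chance
(0.5) toward > 0.9.
"""

import numpy as np

from poprl import AssociationConfig, run_association

config = AssociationConfig(n_trials=4000, delay=1000.0, stop_at=0.9)
result = run_association(config, np.random.default_rng(1))

print("trial   EWMA accuracy")
for k in range(499, len(result.smoothed), 500):
    print(f"{k + 1:5d}   {result.smoothed[k]:.3f}")
print(f"\nbest smoothed accuracy: {result.smoothed.max():.3f}")
ttc = result.extras["trials_to_criterion"]
print(f"trials to criterion (0.9): {ttc if ttc >= 0 else 'not reached'}")
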