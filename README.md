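# poprl

Reward-modulated plasticity cascades in spiking neural populations.

`poprl` simulates reinforcement learning in a population of escape-noise
leaky integrate-and-fire neurons whose synapses learn through a three-stage
eligibility-trace cascade.  Each stage remodulates the previous one with
information arriving on a slower time scale:

1. **e1** — a presynaptic trace: the postsynaptic-potential kernel sum of the
   afferent's recent spikes.
2. **e2** — a pre/post correlation trace: e1 transcribed under a postsynaptic
   signal comparing observed spikes to the neuron's instantaneous escape
   rate.  Over a decision window this equals the *characteristic
   eligibility*, the weight-gradient of the spike train's log-likelihood.
3. **e3** — a decision trace: e2 remodulated by the broadcast decision
   feedback and each neuron's alignment with the decision.
4. Finally, a (possibly much later) reward signal converts e3 into the
   lasting weight change, `dw/dt = R(t) e3(t)`.

Because each stage is a leaky integrator driven by locally available signals
(spikes, transmitter concentrations), reinforcement can arrive seconds after
the decision that earned it — with other decisions intervening — and still be
credited to the right synapses.  The rule is a policy-gradient method: in its
idealized pulse form its mean update provably follows the gradient of
expected reward (see `examples/01_gradient_check.py`).

The package includes three task environments (delayed-reinforcement
association, a variable-interval two-armed bandit, and a linear-track
navigation task), a tabular SARSA(λ) baseline that illustrates how
temporal-difference learning breaks on the same (non-Markovian) tasks, and
Monte-Carlo oracles for validating both learners.

## Worked example

Ten stimuli (frozen Poisson patterns, 80 afferents at 6 Hz for 500 ms), each
with one rewarded binary response; reward ±1 arrives 1000 ms after each
decision, i.e. during the *next* trial:

```python
import numpy as np
from poprl import AssociationConfig, run_association

config = AssociationConfig(n_trials=4000, delay=1000.0, stop_at=0.9)
result = run_association(config, np.random.default_rng(1))
```

Running this (`python examples/02_association_learning.py`) prints:

```
trial   EWMA accuracy
  500   0.430
 1000   0.709
 1500   0.808

best smoothed accuracy: 0.901
trials to criterion (0.9): 1810
```

On the bandit (`examples/03_bandit_population_vs_td.py`), the population
learner approaches the optimal stochastic policy while a memoryless
value learner meliorates toward matching and earns less:

```
fixed-arm payoff:           0.1333
optimal memoryless policy:  p_int = 0.24, reward = 0.1966 +- 0.0019

population learner (policy gradient):
  asymptotic reward/decision: 0.1939
  asymptotic p(intermittent): 0.303

memoryless softmax TD (melioration):
  asymptotic reward/decision: 0.1805 +- 0.0020
  asymptotic p(intermittent): 0.544
```

## Command line

```
poprl run --task assoc --agent population --seed 1 --out run.h5
poprl run --task track --agent sarsa --seed 0
poprl gradcheck --seed 42
poprl oracle --seed 0
```

`--config` accepts a YAML file overriding any field of the task's
configuration dataclass; the resolved configuration is echoed into the run
log.

## Layout

* `src/poprl/` — the library: `neuron`, `plasticity`, `decision`,
  `modulators`, `stimuli`, `tasks`, `td`, `engine`, `experiments`, `cli`.
* `examples/` — narrative scripts demonstrating each headline result.
* `scripts/acceptance.py` — measures the package's quantitative targets and
  writes them as JSON: `python scripts/acceptance.py --seed 1 --out out.json`.
* `docs/methods.md` — model equations, parameter choices, numerical notes.
* `tests/` — unit suites per module plus `tests/test_acceptance.py`, one test
  per acceptance criterion.

## Reproducibility

Every stochastic entry point takes a `numpy.random.Generator` or `--seed`;
runs are deterministic given (configuration, seed).  The numba and pure-Python
engine paths consume the same pre-drawn random numbers and agree to floating
point accumulation order.
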