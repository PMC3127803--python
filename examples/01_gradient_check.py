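"""Validate the plasticity cascade as a policy-gradient rule.

On a problem small enough to enumerate exactly (one neuron, two afferents,
twelve time bins, reward immediately at stimulus end), the average weight
update produced by the idealized learning rule should be proportional to the
gradient of the expected reward with respect to the synaptic weights.

The finite-difference gradient of the exactly enumerated expected reward is
the oracle; the rule's mean update is a Monte-Carlo average over 100,000
episodes.  Expect a cosine similarity very close to 1 and componentwise
z-scores of the residuals within sampling noise.
"""

import numpy as np

from poprl import GradientCheckInstance, NeuronParams, gradient_check

rng = np.random.default_rng(42)
neuron = NeuronParams(rho0=30.0, theta=0.0, delta_u=0.5)
instance = GradientCheckInstance(
    raster=(rng.random((2, 12)) < 0.25).astype(np.uint8),
    weights=rng.normal(0.0, 1.0, size=2),
    neuron=neuron,
)

report = gradient_check(instance, n_episodes=100_000, rng=rng)

print("finite-difference gradient:", np.round(report["fd_gradient"], 6))
print("mean rule update:          ", np.round(report["rule_update"], 6))
print(f"proportionality constant:   {report['slope']:.4f}")
print(f"cosine similarity:          {report['cosine']:.6f}")
print("residual z-scores:         ", np.round(report["z_scores"], 2))
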