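"""Population read-out and stochastic binary decision making.

The decision circuitry uses a spike/no-spike code: each population neuron
contributes +1 if it fired at least once during the current stimulus and -1
otherwise.  The normalized sum is the population activity A, and the binary
behavioral decision D in {-1, +1} is drawn from a logistic function of A.
The derivative of the decision log-likelihood with respect to A is the
decision-feedback magnitude broadcast back to the synapses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DecisionEvent",
    "population_activity",
    "decision_probability",
    "sample_decision",
    "decision_feedback_magnitude",
]


@dataclass(frozen=True)
class DecisionEvent:
    """One behavioral decision: activity A, decision D, its probability, time."""

    A: float
    D: int
    p: float
    t: float = 0.0


def population_activity(first_spike_flags, n_neurons: int | None = None) -> float:
    """A = (1/sqrt(N)) * sum_i chi_i with chi_i = +1 if neuron i spiked else -1.

    ``first_spike_flags`` holds, per neuron, whether it spiked at least once
    during the current decision period.  |A| <= sqrt(N).
    """
    flags = np.asarray(first_spike_flags, dtype=bool)
    n = flags.size if n_neurons is None else n_neurons
    if n < 1 or flags.size != n:
        raise ValueError("need at least one neuron and one flag per neuron")
    chi = np.where(flags, 1.0, -1.0)
    return float(chi.sum() / np.sqrt(n))


def decision_probability(A: float, D: int, gain: float = 1.0) -> float:
    """Logistic decision likelihood P(D | A) = 1 / (1 + exp(-gain * D * A))."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    if D not in (-1, 1):
        raise ValueError("D must be -1 or +1")
    z = gain * D * A
    # numerically stable logistic
    if z >= 0:
        return float(1.0 / (1.0 + np.exp(-z)))
    ez = np.exp(z)
    return float(ez / (1.0 + ez))


def sample_decision(A: float, gain: float, rng: np.random.Generator, t: float = 0.0) -> DecisionEvent:
    """Draw D = +1 with probability P(+1 | A), recording the event."""
    p_plus = decision_probability(A, +1, gain)
    D = 1 if rng.random() < p_plus else -1
    return DecisionEvent(A=A, D=D, p=p_plus if D == 1 else 1.0 - p_plus, t=t)


def decision_feedback_magnitude(event: DecisionEvent, gain: float = 1.0) -> float:
    """f = gain * D * (1 - P(D|A)) = d/dA log P(D|A).

    The pulse has the sign of the decision and is largest when the taken
    decision was close to chance, concentrating plasticity on decisions that
    were still explorative.
    """
    return gain * event.D * (1.0 - decision_probability(event.A, event.D, gain))
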