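"""Three-stage synaptic eligibility-trace cascade and reward-gated update.

Each synapse carries three decaying memory traces that are remodulated in
stages by information arriving on successively slower time scales:

* ``e1`` low-pass filters the presynaptic spikes with the PSP kernel
  (presynaptic memory, time scale tau_m).
* ``e2`` transcribes ``e1`` under a postsynaptic modulation signal PS that
  compares observed postsynaptic spiking to its expected rate
  (pre/post correlation memory, time scale of the decision period).
* ``e3`` remodulates ``e2`` by the decision feedback ``f`` and the neuron's
  alignment sign ``nu`` (pre/post/decision memory, time scale of the
  expected decision-to-reward delay).
* finally the reward signal converts ``e3`` into a lasting weight change,
  ``dw/dt = R(t) e3(t)``.

Two variants of the middle stage are provided.  The *biological* mode
low-pass filters ``PS * e1`` continuously (no knowledge of decision-period
boundaries required); the *idealized* mode integrates ``PS * e1`` over the
decision window, in which case the end-of-window value is exactly the
characteristic eligibility, i.e. the weight-gradient of the spike-train
log-density.  The idealized mode is the analytically checkable ground truth;
the biological mode is the headline learning rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .neuron import NeuronParams, escape_rate

__all__ = [
    "CascadeParams",
    "SynapseTraces",
    "postsyn_signal",
    "update_e1",
    "update_e2",
    "update_e3",
    "update_weight",
]


@dataclass(frozen=True)
class CascadeParams:
    """Time constants of the cascade stages (ms) and the learning rate.

    ``tau_e2`` should be matched to the decision time (the stimulus
    duration); ``tau_e3`` represents a guess at the typical delay between a
    decision and its reinforcement and is deliberately robust to mismatch.
    The learning rate scales the reward signal (it is absorbed into R).
    """

    tau_e2: float = 500.0
    tau_e3: float = 2000.0
    learning_rate: float = 1.0

    def __post_init__(self) -> None:
        if min(self.tau_e2, self.tau_e3) <= 0:
            raise ValueError("cascade time constants must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")


@dataclass
class SynapseTraces:
    """Per-synapse cascade state (arrays may be any common shape)."""

    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray
    w: np.ndarray

    @classmethod
    def zeros(cls, shape, w=None) -> "SynapseTraces":
        w0 = np.zeros(shape) if w is None else np.array(w, dtype=float)
        return cls(np.zeros(shape), np.zeros(shape), np.zeros(shape), w0)


def postsyn_signal(u: float, spiked: bool, params: NeuronParams) -> float:
    """Postsynaptic modulation signal PS for one time step (units 1/ms).

    PS compares the observed spike outcome to the expected escape rate: it is
    positive on spike steps and ``-rho(u)/delta_u`` otherwise, so a weight
    change proportional to ``e1 * PS`` reinforces the observed response.  The
    spike-step value uses the exact per-step Bernoulli score
    ``rho e^{-rho dt}/(1 - e^{-rho dt}) / delta_u`` (-> 1/(dt delta_u) as
    dt -> 0) so that the window integral of ``e1 * PS`` equals the
    characteristic eligibility exactly.
    """
    rho_ms = escape_rate(u, params) / 1000.0
    if spiked:
        x = rho_ms * params.dt
        if x <= 0.0:
            return 0.0
        # rho e^{-x} / (1 - e^{-x}): overflow-safe form of rho / (e^x - 1)
        return float(rho_ms * math.exp(-x) / -math.expm1(-x)) / params.delta_u
    return -rho_ms / params.delta_u


def update_e1(traces: SynapseTraces, presyn_spikes, neuron: NeuronParams) -> SynapseTraces:
    """Advance e1 by one step: the PSP-kernel sum over presynaptic spikes.

    Implemented as the difference of a fast (tau_s) and slow (tau_m)
    exponential filter; for convenience the two filter states are carried on
    the trace object as ``_zf``/``_zs``.
    """
    zf = getattr(traces, "_zf", None)
    if zf is None:
        traces._zf = np.zeros_like(traces.e1)
        traces._zs = np.zeros_like(traces.e1)
    spikes = np.asarray(presyn_spikes, dtype=bool)
    traces._zf *= math.exp(-neuron.dt / neuron.tau_s)
    traces._zs *= math.exp(-neuron.dt / neuron.tau_m)
    traces._zf[spikes] += 1.0
    traces._zs[spikes] += 1.0
    traces.e1 = neuron.kernel_norm * (traces._zs - traces._zf)
    return traces


def update_e2(
    traces: SynapseTraces,
    ps: float,
    params: CascadeParams,
    dt: float,
    mode: str = "biological",
) -> SynapseTraces:
    """Advance e2 by one step.

    biological: ``de2/dt = -e2/tau_e2 + PS * e1`` (low-pass transcription).
    idealized:  pure accumulation ``e2 += PS * e1 * dt`` (reset externally at
    each decision-window start); the end-of-window value is then the
    characteristic eligibility.
    """
    if mode == "biological":
        traces.e2 = traces.e2 * math.exp(-dt / params.tau_e2) + ps * traces.e1 * dt
    elif mode == "idealized":
        traces.e2 = traces.e2 + ps * traces.e1 * dt
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return traces


def update_e3(
    traces: SynapseTraces,
    feedback: float,
    alignment: int,
    params: CascadeParams,
    dt: float,
) -> SynapseTraces:
    """Advance e3 one step: ``de3/dt = -e3/tau_e3 + f(t) nu(t) e2(t)``.

    ``feedback`` is the decision-feedback signal f(t) (signed like the
    decision, large when the decision was uncertain) and ``alignment`` is
    nu in {-1, +1}, +1 when the neuron fired in response to the decision
    stimulus.  Their product determines whether the pre/post correlations
    held in e2 are credited toward or against the decision taken.
    """
    if alignment not in (-1, 1):
        raise ValueError("alignment must be -1 or +1")
    traces.e3 = traces.e3 * math.exp(-dt / params.tau_e3) + feedback * alignment * traces.e2 * dt
    return traces


def update_weight(traces: SynapseTraces, reward_signal: float, dt: float) -> SynapseTraces:
    """Advance the weight one step: ``dw/dt = R(t) e3(t)`` (no bounds)."""
    traces.w = traces.w + reward_signal * traces.e3 * dt
    return traces
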