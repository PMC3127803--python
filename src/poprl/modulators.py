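"""Neuromodulator channels carrying reward and decision feedback.

Both external reinforcement and the decision feedback reach the synapses as
ambient neurotransmitter concentrations rather than as instantaneous pulses.
Each channel relaxes toward a homeostatic level with time constant ``tau_c``;
an event (a delivered reward, a made decision) transiently raises or lowers
the production rate for a duration ``delta_prod``.  The production rate is
scaled so that the time-integral of the concentration deviation equals the
event value -- in the limit ``tau_c, delta_prod -> 0`` the channels converge
to idealized Dirac-like pulses of the same area.

A per-neuron spike trace ``sigma`` (set to 1 on each postsynaptic spike,
decaying with the decision-period time constant otherwise) is thresholded to
obtain the alignment sign ``nu``: a slow, biologically available proxy for
"did this neuron fire in response to the decision stimulus".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModulatorParams",
    "ModulatorState",
    "update_concentration",
    "update_reward_concentration",
    "update_decision_concentration",
    "reward_signal",
    "decision_feedback",
    "update_post_trace",
    "alignment_sign",
    "production_rate",
]


@dataclass(frozen=True)
class ModulatorParams:
    """Shared constants of both transmitter channels.

    tau_c : concentration relaxation time constant (ms).
    delta_prod : duration of the production change after an event (ms).
    c0 : homeostatic reward-transmitter level (arbitrary concentration units).
    tau_sigma : decay time constant of the postsynaptic spike trace (ms);
        matched to the decision period, like the e2 trace.
    vartheta : threshold on sigma for the alignment sign; must lie below
        exp(-T/tau_sigma) because the trace is read out only after the
        stimulus has ended.
    """

    tau_c: float = 200.0
    delta_prod: float = 50.0
    c0: float = 1.0
    tau_sigma: float = 500.0
    vartheta: float = 0.2

    def __post_init__(self) -> None:
        if min(self.tau_c, self.delta_prod, self.tau_sigma) <= 0:
            raise ValueError("time constants must be positive")
        if not (0 < self.vartheta < 1):
            raise ValueError("vartheta must lie in (0, 1)")


def production_rate(value: float, params: ModulatorParams) -> float:
    """Production-rate change encoding an event of the given value.

    Chosen as value / (delta_prod * tau_c) so that the resulting
    concentration deviation integrates to exactly ``value`` over time.
    """
    return value / (params.delta_prod * params.tau_c)


@dataclass
class ModulatorState:
    """Concentrations of the two transmitter channels and the spike traces."""

    c_r: float
    c_d: float = 0.0
    sigma: np.ndarray = field(default_factory=lambda: np.zeros(1))
    # (end_time, rate) of currently active production windows
    reward_productions: list = field(default_factory=list)
    decision_production: tuple | None = None  # (end_time, rate)

    @classmethod
    def homeostatic(cls, n_neurons: int, params: ModulatorParams) -> "ModulatorState":
        return cls(c_r=params.c0, c_d=0.0, sigma=np.zeros(n_neurons))


def update_concentration(
    c: float, baseline: float, prod: float, params: ModulatorParams, dt: float
) -> float:
    """One exact exponential-Euler step of dc/dt = (baseline - c)/tau_c + prod."""
    decay = math.exp(-dt / params.tau_c)
    return baseline + (c - baseline) * decay + prod * params.tau_c * (1.0 - decay)


def _active_rate(productions, t: float) -> float:
    return sum(rate for end, rate in productions if end > t)


def update_reward_concentration(
    state: ModulatorState,
    events,
    params: ModulatorParams,
    dt: float,
    t: float,
) -> ModulatorState:
    """Advance the reward channel from t to t+dt.

    ``events`` is an iterable of (time, value) reinforcements becoming
    available in [t, t+dt); each opens a production window of length
    delta_prod with rate proportional to the value.
    """
    for ev_t, value in events:
        if t <= ev_t < t + dt:
            state.reward_productions.append((ev_t + params.delta_prod, production_rate(value, params)))
    prod = _active_rate(state.reward_productions, t)
    state.c_r = update_concentration(state.c_r, params.c0, prod, params, dt)
    state.reward_productions = [(end, r) for end, r in state.reward_productions if end > t + dt]
    return state


def update_decision_concentration(
    state: ModulatorState,
    pulse: float | None,
    params: ModulatorParams,
    dt: float,
    t: float,
) -> ModulatorState:
    """Advance the decision channel; a non-None ``pulse`` (the feedback
    magnitude of a decision just made) replaces any previous production."""
    if pulse is not None:
        state.decision_production = (t + params.delta_prod, production_rate(pulse, params))
    prod = 0.0
    if state.decision_production is not None:
        end, rate = state.decision_production
        if end > t:
            prod = rate
        else:
            state.decision_production = None
    state.c_d = update_concentration(state.c_d, 0.0, prod, params, dt)
    return state


def reward_signal(state: ModulatorState, learning_rate: float, params: ModulatorParams) -> float:
    """R = eta * (c_r - c0): the deviation from homeostasis, scaled by the
    learning rate (which is absorbed into the reward signal)."""
    return learning_rate * (state.c_r - params.c0)


def decision_feedback(state: ModulatorState) -> float:
    """f(t): deviation of the decision-transmitter concentration from baseline."""
    return state.c_d


def update_post_trace(
    state: ModulatorState, post_spikes, params: ModulatorParams, dt: float
) -> ModulatorState:
    """sigma <- 1 on a postsynaptic spike, otherwise exponential decay."""
    spikes = np.asarray(post_spikes, dtype=bool)
    state.sigma = state.sigma * math.exp(-dt / params.tau_sigma)
    state.sigma[spikes] = 1.0
    return state


def alignment_sign(sigma, vartheta: float):
    """nu = +1 where the spike trace exceeds the threshold, else -1."""
    if not (0 < vartheta < 1):
        raise ValueError("vartheta must lie in (0, 1)")
    s = np.asarray(sigma, dtype=float)
    out = np.where(s >= vartheta, 1, -1)
    if np.isscalar(sigma) or s.ndim == 0:
        return int(out)
    return out
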