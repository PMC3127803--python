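"""Escape-noise leaky integrate-and-fire neuron.

The membrane potential is an affine sum of postsynaptic-potential (PSP)
kernels triggered by presynaptic spikes, plus a hyperpolarizing reset kernel
after each postsynaptic spike (spike-response form).  Action potentials are
generated stochastically with an instantaneous rate that grows exponentially
with the membrane potential ("escape noise"), which gives the spike train a
tractable point-process likelihood and makes its weight-gradient -- the
*characteristic eligibility* of policy-gradient learning -- available in
closed form.

Time is measured in milliseconds throughout; escape rates are specified in
1/s and converted internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "psp_kernel",
    "escape_rate",
    "spike_probability",
    "step_neuron",
    "spike_train_logdensity",
    "characteristic_eligibility",
]

# Guard for the exponential escape rate: exp(60) ~ 1e26 (1/s) already drives
# the per-step spike probability to 1 at any usable dt, so larger exponents
# only risk overflow without changing behaviour.
_MAX_EXPONENT = 60.0


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of the escape-noise LIF neuron.

    Attributes
    ----------
    tau_m : membrane time constant (ms).
    tau_s : synaptic time constant (ms); must be < tau_m.
    u_rest : resting potential (arbitrary units).
    reset_amp : amplitude of the post-spike hyperpolarization (potential units).
    rho0 : escape-rate scale (1/s); the firing rate at the soft threshold.
    theta : soft threshold (potential units).
    delta_u : escape-rate sensitivity (potential units); the deterministic
        threshold neuron is recovered as delta_u -> 0.
    dt : simulation time step (ms).

    The default threshold and sensitivity are calibrated to the default
    population input (80 afferents at 6 Hz, weight SD 4, peak-normalized
    kernels): theta sits at the median of the membrane-potential excursions so
    that roughly half the neurons participate on an untrained stimulus, and
    delta_u spans those excursions so that both silent and active neurons
    retain usable likelihood-gradients.
    """

    tau_m: float = 10.0
    tau_s: float = 2.0
    u_rest: float = 0.0
    reset_amp: float = 1.0
    rho0: float = 10.0
    theta: float = 15.0
    delta_u: float = 2.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau_m > self.tau_s > 0):
            raise ValueError("need tau_m > tau_s > 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt > self.tau_s:
            raise ValueError("dt must not exceed tau_s")
        if self.rho0 <= 0 or self.delta_u <= 0:
            raise ValueError("rho0 and delta_u must be positive")

    @property
    def t_peak(self) -> float:
        """Time (ms) at which the PSP kernel attains its maximum."""
        return (
            self.tau_m
            * self.tau_s
            / (self.tau_m - self.tau_s)
            * math.log(self.tau_m / self.tau_s)
        )

    @property
    def kernel_norm(self) -> float:
        """Normalization making the PSP-kernel peak equal to one."""
        tp = self.t_peak
        return 1.0 / (math.exp(-tp / self.tau_m) - math.exp(-tp / self.tau_s))

    @property
    def rho0_ms(self) -> float:
        """Escape-rate scale in 1/ms."""
        return self.rho0 / 1000.0


def psp_kernel(t_since, params: NeuronParams):
    """Postsynaptic potential kernel epsilon(t).

    Peak-normalized difference of exponentials,
    ``epsilon(t) = K (exp(-t/tau_m) - exp(-t/tau_s))`` for ``t >= 0`` and 0
    otherwise, so synaptic weights are expressed in units of peak PSP.
    """
    t = np.asarray(t_since, dtype=float)
    out = np.where(
        t >= 0,
        params.kernel_norm
        * (np.exp(-np.clip(t, 0, None) / params.tau_m)
           - np.exp(-np.clip(t, 0, None) / params.tau_s)),
        0.0,
    )
    if np.isscalar(t_since):
        return float(out)
    return out


def escape_rate(u, params: NeuronParams):
    """Instantaneous firing rate rho(u) = rho0 * exp((u - theta)/delta_u), in 1/s."""
    arg = (np.asarray(u, dtype=float) - params.theta) / params.delta_u
    out = params.rho0 * np.exp(np.clip(arg, None, _MAX_EXPONENT))
    if np.isscalar(u):
        return float(out)
    return out


def spike_probability(u, params: NeuronParams):
    """Per-step spike probability ``1 - exp(-rho(u) dt)``.

    Unlike the naive ``rho dt`` this remains a probability for arbitrarily
    large membrane potentials; the two agree to O((rho dt)^2).
    """
    rho_ms = escape_rate(u, params) / 1000.0
    out = -np.expm1(-rho_ms * params.dt)
    if np.isscalar(u):
        return float(out)
    return out


@dataclass
class NeuronState:
    """Mutable per-neuron integration state.

    ``syn_fast``/``syn_slow`` are the per-afferent exponential filter states
    (time constants tau_s and tau_m); their normalized difference is the PSP
    kernel sum, which doubles as the first eligibility trace e1.
    ``reset_state`` is the decaying post-spike hyperpolarization.
    """

    syn_fast: np.ndarray
    syn_slow: np.ndarray
    reset_state: float = 0.0
    last_spike: float | None = None
    t: float = 0.0
    u: float = field(default=0.0)

    @classmethod
    def zeros(cls, n_afferents: int, params: NeuronParams) -> "NeuronState":
        return cls(
            syn_fast=np.zeros(n_afferents),
            syn_slow=np.zeros(n_afferents),
            u=params.u_rest,
        )

    def e1(self, params: NeuronParams) -> np.ndarray:
        """Per-afferent PSP kernel sums (= first eligibility traces)."""
        return params.kernel_norm * (self.syn_slow - self.syn_fast)


def membrane_potential(state: NeuronState, weights: np.ndarray, params: NeuronParams) -> float:
    return params.u_rest + float(weights @ state.e1(params)) - state.reset_state


def step_neuron(
    state: NeuronState,
    weights: np.ndarray,
    incoming: np.ndarray,
    params: NeuronParams,
    rng: np.random.Generator,
):
    """Advance the neuron by one time step.

    Filter states are decayed analytically (exponential update, exact for the
    linear kinetics), afferent spikes arriving this step are injected, the
    membrane potential is evaluated, and a postsynaptic spike is drawn with
    probability ``1 - exp(-rho(u) dt)``.  On a spike the reset contribution is
    incremented by ``reset_amp``.

    Returns
    -------
    (state, spiked) : the same (mutated) state and whether a spike occurred.
    """
    incoming = np.asarray(incoming)
    if weights.shape != state.syn_fast.shape or incoming.shape != state.syn_fast.shape:
        raise ValueError(
            f"weights/incoming must have shape {state.syn_fast.shape}, got "
            f"{weights.shape} and {incoming.shape}"
        )
    dt = params.dt
    state.syn_fast *= math.exp(-dt / params.tau_s)
    state.syn_slow *= math.exp(-dt / params.tau_m)
    state.reset_state *= math.exp(-dt / params.tau_m)
    state.t += dt
    mask = incoming.astype(bool)
    state.syn_fast[mask] += 1.0
    state.syn_slow[mask] += 1.0
    state.u = membrane_potential(state, weights, params)
    p = spike_probability(state.u, params)
    spiked = bool(rng.random() < p)
    if spiked:
        state.reset_state += params.reset_amp
        state.last_spike = state.t
    return state, spiked


def _raster_from_trains(trains, t0: float, t1: float, dt: float) -> np.ndarray:
    """Bin spike-time lists into a (n_afferents, n_steps) boolean raster."""
    n_steps = int(round((t1 - t0) / dt))
    raster = np.zeros((len(trains), n_steps), dtype=bool)
    for i, times in enumerate(trains):
        for t in np.atleast_1d(np.asarray(times, dtype=float)):
            b = int(math.floor((t - t0) / dt))
            if 0 <= b < n_steps:
                raster[i, b] = True
    return raster


def _u_trajectory(weights, X, Y, window, params: NeuronParams):
    """Membrane potential per bin for given pre (X) and post (Y) spike trains.

    The potential in a bin is evaluated *before* the reset of a postsynaptic
    spike occurring in that same bin, matching the causal order of the
    stepping simulation.
    """
    t0, t1 = window
    dt = params.dt
    n_steps = int(round((t1 - t0) / dt))
    raster = _raster_from_trains(X, t0, t1, dt)
    y = np.asarray(Y, dtype=float)
    if y.size and (y.min() < t0 or y.max() >= t1):
        raise ValueError("postsynaptic spikes outside the decision window")
    y_bins = np.zeros(n_steps, dtype=bool)
    for t in y:
        y_bins[int(math.floor((t - t0) / dt))] = True

    weights = np.asarray(weights, dtype=float)
    decay_s = math.exp(-dt / params.tau_s)
    decay_m = math.exp(-dt / params.tau_m)
    zf = np.zeros(len(X))
    zs = np.zeros(len(X))
    reset = 0.0
    u = np.empty(n_steps)
    e1 = np.empty((n_steps, len(X)))
    for k in range(n_steps):
        zf *= decay_s
        zs *= decay_m
        reset *= decay_m
        zf += raster[:, k]
        zs += raster[:, k]
        e1[k] = params.kernel_norm * (zs - zf)
        u[k] = params.u_rest + weights @ e1[k] - reset
        if y_bins[k]:
            reset += params.reset_amp
    return u, e1, y_bins


def spike_train_logdensity(weights, X, Y, window, params: NeuronParams) -> float:
    """Log point-process density of postsynaptic train Y given input X.

    Discretization consistent with the stepping simulation: a bin containing
    a spike contributes ``log(1 - exp(-rho dt)) - log dt`` and an empty bin
    contributes ``-rho dt``, so ``exp(logdensity) * dt**|Y|`` is exactly the
    product of per-step Bernoulli probabilities.  As dt -> 0 this converges
    to ``sum log rho(t_hat) - integral rho``.
    """
    u, _, y_bins = _u_trajectory(weights, X, Y, window, params)
    rho_ms = escape_rate(u, params) / 1000.0
    x = rho_ms * params.dt
    ld = 0.0
    # log(1 - e^{-x}) computed via expm1 for small-x stability
    spike_terms = np.log(-np.expm1(-x[y_bins])) - math.log(params.dt)
    ld += float(spike_terms.sum())
    ld -= float(x[~y_bins].sum())
    return ld


def characteristic_eligibility(weights, X, Y, window, afferent: int, params: NeuronParams) -> float:
    """d/dw_i of :func:`spike_train_logdensity` (the score function).

    For the exponential escape rate this equals the time-integral of
    ``e1_i(t) * PS(t)`` with the postsynaptic modulation signal PS of the
    plasticity cascade.
    """
    if not (0 <= afferent < len(X)):
        raise IndexError("afferent index out of range")
    u, e1, y_bins = _u_trajectory(weights, X, Y, window, params)
    rho_ms = escape_rate(u, params) / 1000.0
    x = rho_ms * params.dt
    e1_i = e1[:, afferent]
    # spike bins: d/du log(1-e^{-x}) = (rho/delta_u) dt e^{-x}/(1-e^{-x}) = (rho/delta_u) dt / (e^x - 1)
    spike_part = (x[y_bins] / np.expm1(x[y_bins])) * e1_i[y_bins] / params.delta_u
    quiet_part = -x[~y_bins] * e1_i[~y_bins] / params.delta_u
    return float(spike_part.sum() + quiet_part.sum())
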