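"""Population learning engine.

Couples the escape-noise neurons, the plasticity cascade, the decision
circuitry and the neuromodulator channels into a single stepped simulation.
One call to :meth:`PopulationLearner.present` runs a full decision period
(one stimulus presentation), returns the sampled behavioral decision and
schedules the decision-feedback transmitter production; the caller (a task
loop) then registers reward events with :meth:`deliver_reward`.

Two execution paths implement identical semantics: a numba-compiled kernel
(the default, used for experiments) and a pure-Python reference path that can
additionally record per-step traces for diagnostics.  A test asserts their
trajectories coincide (to floating-point accumulation order) given the same
random numbers.

Modes
-----
``biological``
    All cascade stages are low-pass filters updated every step; feedback
    arrives as slow transmitter concentrations.
``idealized``
    e2 integrates PS * e1 over the decision window (yielding exactly the
    characteristic eligibility) and feedback acts as instantaneous pulses.
    This is the analytically derived gradient-ascent form, used by the
    gradient-check harness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .decision import DecisionEvent, decision_feedback_magnitude, sample_decision
from .modulators import ModulatorParams, production_rate
from .neuron import NeuronParams
from .plasticity import CascadeParams
from .stimuli import StimulusPattern, pattern_to_raster

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco

__all__ = ["PopulationLearner", "RunawayWeightsError"]

_MAX_EXPONENT = 60.0


class RunawayWeightsError(RuntimeError):
    """Raised when synaptic weights overflow (diagnosed numerical failure)."""


@njit(cache=True)
def _present_kernel(
    raster,
    w,
    mask,
    zf,
    zs,
    reset,
    e2,
    e3,
    sigma,
    chi,
    e2acc,
    rew_prod,
    dec_prod,
    uniforms,
    c_r_dev,
    c_d,
    dt,
    decay_s,
    decay_m,
    decay_e2,
    decay_e3,
    decay_sig,
    decay_c,
    tau_c,
    knorm,
    u_rest,
    theta,
    delta_u,
    rho0_ms,
    reset_amp,
    vartheta,
    eta,
    mode,
):
    n_inputs, n_steps = raster.shape
    n_neurons = w.shape[0]
    for t in range(n_steps):
        for i in range(n_inputs):
            zf[i] *= decay_s
            zs[i] *= decay_m
            if raster[i, t]:
                zf[i] += 1.0
                zs[i] += 1.0
        c_r_dev = c_r_dev * decay_c + rew_prod[t] * tau_c * (1.0 - decay_c)
        c_d = c_d * decay_c + dec_prod[t] * tau_c * (1.0 - decay_c)
        rbar = eta * c_r_dev
        for a in range(n_neurons):
            reset[a] *= decay_m
            u = u_rest - reset[a]
            for i in range(n_inputs):
                if mask[a, i]:
                    u += w[a, i] * knorm * (zs[i] - zf[i])
            arg = (u - theta) / delta_u
            if arg > _MAX_EXPONENT:
                arg = _MAX_EXPONENT
            rho = rho0_ms * math.exp(arg)
            x = rho * dt
            p = -math.expm1(-x)
            spiked = uniforms[a, t] < p
            if spiked:
                # rho e^{-x}/(1-e^{-x}): overflow-safe form of rho/(e^x - 1)
                ps = rho * math.exp(-x) / p / delta_u
                sigma[a] = 1.0
                chi[a] = 1
                reset[a] += reset_amp
            else:
                ps = -rho / delta_u
                sigma[a] *= decay_sig
            if mode == 0:
                nu = 1.0 if sigma[a] >= vartheta else -1.0
                for i in range(n_inputs):
                    if mask[a, i]:
                        e1i = knorm * (zs[i] - zf[i])
                        e2[a, i] = e2[a, i] * decay_e2 + ps * e1i * dt
                        e3[a, i] = e3[a, i] * decay_e3 + c_d * nu * e2[a, i] * dt
                        w[a, i] += rbar * e3[a, i] * dt
            else:
                for i in range(n_inputs):
                    if mask[a, i]:
                        e1i = knorm * (zs[i] - zf[i])
                        e2acc[a, i] += ps * e1i * dt
    return c_r_dev, c_d


def _present_python(
    raster, w, mask, zf, zs, reset, e2, e3, sigma, chi, e2acc,
    rew_prod, dec_prod, uniforms, c_r_dev, c_d,
    dt, decay_s, decay_m, decay_e2, decay_e3, decay_sig, decay_c, tau_c,
    knorm, u_rest, theta, delta_u, rho0_ms, reset_amp, vartheta, eta, mode,
    record=None,
):
    """Vectorized reference implementation of the presentation kernel.

    Semantically identical to the numba kernel; optionally appends per-step
    diagnostics (u, e1, e2, e3, sigma, concentrations) to ``record``.
    """
    n_inputs, n_steps = raster.shape
    for t in range(n_steps):
        zf *= decay_s
        zs *= decay_m
        spikes_in = raster[:, t].astype(bool)
        zf[spikes_in] += 1.0
        zs[spikes_in] += 1.0
        e1 = knorm * (zs - zf)
        c_r_dev = c_r_dev * decay_c + rew_prod[t] * tau_c * (1.0 - decay_c)
        c_d = c_d * decay_c + dec_prod[t] * tau_c * (1.0 - decay_c)
        reset *= decay_m
        u = u_rest + (w * mask) @ e1 - reset
        arg = np.clip((u - theta) / delta_u, None, _MAX_EXPONENT)
        rho = rho0_ms * np.exp(arg)
        x = rho * dt
        p = -np.expm1(-x)
        spiked = uniforms[:, t] < p
        with np.errstate(divide="ignore", invalid="ignore"):
            ps_spike = np.where(p > 0, rho * np.exp(-x) / np.where(p > 0, p, 1.0), 0.0)
        ps = np.where(spiked, ps_spike, -rho) / delta_u
        sigma *= np.where(spiked, 1.0, decay_sig)
        sigma[spiked] = 1.0
        chi[spiked] = 1
        reset[spiked] += reset_amp
        if mode == 0:
            nu = np.where(sigma >= vartheta, 1.0, -1.0)
            src = (ps[:, None] * e1[None, :]) * mask
            e2 *= decay_e2
            e2 += src * dt
            e3 *= decay_e3
            e3 += (c_d * nu[:, None]) * e2 * dt
            w += (eta * c_r_dev) * e3 * dt
        else:
            e2acc += (ps[:, None] * e1[None, :]) * mask * dt
        if record is not None:
            record.append(
                dict(t=t, u=u.copy(), e1=e1.copy(), e2=e2.copy(), e3=e3.copy(),
                     sigma=sigma.copy(), c_r_dev=c_r_dev, c_d=c_d, spiked=spiked.copy())
            )
    return c_r_dev, c_d


@dataclass
class PopulationLearner:
    """A population of plastic escape-noise neurons plus decision circuitry."""

    n_inputs: int
    n_neurons: int
    neuron: NeuronParams = field(default_factory=NeuronParams)
    cascade: CascadeParams = field(default_factory=CascadeParams)
    modulator: ModulatorParams = field(default_factory=ModulatorParams)
    gain: float = 1.0
    connectivity: float = 0.5
    init_sd: float = 4.0
    mode: str = "biological"
    use_numba: bool = _HAVE_NUMBA
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def __post_init__(self) -> None:
        if self.mode not in ("biological", "idealized"):
            raise ValueError("mode must be 'biological' or 'idealized'")
        n, m = self.n_neurons, self.n_inputs
        self.w = self.rng.normal(0.0, self.init_sd, size=(n, m))
        self.mask = (self.rng.random((n, m)) < self.connectivity).astype(np.uint8)
        # guarantee at least one synapse per neuron
        for a in range(n):
            if not self.mask[a].any():
                self.mask[a, self.rng.integers(m)] = 1
        self.w *= self.mask
        self.zf = np.zeros(m)
        self.zs = np.zeros(m)
        self.reset = np.zeros(n)
        self.e2 = np.zeros((n, m))
        self.e3 = np.zeros((n, m))
        self.sigma = np.zeros(n)
        self.c_r_dev = 0.0  # deviation of reward transmitter from homeostasis
        self.c_d = 0.0
        self.t = 0.0
        self._productions: list = []  # (start, end, rate) reward-channel windows
        self._decision_production: tuple | None = None
        self._ideal_events: list = []  # (time, value) reward pulses, idealized mode
        self.eta = self.cascade.learning_rate

    # -- feedback scheduling ------------------------------------------------

    def deliver_reward(self, value: float, at_time: float | None = None) -> None:
        """Register external reinforcement of the given value.

        In biological mode this opens a transmitter-production window of
        length delta_prod starting at ``at_time`` (default: now); in
        idealized mode it schedules an instantaneous reward pulse.
        """
        t0 = self.t if at_time is None else at_time
        if t0 < self.t:
            raise ValueError("cannot schedule reinforcement in the past")
        if self.mode == "idealized":
            self._ideal_events.append((t0, value))
        else:
            rate = production_rate(value, self.modulator)
            self._productions.append((t0, t0 + self.modulator.delta_prod, rate))

    def _render_channel(self, productions, n_steps: int) -> np.ndarray:
        dt = self.neuron.dt
        prod = np.zeros(n_steps)
        for start, end, rate in productions:
            k0 = max(0, int(math.ceil((start - self.t) / dt - 1e-9)))
            k1 = min(n_steps, int(math.ceil((end - self.t) / dt - 1e-9)))
            if k1 > k0:
                prod[k0:k1] += rate
        return prod

    # -- main entry point ----------------------------------------------------

    def relax(self, duration: float) -> None:
        """Advance the dynamics for ``duration`` ms with no stimulus.

        No decision is sampled.  Scheduled transmitter productions (decision
        feedback, reward) act on the decaying eligibility traces during this
        interval, so a relaxation period after each presentation lets the
        feedback read out the just-evaluated traces before the next stimulus
        overwrites them.
        """
        n_steps = int(round(duration / self.neuron.dt))
        if n_steps <= 0:
            return
        raster = np.zeros((self.n_inputs, n_steps), dtype=np.uint8)
        self._run_period(raster)

    def present(self, stimulus) -> DecisionEvent:
        """Run one full decision period on the given stimulus.

        ``stimulus`` is a :class:`StimulusPattern` or a pre-binned
        (n_inputs, n_steps) raster.  Returns the sampled decision event; the
        decision-feedback production for the *next* period is scheduled
        internally.
        """
        if isinstance(stimulus, StimulusPattern):
            raster = pattern_to_raster(stimulus, self.neuron.dt)
        else:
            raster = np.asarray(stimulus, dtype=np.uint8)
        if raster.shape[0] != self.n_inputs:
            raise ValueError(f"stimulus has {raster.shape[0]} trains, expected {self.n_inputs}")
        chi = self._run_period(raster)
        mp = self.modulator

        A = float((2.0 * chi - 1.0).sum() / math.sqrt(self.n_neurons))
        event = sample_decision(A, self.gain, self.rng, t=self.t)
        f_val = decision_feedback_magnitude(event, self.gain)
        if self.mode == "idealized":
            nu = np.where(chi.astype(bool), 1.0, -1.0)
            self.e3 += f_val * nu[:, None] * self._last_e2acc
        else:
            rate = production_rate(f_val, self.modulator)
            self._decision_production = (self.t, self.t + mp.delta_prod, rate)
        self._last_chi = chi
        return event

    def _run_period(self, raster: np.ndarray) -> np.ndarray:
        """Step the full dynamics over one binned raster; returns chi."""
        n_steps = raster.shape[1]
        dt = self.neuron.dt
        t_end = self.t + n_steps * dt

        rew_prod = self._render_channel(self._productions, n_steps)
        dec_prods = [self._decision_production] if self._decision_production else []
        dec_prod = self._render_channel(dec_prods, n_steps)

        np_, cp, mp = self.neuron, self.cascade, self.modulator
        chi = np.zeros(self.n_neurons, dtype=np.uint8)
        e2acc = np.zeros_like(self.e2) if self.mode == "idealized" else np.empty((0, 0))
        uniforms = self.rng.random((self.n_neurons, n_steps))
        args = (
            raster, self.w, self.mask, self.zf, self.zs, self.reset,
            self.e2, self.e3, self.sigma, chi, e2acc, rew_prod, dec_prod,
            uniforms, self.c_r_dev, self.c_d,
            dt, math.exp(-dt / np_.tau_s), math.exp(-dt / np_.tau_m),
            math.exp(-dt / cp.tau_e2), math.exp(-dt / cp.tau_e3),
            math.exp(-dt / mp.tau_sigma), math.exp(-dt / mp.tau_c), mp.tau_c,
            np_.kernel_norm, np_.u_rest, np_.theta, np_.delta_u, np_.rho0_ms,
            np_.reset_amp, mp.vartheta, self.eta,
            0 if self.mode == "biological" else 1,
        )
        if self.use_numba:
            self.c_r_dev, self.c_d = _present_kernel(*args)
        else:
            self.c_r_dev, self.c_d = _present_python(*args)

        if self.mode == "idealized":
            self._apply_ideal_rewards(t_end)
        # prune expired reward productions
        self._productions = [p for p in self._productions if p[1] > t_end]
        if self._decision_production and self._decision_production[1] <= t_end:
            self._decision_production = None
        self.t = t_end

        if not np.isfinite(self.w).all():
            raise RunawayWeightsError(
                "synaptic weights overflowed; reduce the learning rate"
            )
        self._last_e2acc = e2acc
        return chi

    def _apply_ideal_rewards(self, t_end: float) -> None:
        """Idealized mode: decay e3 through this period, applying reward
        pulses (w += eta * value * e3) at their scheduled times in order."""
        tau = self.cascade.tau_e3
        due = sorted(ev for ev in self._ideal_events if ev[0] < t_end)
        self._ideal_events = [ev for ev in self._ideal_events if ev[0] >= t_end]
        t_last = self.t
        for te, value in due:
            self.e3 *= math.exp(-(te - t_last) / tau)
            self.w += self.eta * value * self.e3
            t_last = te
        self.e3 *= math.exp(-(t_end - t_last) / tau)
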