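"""Unit tests for the escape-noise neuron and its likelihood machinery."""

import itertools
import math

import numpy as np
import pytest

from poprl.neuron import (
    NeuronParams,
    NeuronState,
    characteristic_eligibility,
    escape_rate,
    psp_kernel,
    spike_probability,
    spike_train_logdensity,
    step_neuron,
)


@pytest.fixture
def params():
    return NeuronParams()


def test_param_validation():
    with pytest.raises(ValueError):
        NeuronParams(tau_m=2.0, tau_s=10.0)
    with pytest.raises(ValueError):
        NeuronParams(dt=-1.0)
    with pytest.raises(ValueError):
        NeuronParams(dt=5.0)  # dt > tau_s
    with pytest.raises(ValueError):
        NeuronParams(rho0=-1.0)
    with pytest.raises(ValueError):
        NeuronParams(delta_u=0.0)


def test_psp_kernel_peak_normalized(params):
    t = np.linspace(0.0, 100.0, 100001)
    k = psp_kernel(t, params)
    assert k.max() == pytest.approx(1.0, abs=1e-6)
    # the maximum is attained at the analytic peak time
    assert abs(t[np.argmax(k)] - params.t_peak) < 2e-3
    # kernel vanishes at onset and for negative times (causality)
    assert psp_kernel(0.0, params) == 0.0
    assert psp_kernel(-5.0, params) == 0.0


def test_psp_kernel_double_exponential_form(params):
    t = 3.7
    expected = params.kernel_norm * (
        math.exp(-t / params.tau_m) - math.exp(-t / params.tau_s)
    )
    assert psp_kernel(t, params) == pytest.approx(expected, rel=1e-12)


def test_escape_rate_exponential(params):
    # rate equals rho0 at the soft threshold
    assert escape_rate(params.theta, params) == pytest.approx(params.rho0)
    # e-fold for each delta_u above threshold
    r1 = escape_rate(params.theta + params.delta_u, params)
    assert r1 == pytest.approx(params.rho0 * math.e, rel=1e-12)


def test_spike_probability_exact_bernoulli(params):
    u = params.theta + 2.0
    rho_ms = escape_rate(u, params) / 1000.0
    p = spike_probability(u, params)
    assert p == pytest.approx(-math.expm1(-rho_ms * params.dt), rel=1e-12)
    assert 0.0 <= p <= 1.0
    # saturates at 1 for huge potentials instead of overflowing
    assert spike_probability(1e6, params) == pytest.approx(1.0)


def _toy_instance(seed, n_aff=3, n_bins=6, rate=0.4):
    """Random spike-time inputs and weights on a small window."""
    rng = np.random.default_rng(seed)
    params = NeuronParams(theta=0.0, delta_u=0.5, rho0=40.0)
    window = (0.0, float(n_bins))
    X = [
        np.flatnonzero(rng.random(n_bins) < rate) + 0.5  # one possible spike/bin
        for _ in range(n_aff)
    ]
    w = rng.normal(0.0, 1.0, n_aff)
    return params, window, X, w


def test_logdensity_normalization_by_enumeration():
    """Sum of probabilities over all 2^6 postsynaptic patterns equals 1."""
    params, window, X, w = _toy_instance(0)
    n_bins = int(window[1])
    total = 0.0
    for pattern in itertools.product((0, 1), repeat=n_bins):
        Y = [t + 0.5 for t, s in enumerate(pattern) if s]
        logp = spike_train_logdensity(w, X, Y, window, params)
        # the density is per unit time; undo the bin measure
        total += math.exp(logp + len(Y) * math.log(params.dt))
    assert total == pytest.approx(1.0, abs=1e-6)


def test_characteristic_eligibility_matches_finite_differences():
    """Weight-gradient of the log-density vs central differences."""
    params, window, X, w = _toy_instance(1, n_bins=12)
    rng = np.random.default_rng(2)
    Y = (np.flatnonzero(rng.random(12) < 0.3) + 0.5).tolist()
    eps = 1e-5
    for i in range(len(w)):
        grad = characteristic_eligibility(w, X, Y, window, i, params)
        wp, wm = w.copy(), w.copy()
        wp[i] += eps
        wm[i] -= eps
        fd = (
            spike_train_logdensity(wp, X, Y, window, params)
            - spike_train_logdensity(wm, X, Y, window, params)
        ) / (2 * eps)
        assert grad == pytest.approx(fd, abs=1e-4)


def test_step_neuron_near_deterministic_limits(params):
    rng = np.random.default_rng(0)
    n = 4
    state = NeuronState.zeros(n, params)
    w = np.zeros(n)
    # no input, resting potential far below threshold: essentially never spikes
    spikes = 0
    for _ in range(200):
        state, spiked = step_neuron(state, w, np.zeros(n), params, rng)
        spikes += spiked
    assert spikes == 0
    # huge weight and an input spike: fires promptly
    state = NeuronState.zeros(n, params)
    w = np.full(n, 1e3)
    fired = False
    inc = np.ones(n)
    for _ in range(10):
        state, spiked = step_neuron(state, w, inc, params, rng)
        inc = np.zeros(n)
        fired = fired or spiked
    assert fired


def test_step_neuron_shape_validation(params):
    state = NeuronState.zeros(3, params)
    with pytest.raises(ValueError):
        step_neuron(state, np.zeros(2), np.zeros(3), params, np.random.default_rng())


def test_reset_hyperpolarizes(params):
    """A forced postsynaptic spike lowers the subsequent potential."""
    _, window, X, w = _toy_instance(3, n_bins=12)
    from poprl.neuron import _u_trajectory

    u_quiet, _, _ = _u_trajectory(w, X, [], window, params=NeuronParams())
    u_spike, _, _ = _u_trajectory(w, X, [4.5], window, params=NeuronParams())
    assert np.all(u_spike[5:] <= u_quiet[5:])
    assert u_spike[5] < u_quiet[5]
    # potential in the spike bin itself is evaluated before the reset
    assert u_spike[4] == u_quiet[4]
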