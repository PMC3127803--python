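"""Unit tests for metrics, runners, and validation oracles."""

import json
import math

import numpy as np
import pytest

from poprl.experiments import (
    AssociationConfig,
    BanditConfig,
    GradientCheckInstance,
    bandit_value_oracle,
    ewma,
    expected_reward_exact,
    gradient_check,
    init_weights,
    optimal_policy_search,
    run_association,
    run_bandit_sarsa,
    run_track_sarsa,
    trials_to_criterion,
)
from poprl.neuron import NeuronParams
from poprl.tasks import BanditSchedule


# -- metrics -----------------------------------------------------------------

def test_ewma_properties():
    # constant series maps to itself
    np.testing.assert_allclose(ewma([3.0] * 10, 0.1), np.full(10, 3.0))
    # smoothing = 1 is the identity
    x = np.array([1.0, -2.0, 0.5])
    np.testing.assert_allclose(ewma(x, 1.0), x)
    # impulse response is a geometric decay
    imp = ewma([1.0, 0, 0, 0, 0], 0.25, init=0.0)
    np.testing.assert_allclose(imp, 0.25 * 0.75 ** np.arange(5))
    with pytest.raises(ValueError):
        ewma([1.0], 0.0)


def test_trials_to_criterion():
    curve = [0.5, 0.6, 0.81, 0.7, 0.9]
    assert trials_to_criterion(curve, 0.8) == 2
    assert trials_to_criterion(curve, 0.95) is None


def test_init_weights():
    assert np.all(init_weights(5, 4, sd=0.0) == 0.0)
    a = init_weights(10, 10, rng=np.random.default_rng(3))
    b = init_weights(10, 10, rng=np.random.default_rng(3))
    np.testing.assert_array_equal(a, b)
    big = init_weights(100, 100, sd=4.0, rng=np.random.default_rng(4))
    assert abs(big.mean()) < 0.2
    assert abs(big.std(ddof=1) - 4.0) < 0.2


# -- association runner ------------------------------------------------------

def test_association_run_smoke_and_log_echo():
    cfg = AssociationConfig(n_trials=30, n_neurons=4, n_afferents=30,
                            duration=100.0, iti=100.0)
    res = run_association(cfg, np.random.default_rng(0))
    assert len(res.decisions) == 30
    assert set(np.unique(res.decisions)) <= {-1, 1}
    assert res.correct.dtype == bool
    assert np.all((res.smoothed >= 0) & (res.smoothed <= 1))
    echo = json.loads(res.config_json)
    assert echo["n_trials"] == 30 and echo["n_neurons"] == 4


def test_association_two_seeds_distinct():
    cfg = AssociationConfig(n_trials=20, n_neurons=4, n_afferents=30,
                            duration=100.0, iti=100.0)
    a = run_association(cfg, np.random.default_rng(1))
    b = run_association(cfg, np.random.default_rng(2))
    assert a.config_json == b.config_json
    assert not np.array_equal(a.decisions, b.decisions) or not np.array_equal(
        a.rewards, b.rewards
    )


def test_association_zero_learning_rate_flat():
    """No plasticity: accuracy has no trend (slope CI contains 0)."""
    cfg = AssociationConfig(n_trials=400, n_neurons=6, n_afferents=40,
                            duration=100.0, iti=100.0, eta=0.0)
    res = run_association(cfg, np.random.default_rng(5))
    y = res.correct.astype(float)
    x = np.arange(y.size, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    se = math.sqrt(resid.var(ddof=2) / ((x - x.mean()) ** 2).sum())
    assert abs(slope) < 3 * se


# -- SARSA baselines ---------------------------------------------------------

def test_bandit_sarsa_memoryless_melioration():
    """Softmax SARSA(0) on one state is melioration: it matches per-arm
    payoffs and at moderate beta over-prefers neither arm extremely."""
    r, se, p_int, q = run_bandit_sarsa(beta=1.0, n_trials=20000,
                                       rng=np.random.default_rng(0))
    assert 0.0 < p_int < 1.0
    assert r > 0.1  # above the floor of pure noise
    # learned Q of the fixed arm is its exact payoff
    assert q[-1] == pytest.approx(BanditSchedule().r_fix, abs=0.02)


def test_track_sarsa_learns_with_annealing():
    rewards, shortcut, q = run_track_sarsa(
        n_episodes=3000, rng=np.random.default_rng(1), lam=1.0, gamma=0.9,
        eps=0.2, eps_final=0.01,
    )
    assert rewards[-500:].mean() > 0.9


# -- oracles -----------------------------------------------------------------

def test_bandit_value_oracle_pure_policies():
    s = BanditSchedule()
    rng = np.random.default_rng(2)
    res0 = bandit_value_oracle(0.0, s, 2000, rng)
    assert res0["avg_reward"] == pytest.approx(s.r_fix)  # exact, no variance
    res1 = bandit_value_oracle(1.0, s, 20000, rng)
    assert abs(res1["avg_reward"] - s.expected_reward(1.0)) < 3 * res1["avg_reward_se"]
    # Q_I under p=1 equals the closed-form intermittent value
    assert abs(res1["q_int"] - s.intermittent_value(1.0)) < 3 * res1["q_int_se"]


def test_optimal_policy_search_degenerate_cases():
    rng = np.random.default_rng(3)
    # reward only on the fixed arm: p* = 0
    s = BanditSchedule(r_int=0.0, r_fix=0.5)
    p_star, r_star, se, grid, rewards = optimal_policy_search(s, rng, n_grid=11, n_steps=2000)
    assert p_star == 0.0 and r_star == pytest.approx(0.5)
    # always-baited arm paying more than fixed: p* = 1
    s = BanditSchedule(min_interval=1, max_interval=1, r_int=1.0, r_fix=0.01)
    # note: with a 1-step interval the arm is rebaited after one step
    p_star, r_star, *_ = optimal_policy_search(s, rng, n_grid=11, n_steps=4000)
    assert p_star == 1.0


def test_gradient_check_zero_gradient_case():
    """Reward independent of the decision: gradient and rule update vanish."""
    rng = np.random.default_rng(4)
    neuron = NeuronParams(rho0=30.0, theta=0.0, delta_u=0.5)
    raster = (rng.random((2, 8)) < 0.3).astype(np.uint8)
    inst = GradientCheckInstance(
        raster=raster, weights=np.zeros(2), neuron=neuron,
        reward_plus=1.0, reward_minus=1.0,
    )
    report = gradient_check(inst, n_episodes=20000, rng=rng)
    np.testing.assert_allclose(report["fd_gradient"], 0.0, atol=1e-8)
    assert np.all(np.abs(report["rule_update"]) <= 3 * report["rule_se"] + 1e-12)


def test_gradient_check_symmetric_afferents():
    """Two identical afferents receive equal gradient components."""
    rng = np.random.default_rng(5)
    neuron = NeuronParams(rho0=30.0, theta=0.0, delta_u=0.5)
    row = (rng.random(8) < 0.4).astype(np.uint8)
    raster = np.vstack([row, row])
    inst = GradientCheckInstance(raster=raster, weights=np.array([0.3, 0.3]), neuron=neuron)
    report = gradient_check(inst, n_episodes=20000, rng=rng)
    fd = report["fd_gradient"]
    assert fd[0] == pytest.approx(fd[1], rel=1e-6)


def test_expected_reward_exact_bounds():
    rng = np.random.default_rng(6)
    neuron = NeuronParams(rho0=30.0, theta=0.0, delta_u=0.5)
    raster = (rng.random((2, 6)) < 0.4).astype(np.uint8)
    inst = GradientCheckInstance(raster=raster, weights=rng.normal(size=2), neuron=neuron)
    r = expected_reward_exact(inst, inst.weights)
    assert 0.0 <= r <= 1.0
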