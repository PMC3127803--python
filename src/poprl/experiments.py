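"""Experiment runners, metrics, and validation oracles.

Provides the task loops coupling :class:`~poprl.engine.PopulationLearner` to
the environments, the SARSA baselines on the same tasks, the Monte-Carlo
value oracle and optimal-policy grid search for the bandit, and the
finite-difference gradient check that validates the plasticity cascade as a
policy-gradient rule.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .decision import decision_probability
from .engine import PopulationLearner
from .modulators import ModulatorParams
from .neuron import NeuronParams
from .plasticity import CascadeParams
from .stimuli import generate_pattern, jitter_pattern, pattern_to_raster
from .tasks import AssociationTask, BanditSchedule, BanditTask, PositionEncoder, TrackTask
from .td import TERMINAL, QTable, epsilon_greedy, sarsa_update, softmax_policy

__all__ = [
    "init_weights",
    "ewma",
    "trials_to_criterion",
    "AssociationConfig",
    "BanditConfig",
    "TrackConfig",
    "RunResult",
    "run_association",
    "run_bandit",
    "run_track",
    "run_bandit_sarsa",
    "run_track_sarsa",
    "gradient_check",
    "bandit_value_oracle",
    "optimal_policy_search",
]


# ---------------------------------------------------------------------------
# small utilities
# ---------------------------------------------------------------------------

def init_weights(n_afferents: int, n_neurons: int, sd: float = 4.0,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Initial synaptic strengths: i.i.d. zero-mean Gaussians of the given SD."""
    rng = np.random.default_rng() if rng is None else rng
    return rng.normal(0.0, sd, size=(n_neurons, n_afferents))


def ewma(series, smoothing: float, init: float | None = None) -> np.ndarray:
    """Exponentially weighted moving average, y_t = (1-s) y_{t-1} + s x_t."""
    if not (0 < smoothing <= 1):
        raise ValueError("smoothing must lie in (0, 1]")
    x = np.asarray(series, dtype=float)
    y = np.empty_like(x)
    prev = x[0] if init is None else init
    for i, v in enumerate(x):
        prev = (1.0 - smoothing) * prev + smoothing * v
        y[i] = prev
    return y


def trials_to_criterion(curve, criterion: float) -> int | None:
    """Index of the first point at or above the criterion, or None."""
    idx = np.flatnonzero(np.asarray(curve) >= criterion)
    return int(idx[0]) if idx.size else None


# ---------------------------------------------------------------------------
# configs and run logs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationConfig:
    """Stimulus-response association experiment (delayed reinforcement)."""

    n_stimuli: int = 10
    n_neurons: int = 20
    n_afferents: int = 80
    duration: float = 500.0
    rate: float = 6.0
    jitter_sd: float = 2.0
    delay: float = 0.0
    delay_range: tuple | None = None
    n_trials: int = 3000
    iti: float = 600.0  # post-decision feedback epoch (no stimulus), ms
    eta: float = 1.0
    gain: float = 2.0
    connectivity: float = 0.5
    init_sd: float = 4.0
    ewma_smoothing: float = 0.02
    stop_at: float | None = None  # optional EWMA-accuracy early-stop criterion
    mode: str = "biological"
    neuron: NeuronParams = field(default_factory=NeuronParams)
    cascade: CascadeParams = field(default_factory=CascadeParams)
    modulator: ModulatorParams = field(default_factory=ModulatorParams)


@dataclass(frozen=True)
class BanditConfig:
    """Two-armed bandit with the variable-interval intermittent arm."""

    n_neurons: int = 10
    n_afferents: int = 80
    duration: float = 500.0
    rate: float = 6.0
    jitter_sd: float = 2.0
    n_trials: int = 8000
    iti: float = 600.0
    eta: float = 0.1
    gain: float = 1.0
    connectivity: float = 0.5
    init_sd: float = 4.0
    ewma_smoothing: float = 0.02
    schedule: BanditSchedule = field(default_factory=BanditSchedule)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    cascade: CascadeParams = field(default_factory=CascadeParams)
    modulator: ModulatorParams = field(default_factory=ModulatorParams)


@dataclass(frozen=True)
class TrackConfig:
    """Linear-track navigation with the population learner."""

    n_neurons: int = 20
    duration: float = 500.0
    rate: float = 6.0
    jitter_sd: float = 2.0
    n_episodes: int = 2000
    max_steps: int = 50
    iti: float = 600.0
    eta: float = 0.1
    gain: float = 1.0
    connectivity: float = 0.5
    init_sd: float = 4.0
    ewma_smoothing: float = 0.05
    memory: bool = True
    neuron: NeuronParams = field(default_factory=NeuronParams)
    cascade: CascadeParams = field(default_factory=CascadeParams)
    modulator: ModulatorParams = field(default_factory=ModulatorParams)


def _config_json(config) -> str:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    return json.dumps(asdict(config), default=default, sort_keys=True)


@dataclass
class RunResult:
    """Per-trial (or per-episode) logs of one run plus smoothed metrics."""

    decisions: np.ndarray
    rewards: np.ndarray
    correct: np.ndarray | None
    smoothed: np.ndarray
    config_json: str
    extras: dict = field(default_factory=dict)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["config"] = self.config_json
            f.create_dataset("decisions", data=self.decisions)
            f.create_dataset("rewards", data=self.rewards)
            if self.correct is not None:
                f.create_dataset("correct", data=self.correct.astype(np.uint8))
            f.create_dataset("smoothed", data=self.smoothed)
            for k, v in self.extras.items():
                f.create_dataset(k, data=np.asarray(v))


# ---------------------------------------------------------------------------
# population-learner task loops
# ---------------------------------------------------------------------------

def _make_learner(config, n_inputs: int, rng: np.random.Generator,
                  mode: str = "biological") -> PopulationLearner:
    cascade = replace(config.cascade, learning_rate=config.eta)
    return PopulationLearner(
        n_inputs=n_inputs,
        n_neurons=config.n_neurons,
        neuron=config.neuron,
        cascade=cascade,
        modulator=config.modulator,
        gain=config.gain,
        connectivity=config.connectivity,
        init_sd=config.init_sd,
        mode=mode,
        rng=rng,
    )


def run_association(config: AssociationConfig, rng: np.random.Generator) -> RunResult:
    """Population learning of stimulus-response associations.

    A fresh set of frozen stimulus patterns and initial weights is drawn per
    run.  Rewards of +/-1 are delivered with the configured delay while the
    task keeps presenting further stimuli, so the learner must bridge the gap
    with its eligibility cascade.
    """
    patterns = [
        generate_pattern(config.n_afferents, config.duration, config.rate, rng, label=k)
        for k in range(config.n_stimuli)
    ]
    task = AssociationTask(
        n_stimuli=config.n_stimuli,
        delay=config.delay,
        delay_range=config.delay_range,
        rng=rng,
    )
    learner = _make_learner(config, config.n_afferents, rng, config.mode)

    decisions = np.zeros(config.n_trials, dtype=np.int8)
    rewards = np.zeros(config.n_trials)
    correct = np.zeros(config.n_trials, dtype=bool)
    acc = 0.5  # EWMA of correctness, seeded at chance
    smoothed = np.zeros(config.n_trials)
    n_done = config.n_trials
    for k in range(config.n_trials):
        stim = jitter_pattern(patterns[task.current], config.jitter_sd, rng)
        event = learner.present(stim)
        _, events, ok = task.step(event.D, learner.t)
        for t_due, value in events:
            learner.deliver_reward(value, t_due)
        learner.relax(config.iti)
        decisions[k] = event.D
        rewards[k] = events[0][1]
        correct[k] = ok
        acc = (1 - config.ewma_smoothing) * acc + config.ewma_smoothing * ok
        smoothed[k] = acc
        if config.stop_at is not None and acc >= config.stop_at:
            n_done = k + 1
            break
    sl = slice(0, n_done)
    ttc = trials_to_criterion(smoothed[sl], config.stop_at) if config.stop_at else None
    return RunResult(
        decisions=decisions[sl],
        rewards=rewards[sl],
        correct=correct[sl],
        smoothed=smoothed[sl],
        config_json=_config_json(config),
        extras={"trials_to_criterion": -1 if ttc is None else ttc,
                "final_weights": learner.w},
    )


def run_bandit(config: BanditConfig, rng: np.random.Generator) -> RunResult:
    """Population learning on the variable-interval two-armed bandit.

    One and the same stimulus is presented on every trial (the learner has no
    access to its decision history), so a good policy is necessarily
    stochastic; D = +1 chooses the intermittent arm.
    """
    pattern = generate_pattern(config.n_afferents, config.duration, config.rate, rng)
    task = BanditTask(schedule=config.schedule, rng=rng)
    learner = _make_learner(config, config.n_afferents, rng)

    decisions = np.zeros(config.n_trials, dtype=np.int8)
    rewards = np.zeros(config.n_trials)
    for k in range(config.n_trials):
        stim = jitter_pattern(pattern, config.jitter_sd, rng)
        event = learner.present(stim)
        r = task.step(event.D)
        learner.deliver_reward(r, learner.t)
        learner.relax(config.iti)
        decisions[k] = event.D
        rewards[k] = r
    smoothed = ewma(rewards, config.ewma_smoothing, init=0.0)
    return RunResult(
        decisions=decisions,
        rewards=rewards,
        correct=None,
        smoothed=smoothed,
        config_json=_config_json(config),
        extras={"p_int_curve": ewma((decisions == 1).astype(float),
                                    config.ewma_smoothing, init=0.5)},
    )


def run_track(config: TrackConfig, rng: np.random.Generator) -> RunResult:
    """Population learning on the linear track (episodic)."""
    encoder = PositionEncoder(
        duration=config.duration, rate=config.rate, memory=config.memory, rng=rng
    )
    n_inputs = 80
    task = TrackTask()
    learner = _make_learner(config, n_inputs, rng)

    ep_rewards = np.zeros(config.n_episodes)
    ep_steps = np.zeros(config.n_episodes, dtype=int)
    for ep in range(config.n_episodes):
        task.reset()
        r_total = 0.0
        while True:
            stim = jitter_pattern(
                encoder.encode(task.position, task.previous), config.jitter_sd, rng
            )
            event = learner.present(stim)
            terminal, r = task.step(event.D)
            if r:
                learner.deliver_reward(r, learner.t)
                r_total += r
            learner.relax(config.iti)
            if terminal or task.steps >= config.max_steps:
                break
        ep_rewards[ep] = r_total
        ep_steps[ep] = task.steps
    smoothed = ewma(ep_rewards, config.ewma_smoothing, init=0.0)
    return RunResult(
        decisions=np.zeros(config.n_episodes, dtype=np.int8),
        rewards=ep_rewards,
        correct=None,
        smoothed=smoothed,
        config_json=_config_json(config),
        extras={"steps": ep_steps},
    )


# ---------------------------------------------------------------------------
# SARSA baselines on the same tasks
# ---------------------------------------------------------------------------

def run_bandit_sarsa(
    beta: float,
    n_trials: int,
    rng: np.random.Generator,
    schedule: BanditSchedule | None = None,
    alpha: float = 0.1,
    gamma: float = 0.0,
    asymptotic_window: int | None = None,
):
    """Memoryless softmax SARSA on the bandit.

    Returns ``(mean asymptotic reward, SE, realized p_int, learned Q)`` where
    ``learned Q`` maps each arm to its Q value *time-averaged over the
    asymptotic window* (a constant step size keeps the instantaneous Q
    fluctuating around the arm's true mean payoff; the time average removes
    that fluctuation).  With a single state and gamma = 0 the update reduces
    to a running average of each arm's observed payoff, whose softmax readout
    enacts melioration rather than global reward optimization.
    """
    schedule = BanditSchedule() if schedule is None else schedule
    task = BanditTask(schedule=schedule, rng=rng)
    q = QTable(actions=(-1, 1))
    s = "memoryless"
    rewards = np.zeros(n_trials)
    choices = np.zeros(n_trials, dtype=np.int8)
    win = asymptotic_window or n_trials // 2
    q_sums = {a: 0.0 for a in q.actions}
    for k in range(n_trials):
        a = softmax_policy(q, s, beta, rng)
        r = task.step(a)
        q.values[(s, a)] += alpha * (r + gamma * 0.0 - q.values[(s, a)])
        rewards[k] = r
        choices[k] = a
        if k >= n_trials - win:
            for act in q.actions:
                q_sums[act] += q.values[(s, act)]
    tail_r = rewards[-win:]
    tail_c = choices[-win:] == 1
    se = tail_r.std(ddof=1) / math.sqrt(win)
    return (
        float(tail_r.mean()),
        float(se),
        float(tail_c.mean()),
        {a: q_sums[a] / win for a in q.actions},
    )


def run_track_sarsa(
    n_episodes: int,
    rng: np.random.Generator,
    lam: float = 0.0,
    alpha: float = 0.1,
    gamma: float = 0.9,
    eps: float = 0.1,
    eps_final: float | None = None,
    max_steps: int = 500,
):
    """SARSA(lambda) on the track with memory-1 states (previous, current).

    ``eps_final`` enables linear annealing of the exploration rate over the
    first half of training (used by the SARSA(1) convergence runs; the
    instability runs keep eps constant).  Returns per-episode rewards and the
    per-episode trajectory of the shortcut value Q((_1_2), left).
    """
    q = QTable(actions=(-1, 1))
    task = TrackTask()
    ep_rewards = np.zeros(n_episodes)
    shortcut_value = np.zeros(n_episodes)
    half = max(1, n_episodes // 2)
    for ep in range(n_episodes):
        if eps_final is None:
            eps_ep = eps
        else:
            frac = min(1.0, ep / half)
            eps_ep = eps + (eps_final - eps) * frac
        task.reset()
        q.clear_traces()
        s = (None, task.position)
        a = epsilon_greedy(q, s, eps_ep, rng)
        total = 0.0
        while True:
            terminal, r = task.step(a)
            total += r
            if terminal or task.steps >= max_steps:
                sarsa_update(q, (s, a, r, TERMINAL, None), alpha, gamma, lam)
                break
            s_next = (task.previous, task.position)
            a_next = epsilon_greedy(q, s_next, eps_ep, rng)
            sarsa_update(q, (s, a, r, s_next, a_next), alpha, gamma, lam)
            s, a = s_next, a_next
        ep_rewards[ep] = total
        shortcut_value[ep] = q.values[((1, 2), -1)]
    return ep_rewards, shortcut_value, q


# ---------------------------------------------------------------------------
# bandit value oracle and optimal-policy search
# ---------------------------------------------------------------------------

def bandit_value_oracle(
    p: float,
    schedule: BanditSchedule,
    n_steps: int,
    rng: np.random.Generator,
):
    """Monte-Carlo estimate of the long-run performance of the memoryless
    stochastic policy choosing the intermittent arm with probability p.

    Returns a dict with the average reward per decision, its SE, the value of
    an intermittent choice Q_I(p) (mean payoff per intermittent pick) and its
    SE.
    """
    task = BanditTask(schedule=schedule, rng=rng)
    rewards = np.zeros(n_steps)
    int_rewards = []
    for k in range(n_steps):
        a = 1 if rng.random() < p else -1
        r = task.step(a)
        rewards[k] = r
        if a == 1:
            int_rewards.append(r)
    int_rewards = np.asarray(int_rewards)
    out = {
        "avg_reward": float(rewards.mean()),
        "avg_reward_se": float(rewards.std(ddof=1) / math.sqrt(n_steps)),
        "n_intermittent": int(int_rewards.size),
    }
    if int_rewards.size > 1:
        out["q_int"] = float(int_rewards.mean())
        out["q_int_se"] = float(int_rewards.std(ddof=1) / math.sqrt(int_rewards.size))
    else:
        out["q_int"] = float("nan")
        out["q_int_se"] = float("nan")
    return out


def optimal_policy_search(
    schedule: BanditSchedule,
    rng: np.random.Generator,
    n_grid: int = 101,
    n_steps: int = 20000,
):
    """Grid search over the memoryless choice probability p.

    Returns (p_star, reward_star, se_star, grid, rewards): the probability
    maximizing the Monte-Carlo estimated long-run reward per decision.
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    rewards = np.zeros(n_grid)
    ses = np.zeros(n_grid)
    for i, p in enumerate(grid):
        res = bandit_value_oracle(float(p), schedule, n_steps, rng)
        rewards[i] = res["avg_reward"]
        ses[i] = res["avg_reward_se"]
    best = int(np.argmax(rewards))
    return float(grid[best]), float(rewards[best]), float(ses[best]), grid, rewards


# ---------------------------------------------------------------------------
# gradient-check harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientCheckInstance:
    """A deliberately tiny, enumerable learning problem.

    One escape-noise neuron, a handful of afferents and time bins, immediate
    reward at stimulus end; reward depends only on the decision.  Small
    enough that the expected reward (and hence its weight-gradient) can be
    computed exactly by enumerating all postsynaptic spike patterns.
    """

    raster: np.ndarray  # (n_afferents, n_bins) presynaptic spikes
    weights: np.ndarray
    neuron: NeuronParams
    gain: float = 1.0
    reward_plus: float = 1.0
    reward_minus: float = 0.0

    @property
    def n_bins(self) -> int:
        return self.raster.shape[1]


def _instance_dynamics(inst: GradientCheckInstance, w: np.ndarray):
    """Per-bin e1 for every afferent (independent of Y) given the raster."""
    p = inst.neuron
    nb = inst.n_bins
    decay_s, decay_m = math.exp(-p.dt / p.tau_s), math.exp(-p.dt / p.tau_m)
    zf = np.zeros(inst.raster.shape[0])
    zs = np.zeros(inst.raster.shape[0])
    e1 = np.zeros((nb, inst.raster.shape[0]))
    for t in range(nb):
        zf *= decay_s
        zs *= decay_m
        zf += inst.raster[:, t]
        zs += inst.raster[:, t]
        e1[t] = p.kernel_norm * (zs - zf)
    return e1


def expected_reward_exact(inst: GradientCheckInstance, w: np.ndarray) -> float:
    """Exact E[reward] by enumeration over all 2^n_bins spike patterns."""
    p = inst.neuron
    nb = inst.n_bins
    e1 = _instance_dynamics(inst, w)
    decay_m = math.exp(-p.dt / p.tau_m)
    total = 0.0
    for code in range(1 << nb):
        prob = 1.0
        reset = 0.0
        spiked_any = False
        for t in range(nb):
            reset *= decay_m
            u = p.u_rest + float(w @ e1[t]) - reset
            rho = p.rho0_ms * math.exp(min((u - p.theta) / p.delta_u, 60.0))
            ps = -math.expm1(-rho * p.dt)
            if (code >> t) & 1:
                prob *= ps
                reset += p.reset_amp
                spiked_any = True
            else:
                prob *= 1.0 - ps
            if prob == 0.0:
                break
        if prob == 0.0:
            continue
        A = 1.0 if spiked_any else -1.0
        rbar = (
            decision_probability(A, 1, inst.gain) * inst.reward_plus
            + decision_probability(A, -1, inst.gain) * inst.reward_minus
        )
        total += prob * rbar
    return total


def _simulate_rule_updates(inst: GradientCheckInstance, n_episodes: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Vectorized Monte-Carlo episodes of the idealized rule.

    Per episode: simulate the neuron, accumulate e2 = integral(PS * e1)
    (the characteristic eligibility), read out chi and the decision, apply
    the decision pulse and the immediate reward pulse.  Returns the
    per-episode weight updates, shape (n_episodes, n_afferents).
    """
    p = inst.neuron
    nb = inst.n_bins
    n_aff = inst.raster.shape[0]
    e1 = _instance_dynamics(inst, inst.weights)
    decay_m = math.exp(-p.dt / p.tau_m)

    reset = np.zeros(n_episodes)
    spiked_any = np.zeros(n_episodes, dtype=bool)
    e2 = np.zeros((n_episodes, n_aff))
    base = p.u_rest + e1 @ inst.weights  # (nb,)
    for t in range(nb):
        reset *= decay_m
        u = base[t] - reset
        rho = p.rho0_ms * np.exp(np.clip((u - p.theta) / p.delta_u, None, 60.0))
        x = rho * p.dt
        prob = -np.expm1(-x)
        spiked = rng.random(n_episodes) < prob
        safe = np.where(prob > 0, prob, 1.0)
        ps = np.where(spiked, rho * np.exp(-x) / safe, -rho) / p.delta_u
        e2 += ps[:, None] * e1[t][None, :] * p.dt
        reset[spiked] += p.reset_amp
        spiked_any |= spiked

    chi = np.where(spiked_any, 1.0, -1.0)
    A = chi  # single neuron: A = chi / sqrt(1)
    p_plus = 1.0 / (1.0 + np.exp(-inst.gain * A))
    D = np.where(rng.random(n_episodes) < p_plus, 1.0, -1.0)
    p_taken = np.where(D > 0, p_plus, 1.0 - p_plus)
    f = inst.gain * D * (1.0 - p_taken)
    R = np.where(D > 0, inst.reward_plus, inst.reward_minus)
    return (R * f * chi)[:, None] * e2


def gradient_check(
    inst: GradientCheckInstance,
    n_episodes: int = 100_000,
    rng: np.random.Generator | None = None,
    fd_step: float = 1e-3,
):
    """Compare the plasticity rule's mean update to the reward gradient.

    The finite-difference gradient of the exactly enumerated expected reward
    is the oracle; the rule's mean update is a Monte-Carlo average over
    episodes.  Reports the two vectors, componentwise standard errors, the
    proportionality constant fitted through the origin, componentwise
    z-scores of the residuals, and the cosine similarity.
    """
    rng = np.random.default_rng() if rng is None else rng
    w0 = inst.weights.astype(float)
    n_aff = w0.size

    fd = np.zeros(n_aff)
    for i in range(n_aff):
        wp, wm = w0.copy(), w0.copy()
        wp[i] += fd_step
        wm[i] -= fd_step
        fd[i] = (expected_reward_exact(inst, wp) - expected_reward_exact(inst, wm)) / (
            2 * fd_step
        )

    updates = _simulate_rule_updates(inst, n_episodes, rng)
    mean_update = updates.mean(axis=0)
    se = updates.std(axis=0, ddof=1) / math.sqrt(n_episodes)

    denom = float(fd @ fd)
    slope = float(mean_update @ fd) / denom if denom > 0 else float("nan")
    resid = mean_update - slope * fd
    z = np.divide(resid, se, out=np.zeros_like(resid), where=se > 0)
    norm = np.linalg.norm(mean_update) * np.linalg.norm(fd)
    cosine = float(mean_update @ fd / norm) if norm > 0 else float("nan")
    return {
        "fd_gradient": fd,
        "rule_update": mean_update,
        "rule_se": se,
        "slope": slope,
        "z_scores": z,
        "cosine": cosine,
        "n_episodes": n_episodes,
    }
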