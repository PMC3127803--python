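"""Tabular SARSA(lambda) baseline with epsilon-greedy and softmax policies.

Used to contrast temporal-difference value learning with the population
policy-gradient rule on tasks that violate the Markov assumption.  States are
arbitrary hashable ids; history-augmented state constructions are provided
for the bandit (a window of past decision/outcome pairs) and the track
(previous/current position pairs).
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QTable",
    "sarsa_update",
    "softmax_policy",
    "epsilon_greedy",
    "HistoryState",
    "make_history_state",
]

TERMINAL = "__terminal__"


@dataclass
class QTable:
    """State-action values plus eligibility traces (for lambda > 0)."""

    actions: tuple = (-1, 1)
    values: dict = field(default_factory=lambda: defaultdict(float))
    traces: dict = field(default_factory=lambda: defaultdict(float))

    def q(self, state, action) -> float:
        if state == TERMINAL:
            return 0.0  # terminal states have value zero by definition
        return self.values[(state, action)]

    def clear_traces(self) -> None:
        self.traces.clear()


def sarsa_update(
    q: QTable,
    transition,
    alpha: float,
    gamma: float,
    lam: float = 0.0,
) -> QTable:
    """On-policy TD update for one transition (s, a, r, s', a').

    ``s'`` may be :data:`TERMINAL`, in which case Q(s', .) = 0.  For
    lambda = 0 only (s, a) is updated; for lambda > 0 an accumulating
    eligibility trace spreads the TD error over recently visited pairs
    (lambda = 1 with gamma = 1 amounts to incremental Monte-Carlo return
    estimation).
    """
    s, a, r, s_next, a_next = transition
    if s == TERMINAL:
        raise ValueError("cannot update from a terminal state")
    delta = r + gamma * q.q(s_next, a_next) - q.q(s, a)
    if lam == 0.0:
        q.values[(s, a)] += alpha * delta
        return q
    q.traces[(s, a)] += 1.0
    decay = gamma * lam
    for key in list(q.traces):
        q.values[key] += alpha * delta * q.traces[key]
        q.traces[key] *= decay
        if q.traces[key] < 1e-12:
            del q.traces[key]
    return q


def softmax_policy(q: QTable, state, beta: float, rng: np.random.Generator):
    """Boltzmann action selection, P(a) proportional to exp(beta Q(s,a))."""
    if beta < 0:
        raise ValueError("inverse temperature must be non-negative")
    vals = np.array([q.q(state, a) for a in q.actions])
    z = beta * (vals - vals.max())
    p = np.exp(z)
    p /= p.sum()
    return q.actions[rng.choice(len(q.actions), p=p)]


def epsilon_greedy(q: QTable, state, eps: float, rng: np.random.Generator):
    """Greedy with probability 1 - eps, uniform otherwise; ties uniform."""
    if not (0 <= eps <= 1):
        raise ValueError("eps must lie in [0, 1]")
    if rng.random() < eps:
        return q.actions[rng.integers(len(q.actions))]
    vals = np.array([q.q(state, a) for a in q.actions])
    best = np.flatnonzero(vals == vals.max())
    return q.actions[best[rng.integers(best.size)]]


@dataclass
class HistoryState:
    """Sliding window of the last ``depth`` (decision, outcome) pairs."""

    depth: int
    window: deque = field(init=False)

    def __post_init__(self) -> None:
        self.window = deque(maxlen=self.depth if self.depth > 0 else 1)
        if self.depth == 0:
            self.window = deque(maxlen=0)

    def push(self, decision, outcome) -> None:
        if self.depth > 0:
            self.window.append((decision, outcome))

    def state_id(self):
        return make_history_state(self.window, self.depth)


def make_history_state(history, depth: int):
    """Injective encoding of the last ``depth`` (decision, outcome) pairs.

    ``depth`` = 0 collapses everything onto a single state (the memoryless
    learner).  For the 12-step bandit history the reachable id space is
    bounded by (2 decisions x 2 outcomes)^12 = 4^12 states.
    """
    if depth == 0:
        return "memoryless"
    items = tuple(history)[-depth:]
    return items
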