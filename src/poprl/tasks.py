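"""Task environments: delayed-reinforcement association, variable-interval
two-armed bandit, and a linear-track navigation task.

All three tasks share the binary decision interface D in {-1, +1} and emit
reward *events* (value, delivery time) rather than instantaneous scalars, so
reinforcement can be arbitrarily delayed relative to the decision that earned
it.  The bandit and the track are deliberately non-Markovian with respect to
the stimulus shown to the learner.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .stimuli import StimulusPattern, generate_pattern

__all__ = [
    "AssociationTask",
    "BanditSchedule",
    "BanditTask",
    "TrackTask",
    "PositionEncoder",
    "track_shortest_rewarded_path",
]


# ---------------------------------------------------------------------------
# stimulus-response association with delayed reinforcement
# ---------------------------------------------------------------------------

@dataclass
class AssociationTask:
    """Operant-conditioning task: each stimulus has one correct decision.

    ``n_stimuli`` stimuli are presented in random order; a correct decision
    queues reward ``+reward_magnitude`` and an incorrect one
    ``-reward_magnitude``, delivered ``delay`` ms after the decision (a fixed
    number, or a per-trial draw if ``delay_range`` is given).  Because the
    next stimulus is presented immediately, large delays imply intervening
    decisions that are themselves subject to delayed reinforcement.
    """

    n_stimuli: int = 10
    delay: float = 0.0
    delay_range: tuple | None = None  # (low, high) ms, drawn per trial
    reward_magnitude: float = 1.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    correct: np.ndarray = field(init=False)
    current: int = field(init=False)
    pending: deque = field(init=False, default_factory=deque)

    def __post_init__(self) -> None:
        self.correct = self.rng.choice([-1, 1], size=self.n_stimuli)
        self.current = int(self.rng.integers(self.n_stimuli))

    def _draw_delay(self) -> float:
        if self.delay_range is not None:
            lo, hi = self.delay_range
            return float(self.rng.uniform(lo, hi))
        return self.delay

    def step(self, decision: int, t: float):
        """Register the decision on the current stimulus made at time ``t``.

        Returns ``(next_stimulus_index, events, correct)`` where ``events``
        is a list of (delivery_time, value) reward events queued by this
        decision and ``correct`` flags whether the decision was right.
        """
        ok = decision == self.correct[self.current]
        value = self.reward_magnitude if ok else -self.reward_magnitude
        events = [(t + self._draw_delay(), value)]
        self.current = int(self.rng.integers(self.n_stimuli))
        return self.current, events, bool(ok)


# ---------------------------------------------------------------------------
# two-armed bandit with a variable-interval (baited) arm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BanditSchedule:
    """Variable-interval baiting schedule and reward calibration.

    After the intermittent arm's reward is collected the arm stays un-baited
    for U ~ Uniform{min_interval..max_interval} decision steps and is then
    baited until chosen again.  With the default calibration
    ``r_fix = r_int / (E[U] + 1)`` an always-intermittent policy earns
    exactly the fixed arm's rate, so intermediate choice probabilities are
    required to beat either pure policy.
    """

    min_interval: int = 1
    max_interval: int = 12
    r_int: float = 1.0
    r_fix: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.min_interval <= self.max_interval):
            raise ValueError("need 1 <= min_interval <= max_interval")
        if self.r_fix is None:
            object.__setattr__(self, "r_fix", self.r_int / (self.mean_interval + 1.0))

    @property
    def mean_interval(self) -> float:
        return 0.5 * (self.min_interval + self.max_interval)

    def expected_reward(self, p: float) -> float:
        """Closed-form long-run reward per decision when the intermittent arm
        is chosen i.i.d. with probability p (renewal-reward argument)."""
        if p == 0:
            return self.r_fix
        return (1.0 - p) * self.r_fix + self.r_int * p / (self.mean_interval * p + 1.0)

    def intermittent_value(self, p: float) -> float:
        """Closed-form expected reward per *intermittent choice* under policy p."""
        return self.r_int / (1.0 + self.mean_interval * p)


@dataclass
class BanditTask:
    """State machine for the variable-interval bandit.

    Decision convention: D = +1 chooses the intermittent arm, D = -1 the
    fixed arm.  Each call to :meth:`step` is one decision step; the baiting
    countdown advances at the start of every step.
    """

    schedule: BanditSchedule = field(default_factory=BanditSchedule)
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    baited: bool = True
    countdown: int = 0

    def step(self, decision: int) -> float:
        # baiting clock ticks first: the arm is re-baited after exactly U
        # full un-baited steps
        if not self.baited:
            if self.countdown <= 0:
                self.baited = True
            else:
                self.countdown -= 1
        if decision == 1:  # intermittent arm
            if self.baited:
                self.baited = False
                self.countdown = int(
                    self.rng.integers(self.schedule.min_interval, self.schedule.max_interval + 1)
                )
                return self.schedule.r_int
            return 0.0
        return self.schedule.r_fix


# ---------------------------------------------------------------------------
# linear-track sequential decision task
# ---------------------------------------------------------------------------

@dataclass
class TrackTask:
    """Path-finding on a linear track with positions 0..5.

    An episode starts at position 1; D = -1 moves left, D = +1 moves right.
    Reaching home (position 0) ends the episode, with reward only if
    position 3 was visited at least once on the way; reaching position 5
    ends the episode without reward.  The shortest rewarded episode takes 5
    decisions (1-2-3-2-1-0).
    """

    reward: float = 1.0
    position: int = 1
    previous: int | None = None
    visited3: bool = False
    steps: int = 0

    def reset(self) -> None:
        self.position, self.previous, self.visited3, self.steps = 1, None, False, 0

    def step(self, decision: int):
        """Apply one move.  Returns (terminal, reward_value)."""
        if self.position in (0, 5):
            raise ValueError("episode already terminal; call reset()")
        if decision not in (-1, 1):
            raise ValueError("decision must be -1 (left) or +1 (right)")
        self.previous = self.position
        self.position += 1 if decision == 1 else -1
        self.steps += 1
        if self.position == 3:
            self.visited3 = True
        if self.position == 0:
            return True, (self.reward if self.visited3 else 0.0)
        if self.position == 5:
            return True, 0.0
        return False, 0.0


def track_shortest_rewarded_path() -> int:
    """Breadth-first search for the minimum number of decisions of a rewarded
    episode (an independent check of the task's structure)."""
    start = (1, False)
    frontier = deque([(start, 0)])
    seen = {start}
    while frontier:
        (pos, v3), depth = frontier.popleft()
        for move in (-1, 1):
            np_, nv3 = pos + move, v3 or (pos + move == 3)
            if np_ == 0:
                if nv3:
                    return depth + 1
                continue
            if np_ == 5:
                continue
            nstate = (np_, nv3)
            if nstate not in seen:
                seen.add(nstate)
                frontier.append((nstate, depth + 1))
    raise RuntimeError("no rewarded path exists")


# ---------------------------------------------------------------------------
# position encoding (with and without one-step working memory)
# ---------------------------------------------------------------------------

class PositionEncoder:
    """Frozen pattern banks mapping track positions to stimulus patterns.

    memoryless mode: one 80-train pattern per position.
    memory mode: 50 trains encode the current position, concatenated with 30
    trains encoding the immediately preceding one (a separate "none" bank
    entry covers the episode start, where there is no preceding position).
    """

    def __init__(
        self,
        positions=(0, 1, 2, 3, 4, 5),
        duration: float = 500.0,
        rate: float = 6.0,
        memory: bool = False,
        rng: np.random.Generator | None = None,
        n_current: int = 50,
        n_previous: int = 30,
        n_memoryless: int = 80,
    ) -> None:
        rng = np.random.default_rng() if rng is None else rng
        self.memory = memory
        self.duration = duration
        if memory:
            self.current_bank = {
                p: generate_pattern(n_current, duration, rate, rng, label=("cur", p))
                for p in positions
            }
            prev_keys = list(positions) + [None]
            self.previous_bank = {
                p: generate_pattern(n_previous, duration, rate, rng, label=("prev", p))
                for p in prev_keys
            }
        else:
            self.bank = {
                p: generate_pattern(n_memoryless, duration, rate, rng, label=("pos", p))
                for p in positions
            }

    def encode(self, current: int, previous: int | None = None) -> StimulusPattern:
        if not self.memory:
            return self.bank[current]
        cur = self.current_bank[current]
        prev = self.previous_bank[previous]
        return StimulusPattern(
            [t.copy() for t in cur.trains] + [t.copy() for t in prev.trains],
            self.duration,
            label=(current, previous),
        )
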