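"""Unit tests for the three task environments."""

import math

import numpy as np
import pytest

from poprl.tasks import (
    AssociationTask,
    BanditSchedule,
    BanditTask,
    PositionEncoder,
    TrackTask,
    track_shortest_rewarded_path,
)


# -- association ------------------------------------------------------------

def test_association_reward_signs_and_delay():
    task = AssociationTask(n_stimuli=4, delay=750.0, rng=np.random.default_rng(0))
    cur = task.current
    right = int(task.correct[cur])
    _, events, ok = task.step(right, t=100.0)
    assert ok and events == [(850.0, 1.0)]
    cur = task.current
    wrong = -int(task.correct[cur])
    _, events, ok = task.step(wrong, t=200.0)
    assert not ok and events == [(950.0, -1.0)]


def test_association_random_delay_range():
    task = AssociationTask(delay_range=(100.0, 300.0), rng=np.random.default_rng(1))
    delays = []
    for _ in range(200):
        _, events, _ = task.step(1, t=0.0)
        delays.append(events[0][0])
    delays = np.array(delays)
    assert delays.min() >= 100.0 and delays.max() <= 300.0
    assert delays.std() > 10.0  # actually varies


def test_association_uniform_presentation():
    task = AssociationTask(n_stimuli=5, rng=np.random.default_rng(2))
    seen = [task.current]
    for _ in range(2000):
        nxt, _, _ = task.step(1, 0.0)
        seen.append(nxt)
    counts = np.bincount(seen, minlength=5)
    assert counts.min() > 300  # roughly uniform over 5 stimuli


# -- bandit -----------------------------------------------------------------

def test_bandit_schedule_validation_and_calibration():
    with pytest.raises(ValueError):
        BanditSchedule(min_interval=0)
    with pytest.raises(ValueError):
        BanditSchedule(min_interval=5, max_interval=2)
    s = BanditSchedule()
    assert s.mean_interval == pytest.approx(6.5)
    # calibration: always-intermittent earns exactly the fixed rate
    assert s.r_fix == pytest.approx(s.r_int / 7.5)
    assert s.expected_reward(1.0) == pytest.approx(s.r_fix)
    assert s.expected_reward(0.0) == pytest.approx(s.r_fix)


def test_bandit_fixed_arm_pays_exactly():
    task = BanditTask(rng=np.random.default_rng(3))
    for _ in range(20):
        assert task.step(-1) == task.schedule.r_fix


def test_bandit_baiting_semantics():
    """After collection the arm is un-baited for exactly U steps."""
    rng = np.random.default_rng(4)
    task = BanditTask(rng=rng)
    assert task.step(1) == task.schedule.r_int  # initially baited
    # choose intermittent until rebaited; count zero-reward steps
    runs = []
    zeros = 0
    for _ in range(100_000):
        r = task.step(1)
        if r == 0.0:
            zeros += 1
        else:
            runs.append(zeros)
            zeros = 0
    runs = np.asarray(runs)
    assert runs.min() >= task.schedule.min_interval
    assert runs.max() <= task.schedule.max_interval
    assert runs.max() == task.schedule.max_interval  # attained over 1e5 steps
    # uniform over {1..12}: mean 6.5
    assert abs(runs.mean() - 6.5) < 0.1


def test_bandit_closed_form_against_simulation():
    rng = np.random.default_rng(5)
    s = BanditSchedule()
    for p in (0.25, 0.6):
        task = BanditTask(schedule=s, rng=rng)
        n = 200_000
        total = 0.0
        for _ in range(n):
            a = 1 if rng.random() < p else -1
            total += task.step(a)
        mean = total / n
        assert mean == pytest.approx(s.expected_reward(p), abs=3e-3)


def test_bandit_stays_baited_until_chosen():
    rng = np.random.default_rng(6)
    task = BanditTask(rng=rng)
    task.step(1)  # collect; now un-baited with some countdown
    for _ in range(50):  # choosing fixed lets the countdown elapse
        task.step(-1)
    assert task.baited  # baited and waiting
    assert task.step(1) == task.schedule.r_int


# -- track ------------------------------------------------------------------

def test_track_shortest_rewarded_path_is_five():
    assert track_shortest_rewarded_path() == 5


def test_track_rewarded_and_unrewarded_episodes():
    task = TrackTask()
    # optimal: 1-2-3-2-1-0, reward 1
    moves = [1, 1, -1, -1, -1]
    rewards = []
    for m in moves:
        terminal, r = task.step(m)
        rewards.append(r)
    assert terminal and rewards[-1] == 1.0 and task.steps == 5
    # shortcut: 1-0 without visiting 3 gives no reward
    task.reset()
    terminal, r = task.step(-1)
    assert terminal and r == 0.0
    # right border: 1-2-3-4-5 terminates unrewarded even though 3 was visited
    task.reset()
    for m in [1, 1, 1, 1]:
        terminal, r = task.step(m)
    assert terminal and r == 0.0


def test_track_error_handling():
    task = TrackTask()
    task.step(-1)  # terminal at 0
    with pytest.raises(ValueError):
        task.step(1)
    task.reset()
    with pytest.raises(ValueError):
        task.step(0)


def test_track_previous_tracking():
    task = TrackTask()
    assert task.previous is None
    task.step(1)
    assert (task.previous, task.position) == (1, 2)
    task.step(-1)
    assert (task.previous, task.position) == (2, 1)


# -- position encoder -------------------------------------------------------

def test_position_encoder_memoryless():
    enc = PositionEncoder(memory=False, rng=np.random.default_rng(7))
    p1 = enc.encode(1)
    p2 = enc.encode(2)
    assert p1.n_trains == 80 and p2.n_trains == 80
    # same position twice: identical frozen pattern
    assert all(np.array_equal(a, b) for a, b in zip(p1.trains, enc.encode(1).trains))
    # previous position is ignored
    assert all(
        np.array_equal(a, b)
        for a, b in zip(enc.encode(1, 0).trains, enc.encode(1, 2).trains)
    )


def test_position_encoder_memory():
    enc = PositionEncoder(memory=True, rng=np.random.default_rng(8))
    a = enc.encode(1, None)   # episode start
    b = enc.encode(1, 2)
    c = enc.encode(1, 0)
    assert a.n_trains == b.n_trains == 80  # 50 current + 30 previous
    # shared current-position bank: first 50 trains identical
    for x, y in zip(a.trains[:50], b.trains[:50]):
        np.testing.assert_array_equal(x, y)
    # different previous position changes the last 30 trains
    assert any(not np.array_equal(x, y) for x, y in zip(b.trains[50:], c.trains[50:]))
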