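"""Shortcut-value inflation: how state aliasing destabilizes SARSA(0).

On the linear track (positions 0..5, start at 1, home at 0) an episode is
rewarded only if position 3 was visited on the way home.  With memory-1
states (previous, current position) the task is not Markovian: the state
(_1_2) -- "at 1, came from 2" -- does not record whether 3 was visited.

Bootstrapping exploits that: Q((_1_2), left) inherits value from the rewarded
returns passing through the same state, inflating the worthless direct-home
shortcut until the greedy policy takes it, performance collapses, the
shortcut value is unlearned, and the cycle repeats.  SARSA(1), which backs up
actual returns instead of bootstrapped estimates, converges cleanly.
"""

import numpy as np

from poprl import ewma, run_track_sarsa

rewards, shortcut, q = run_track_sarsa(
    n_episodes=5000, rng=np.random.default_rng(0), lam=0.0, gamma=0.9, eps=0.1
)
sm = ewma(rewards, 0.05, init=0.0)

print("SARSA(0), memory-1 states:")
print("episode   smoothed reward   Q((_1_2), left)")
for k in range(249, 5000, 250):
    print(f"{k + 1:7d}   {sm[k]:15.3f}   {shortcut[k]:15.3f}")
print(f"\nmax shortcut value: {shortcut.max():.3f} (its true return is 0)")

rewards1, _, _ = run_track_sarsa(
    n_episodes=3000, rng=np.random.default_rng(1), lam=1.0, gamma=0.9,
    eps=0.2, eps_final=0.01,
)
print(f"\nSARSA(1), annealed exploration: final reward/episode = "
      f"{rewards1[-500:].mean():.3f}")
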