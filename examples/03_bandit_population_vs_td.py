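"""Two-armed bandit: global reward optimization versus melioration.

The fixed arm always pays r_fix = r_int / 7.5.  The intermittent arm, once
collected, stays empty for U ~ Uniform{1..12} steps and is then re-baited, so
its per-choice value *grows* the less often it is chosen.  Always choosing
either arm earns exactly r_fix; the optimal memoryless policy picks the
intermittent arm with probability ~0.27, earning ~0.195.

A value learner that estimates per-arm values and then prefers the better arm
("melioration") is driven toward matching (p_int ~ 0.5+), not optimality: the
population policy-gradient learner, in contrast, climbs the global reward.
"""

import numpy as np

from poprl import (
    BanditConfig,
    BanditSchedule,
    optimal_policy_search,
    run_bandit,
    run_bandit_sarsa,
)

schedule = BanditSchedule()
rng = np.random.default_rng(1)

print(f"fixed-arm payoff:           {schedule.r_fix:.4f}")
p_star, r_star, se, _, _ = optimal_policy_search(schedule, rng, n_grid=51, n_steps=20_000)
print(f"optimal memoryless policy:  p_int = {p_star:.2f}, reward = {r_star:.4f} +- {se:.4f}")
print(f"closed-form check:          r(p*) = {schedule.expected_reward(p_star):.4f}\n")

result = run_bandit(BanditConfig(n_trials=6000), np.random.default_rng(1))
half = len(result.rewards) // 2
print("population learner (policy gradient):")
print(f"  asymptotic reward/decision: {result.rewards[half:].mean():.4f}")
print(f"  asymptotic p(intermittent): {np.mean(result.decisions[half:] == 1):.3f}\n")

r, se, p_int, q = run_bandit_sarsa(beta=2.0, n_trials=50_000, rng=np.random.default_rng(2))
print("memoryless softmax TD (melioration):")
print(f"  asymptotic reward/decision: {r:.4f} +- {se:.4f}")
print(f"  asymptotic p(intermittent): {p_int:.3f}")
print(f"  learned arm values:         fixed {q[-1]:.4f}, intermittent {q[1]:.4f}")
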