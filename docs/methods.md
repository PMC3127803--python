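# Model and methods

This document specifies the model implemented by `poprl`, the parameter
defaults and how they were chosen, and the numerical decisions that matter
for reproducing results.  Time is in milliseconds throughout; rates are
specified in 1/s and converted internally.

## Escape-noise neuron (`poprl.neuron`)

Each population neuron is a spike-response-model neuron.  Its membrane
potential is

```
u(t) = u_rest + sum_i w_i * e1_i(t) - reset(t)
```

where `e1_i` is the sum of postsynaptic-potential kernels triggered by
afferent *i*'s spikes and `reset` is a hyperpolarizing kernel of amplitude
`reset_amp` added after each postsynaptic spike, decaying with `tau_m`.  The
PSP kernel is the peak-normalized double exponential

```
eps(t) = K * (exp(-t / tau_m) - exp(-t / tau_s)),   t >= 0
```

with `K` chosen so that `max_t eps(t) = 1`; weights are therefore in units of
peak PSP.  Spikes are stochastic with the exponential escape rate

```
rho(u) = rho0 * exp((u - theta) / delta_u).
```

**Discretization.**  With step `dt` the per-bin spike probability is the
exact Bernoulli `p = 1 - exp(-rho dt)` (not `rho dt`, which exceeds 1 for
large `u`).  The spike-train log-density uses the matching bin terms
(`log(1 - e^-x) - log dt` for spike bins, `-x` otherwise, `x = rho dt`), so
that probabilities over all postsynaptic patterns sum to one *exactly* at any
`dt` — verified by 2^6-pattern enumeration in the tests.  The weight-gradient
of this log-density (the *characteristic eligibility*) then has bin terms
`(x / (e^x - 1)) * e1 / delta_u` (spike) and `-x * e1 / delta_u` (quiet);
both reduce to the familiar continuous-time forms as `dt -> 0`.  Using the
exact discrete score keeps the gradient identity of the learning rule an
identity in the simulation, not just in the limit.

## Plasticity cascade (`poprl.plasticity`)

Each synapse carries three traces:

```
e1 = PSP kernel sum of presynaptic spikes          (time scale tau_m)
de2/dt = -e2 / tau_e2 + PS(t) * e1(t)              (tau_e2 = decision period)
de3/dt = -e3 / tau_e3 + f(t) * nu(t) * e2(t)       (tau_e3 = expected reward delay)
dw/dt  = R(t) * e3(t)
```

`PS` is the postsynaptic signal comparing the observed spike outcome with the
expected rate: on a spike bin `rho e^{-x} / (1 - e^{-x}) / delta_u` (the exact
per-bin score, `-> 1/(dt delta_u)` as `dt -> 0`) and `-rho / delta_u`
otherwise.  The window integral of `PS * e1` is exactly the characteristic
eligibility.  `f` is the broadcast decision feedback, `nu` in {-1, +1} each
neuron's alignment with the decision period's activity (below), and `R` the
reward signal, which absorbs the learning rate.

Two execution modes share all semantics up to the middle stage:

* **idealized** — e2 accumulates `PS * e1` over the decision window;
  feedback and reward act as instantaneous pulses.  In this form the mean
  update provably equals a positive multiple of the reward gradient; the
  `gradient_check` harness verifies that against exact enumeration.
* **biological** — every stage is a leaky integrator updated each step, and
  feedback arrives as transmitter concentrations (below).  No signal in this
  mode requires knowledge of trial boundaries.

## Decision circuit (`poprl.decision`)

The population read-out uses a spike/no-spike code: `chi_i = +1` if neuron
*i* spiked at least once during the stimulus, else -1.  The population
activity is `A = sum_i chi_i / sqrt(N)` and the binary decision `D` in
{-1, +1} is drawn from the logistic `P(D | A) = 1 / (1 + exp(-g D A))`.  The
decision feedback broadcast to all synapses is the score of that likelihood,

```
f = g * D * (1 - P(D | A)) = d/dA log P(D | A),
```

largest when the taken decision was still uncertain.

## Neuromodulator channels (`poprl.modulators`)

In biological mode both reward and decision feedback reach synapses as
transmitter concentrations.  Each channel relaxes to its homeostatic level
with `tau_c = 200`; an event of value `v` raises the production rate by
`v / (delta_prod * tau_c)` for `delta_prod = 50`, so the concentration
deviation integrates to exactly `v` (the channels converge to idealized
pulses as `tau_c, delta_prod -> 0`).  The reward signal is the deviation
`c_r - c0`; negative rewards lower the concentration below baseline.  A new
decision replaces the previous decision-channel production.

The alignment sign is read from a per-neuron spike trace `sigma` (set to 1 on
each spike, decaying with `tau_sigma = 500`): `nu = +1` iff
`sigma >= vartheta = 0.2`.  The threshold satisfies
`vartheta < exp(-T / tau_sigma)` for `T = 500`, so a neuron that spiked at any
point in the stimulus still reads as aligned when the feedback acts after the
stimulus end.

## Trial structure: the feedback epoch

The engine exposes `present(stimulus)` — one decision period — and
`relax(duration)` — stimulus-free dynamics during which scheduled transmitter
productions act on the decaying traces.  The experiment loops insert a
relaxation interval (`iti`, default 600 ms) after every presentation.  This
matters: if the next stimulus starts immediately, the feedback concentrations
(50 ms production + 200 ms decay) read out e2 and sigma *after* the new
stimulus has begun rewriting them, and the measured per-trial weight update
decorrelates from the idealized gradient update (cosine ~0.12 with no gap
vs ~0.6 with a 600 ms gap in our calibration runs).  Delayed rewards may
still land during any later presentation and are handled identically.

## Parameter defaults and calibration

| parameter | value | origin |
|---|---|---|
| tau_m, tau_s | 10, 2 | standard membrane/synapse constants |
| afferents, rate, duration | 80, 6 Hz, 500 ms | task design |
| initial weight SD | 4 | matches the acceptance target (t5) |
| position encoding | 50 current + 30 previous trains | working-memory variant |
| bandit schedule | U ~ {1..12}, r_fix = r_int / 7.5 | calibrated so always-intermittent = always-fixed |
| rho0 | 10 1/s | escape-rate scale |
| theta | 15 | calibrated (below) |
| delta_u | 2 | calibrated (below) |
| tau_e2, tau_sigma | 500 | matched to the decision period |
| tau_e3 | 2000 | bridges reward delays up to ~2 stimulus durations |
| tau_c, delta_prod, c0 | 200, 50, 1 | transmitter kinetics |
| vartheta | 0.2 | < exp(-T / tau_sigma) = 0.37 |
| iti | 600 ms | feedback epoch (above) |
| eta (assoc / bandit / track) | 1.0 / 0.1 / 0.1 | pilot-tuned per task |
| gain g | 2 (assoc), 1 (bandit, sweep) | see below |

**theta and delta_u.**  At the default population input (80 afferents x 6 Hz,
weight SD 4, peak-normalized kernels) membrane excursions span roughly 9–22
units.  `theta = 15` places the soft threshold at the median excursion so
that about half the population participates on an untrained stimulus (initial
behavior near chance), and `delta_u = 2` spans the excursion range so that
both silent and active neurons retain usable likelihood gradients.  Small
`delta_u` starves learning in both directions (silent neurons have
`rho ~ 0`, saturated neurons have score `~ 0`).

**gain.**  With `g = 2` a trained 20-neuron population reads out nearly
deterministically (smoothed accuracy > 0.95).  The population-size speedup of
trials-to-criterion (N = 1, 5, 20) is assessed at `g = 1`, where the
accuracy ceilings `sigma(g * A_max)` are graded in N — a single neuron cannot
reach the 0.8 criterion, five neurons sit near it, twenty clear it — which is
the mechanism that makes larger populations reach criterion sooner.

## Tasks

* **Association** (`AssociationTask`): ten stimuli, each with a correct
  decision; reward ±1 delivered after a fixed or per-trial-random delay while
  further stimuli are presented.
* **Bandit** (`BanditTask`): D = +1 chooses the intermittent arm.  After
  collection the arm is un-baited for exactly U ~ Uniform{1..12} steps (the
  countdown ticks at the start of each step), then baited until chosen.  The
  closed-form long-run reward of the memoryless policy `p` is
  `(1-p) r_fix + r_int p / (6.5 p + 1)` (renewal-reward argument); the
  optimum is `p* ~ 0.27`, `r* ~ 0.195` with `r_int = 1`.
* **Track** (`TrackTask`): positions 0..5, start at 1; home (0) ends the
  episode, rewarded only if 3 was visited; 5 ends it unrewarded.  The
  shortest rewarded episode takes 5 decisions (breadth-first-search check).
  Position encoders provide stimuli with or without a one-step memory of the
  previous position.

## SARSA(λ) baseline (`poprl.td`)

Tabular SARSA with softmax or epsilon-greedy policies and accumulating
eligibility traces.  On the bandit (single state, gamma = 0) it reduces to
per-arm payoff averaging, and its softmax readout *meliorates* toward
matching (p_int ~ 0.5+) instead of the optimum — asymptotic reward decreases
with the inverse temperature beta.  On the track with memory-1 states the
shortcut state (_1_2) aliases "visited 3" with "did not": SARSA(0)
bootstraps value into the worthless direct-home move until the greedy policy
collapses onto it, unlearns it, and repeats; SARSA(1) (direct returns)
converges, but requires a discount gamma < 1 — with gamma = 1 the capped
zero-reward episodes assign return 0 everywhere and loops are never
penalized relative to short paths.

## Numerical notes

* Exponential decays use exact exponential-Euler factors, so linear kinetics
  have no step-size error; concentrations use the closed-form update
  `c' = base + (c - base) e^{-dt/tau} + prod tau (1 - e^{-dt/tau})`.
* All exponentials of membrane potential are clipped at `exp(60)`; the
  spike-step score uses the overflow-safe form `rho e^{-x} / (1 - e^{-x})`.
* The numba kernel and the pure-Python reference path consume identical
  pre-drawn uniforms and agree to float accumulation order (~1e-13 after
  several trials); tests compare them at rtol 1e-9.
* Weight overflow raises `RunawayWeightsError` rather than propagating NaN.

## Limitations

* The temporal accumulation of population activity into a decision is not
  modeled circuit-level; the decision is a function of spike/no-spike flags
  at the stimulus end.
* The alignment trace cannot distinguish a spike at the start of the current
  stimulus from one at the end of the previous one closer than
  `tau_sigma ln(1/vartheta) - T ~ 300 ms`; the feedback epoch keeps this
  misattribution rare.
* Learning-rate defaults are pilot-tuned per task; no annealing schedules are
  used for the population learner.
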