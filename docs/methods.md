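# Methods

`coeruleus` simulates discrete-state active-inference agents whose
moment-to-moment Bayesian surprise drives a model of locus-coeruleus (LC)
firing and, through a simulated noradrenergic feedback loop, the rate at
which the agent forgets its own world model. This note documents the
model, the numerical choices, and what the simulations do and do not
establish.

## The generative model and the update cycle

Each task is a finite POMDP: hidden states `s`, observations `o`,
actions `u`, trials of `T` one-second timesteps. The agent's model
comprises a likelihood `A(o|s)` (column-stochastic, observations ×
states), action-conditioned transitions `B(s'|s,u)`, log-preferences
over observations `C`, an initial-state prior `D`, and an enumerated set
of policies (action sequences of length `T−1`).

At each timestep the agent:

1. **Infers states per policy.** For every policy still compatible with
   the actions already taken, the posterior over the full state
   trajectory — smoothed for past times, filtered for the present,
   predictive for the future — is computed by exact forward–backward
   message passing on the policy-conditioned chain. On a chain the
   messages do not depend on the marginals, so the sweep converges in a
   single pass and the reported free-energy trace is already at its
   minimum; the variational free energy per policy is the exact negative
   log evidence of the observations so far under the expected
   parameters. Learnable arrays enter the messages through their
   expected log-parameters, `ψ(count) − ψ(column sum)`; predictive
   (outcome) distributions use the normalised means.
2. **Scores policies.** The expected free energy per policy sums, over
   future timesteps, a pragmatic *risk* term `o·(ln o − ln C̃)` (with
   `C̃` the softmax-normalised preferences), an *ambiguity* term
   `s·H_A` (expected likelihood entropy), minus an expected *novelty*
   (information gain about learnable Dirichlet parameters), using the
   standard weight `W = ½(1/count − 1/column-sum)` on learnable entries.
3. **Updates the policy posterior and precision.** `π =
   softmax(−F − γG)`; the precision `γ = 1/β_q` follows a damped
   fixed-point iteration `β_q ← β + (π − π₀)·G` (prior rate β = 1,
   damping ½, tolerance 1e−6, cap 16 iterations), lowering confidence in
   `G` when the evidence disagrees with it.
4. **Forms the Bayesian Model Average** `S_τ = Σ_π π_p s^p_τ` over all
   within-trial times — the agent's complete map of past, present and
   future.
5. **Computes the state-action prediction error** (from the second
   timestep on): `SAPE(t) = Σ_τ KL[S_τ^t ‖ S_τ^{t−1}]` in nats, the
   Bayesian surprise induced by the newest observation. Probabilities
   are floored at 1e−16 inside logarithms.
6. **Selects an action** by sampling from the policy-marginal action
   distribution (an argmax mode with seeded tie-break is available).
   Sampling is deliberate: with a deterministic rule, "always withdraw"
   is an absorbing state of the go/no-go task — a chance run of no-go
   trials starves the go branch of credit and no mechanism can break
   out — whereas the behavioural variability produced by sampling is
   itself part of the phenomenon being modelled (flattened priors →
   variable behaviour).

## LC firing

The per-second firing probability is an increasing logistic in the
surprise, `p = 1/(1+e^{−k(SAPE−m)})` with gradient `k = 8`; each second
is divided into ten 0.1 s bins that each emit at most one spike with
probability `p`, giving a 10 Hz ceiling. Note the printed form of this
logistic in the source material decreases with its input; the increasing
orientation is the only one consistent with phasic bursts at high
surprise, and is used throughout.

## Learning with surprise-controlled forgetting

After each trial the learnable concentration parameters receive the
standard Dirichlet accretion — `d` gets the BMA state posterior at
τ = 1; `a` the outer products of each observed outcome with the BMA
state posterior at its timestep; `b` the τ→τ+1 BMA coincidences under
the action taken — together with a decay:

```
new = counts + increment − exposure · (counts − baseline) / α
```

* **Baseline.** Forgetting returns each array to its *initial*
  concentration parameters — the agent's structural prior. For `d` the
  baseline is all ones (the printed `−(d−1)/α` rule). For likelihoods
  the task defines small floors (0.25 for the two candidate cue
  emissions, 0.05 for never-emitted outcomes): a flat floor of 1 in
  every cell caps all likelihood ratios at ≈ 1+α, which makes confident
  inference at a 1:9 context prior impossible for any admissible α.
* **Exposure.** In the go/no-go task the likelihood decay is weighted by
  how much each column was re-experienced in the trial (you do not
  unlearn what a cue means during trials in which no cue state was
  visited); `d` is credited every trial, so for it the exposure-weighted
  and plain rules coincide. In the bandit the transition decay is plain
  (time-based): drifting unvisited arms back toward their optimistic
  coin-flip baseline *is* the exploration mechanism that fast forgetting
  provides.
* **α feedback.** α is set per trial from the trial's *maximum*
  prediction error through a decreasing logistic, `α = α_min +
  α_max/(1+e^{k(SAPE−m)})` with α_min = 2, α_max = 32, k = 8. The
  midpoint `m` is calibrated per task as mean + 1 SD of every
  per-timestep SAPE over 100 trials at fixed α = 16, starting from the
  same counts as the run being calibrated. The printed decay appears
  without the fraction bar; division by α is the only reading on which
  large α means slow forgetting.

Entries outside a task's learnability mask (structural emissions such as
"the reward state emits the reward", the bandit's non-start transitions)
are fixed task knowledge and are neither incremented nor decayed.

## Tasks

**Go/no-go** (6 states, T = 3, 2 actions). States pair location with
context: start/go, start/no-go, cue-location/go-cue,
cue-location/no-go-cue, ramp/rewarded, ramp/unrewarded. Both actions
move the agent from the start to the cue location; it then *approaches*
the ramp (reward +3 in the go context, aversive no-reward −3 otherwise)
or *withdraws* to the start (neutral). The go context occurs with
probability `p_go` (default 0.10). Only the cue columns of `a` (which
cue sounds in which context, initially symmetric) and the context prior
`d` are learned; a reversal swaps the true cue emissions. The single
unrewarded-ramp state plus withdrawal-to-start keeps the six-state
budget while preserving the approach/withdraw incentive asymmetry.

**Explore/exploit bandit** (7 states, T = 2, 4 actions). A neutral start
plus reward/no-reward versions of three arms; observations map 1:1 onto
states. One arm pays with probability 0.9, the others 0.1; the high arm
moves according to a block schedule (every 15 or 50 trials, or after
random intervals drawn uniformly from 10–60 trials). The agent learns
only the start→arm-outcome transition counts; preferences are +3 for
reward and −3 for an empty arm (without the aversion, a known-bad arm
is barely worse than an unknown one and choices stay noisy).

Preference magnitudes are not printed in the source material; ±3 are
this package's defaults, with the reward value exposed for sweeps
(c ∈ {1, 2, 3, 4}).

## Experiments and statistics

The protocols are: 750 training trials from naive counts (flexible α,
after calibration); 2000-trial static runs from the trained counts, with
cue-time (t = 2) and feedback-time (t = 3) peak tables split by trial
type and predecessor type; 300-trial reversal sessions (cue meanings
flip at trial 35) × 50 repeats for flexible and fixed α ∈ {2, 16, 32}
agents, scored by d′ over 20-trial bins with rates clamped to
[1/(2n), 1−1/(2n)] (an empty trial type counts as chance); and
150-trial bandit sessions × 50 repeats per block condition. Group
comparisons use seeded permutation tests (10 000 draws; sign-flipping of
per-repeat differences for the paired designs, in which all agents in a
repeat share an environment seed) instead of parametric ANOVA/t-tests.
The conditioned-stimulus transfer analysis averages post-reversal
go-trial peaks across repeats by ordinal position (positions reached by
at least half the repeats) and smooths with a 5-point moving average
before locating the first cue-over-feedback crossover.

## What the simulations show — and known limitations

The simulations reproduce, with the defaults above: phasic surprise
bursts to rare go cues against near-silent tonic background; larger
responses for rarer cues and for larger rewards; suppression of the
second of two consecutive go-cue responses; tonic surprise elevation and
the phasic→tonic→phasic sequence across a reversal, with responses
migrating from the reward to the predictive cue; fast-forgetting agents
winning volatile bandit blocks and slow-forgetting agents winning stable
ones.

Three quantitative caveats, all traceable to a single mechanism. With
the printed α-logistic (k = 8) and calibration rule, the well-trained
agent's go-cue surprise (≈ 7 nats) always lies far above any achievable
m (mean + 1 SD of a bimodal distribution is always below its upper
mode), so the flexible agent's α saturates at 2 on every go trial and
the context prior then takes a large forgetting hit. Consequently:
(i) the consecutive-cue suppression measures ≈ 35–50% rather than the
≈ 13% the stable regime produces (a fixed α = 32 agent measures ≈ 13%,
and suppression decreases with α exactly as expected); (ii) the
flexible agent's go branch never re-consolidates beyond the α = 2
agent's level, so after a reversal its final d′ matches (rather than
exceeds) the fixed α = 2 agent, while clearly beating α ∈ {16, 32};
(iii) in the bandit, false-alarm α-crashes on the high arm's intrinsic
10% failures offset part of the flexible agent's post-switch advantage,
leaving its edge over the α = 32 agent under random blocks positive but
small. At even cue probabilities the cue peaks track rarity rather than
the go/no-go identity: with softmax-normalised preferences the neutral
withdrawal outcome carries a cost close to the risky approach, so there
is no strong default plan whose reprogramming would make the go cue
special; raising the ramp aversion restores the asymmetry at p(go) = 0.5
but suppresses the exploratory approaches that reversal learning
requires, and the symmetric default is kept.

These are simulations of an idealised agent in its own generative
world: nothing here constitutes evidence about biological LC recordings,
and the synthetic tasks lack (among much else) graded motivation,
reaction-time dynamics, and within-trial timing variability.

## Reproducibility

Every run is exactly reproducible from its configuration and a single
integer seed; environments, agents, calibrations and spike generation
draw from independently spawned streams, so enabling or disabling spike
simulation does not perturb behaviour.
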