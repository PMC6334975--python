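# coeruleus

Active-inference POMDP agents whose Bayesian surprise drives a simulated
locus coeruleus (LC) and an adaptive forgetting rate.

The locus coeruleus — the brain's main source of noradrenaline — fires
in two modes: brief phasic bursts to salient stimuli and sustained tonic
elevation during behavioural flexibility and exploration. `coeruleus`
implements a computational account in which both modes emerge from one
quantity: the **state-action prediction error** (SAPE), the Bayesian
surprise induced in a discrete active-inference agent's beliefs by each
new observation,

```
S_τ = Σ_p π_p s_τ^p                      (Bayesian model average)
SAPE(t) = Σ_τ KL[ S_τ^t ‖ S_τ^{t−1} ]    (nats)
```

where `s_τ^p` are per-policy state posteriors and `π_p` the policy
posterior. SAPE is converted to spiking through a logistic firing
probability per second (0.1 s bins, 10 Hz ceiling) and fed back to
control the decay of the agent's Dirichlet-parameterised world model,

```
α = α_min + α_max / (1 + e^{k(SAPE − m)}),   counts ← counts + increment − (counts − base)/α
```

so that large surprises (low α, fast forgetting) make the model flexible
and calm periods (high α) keep it stable. Two tasks exercise the loop: a
rat go/no-go paradigm with rare reward-predicting cues and cue-meaning
reversals, and a three-arm explore/exploit bandit with a moving
high-reward arm. See `docs/methods.md` for the full model description.

It is aimed at computational-neuroscience researchers who want a
self-contained, seedable simulator of these phenomena — there is no
empirical data input; every experiment is generated by the package.

## Worked example

Train a naive agent for 750 go/no-go trials (go-cue probability 10%),
then run 2000 trials with fixed cue meanings and flexible α:

```
$ coeruleus gonogo-static --seed 0
go peak 7.010, no-go peak 0.669, consecutive-cue reduction 39.2%
```

The rare go cue evokes a mean cue-time surprise of 7.0 nats — a phasic
LC burst at the 10 Hz ceiling — against 0.67 nats for the expected no-go
cue (tonic near-silence); when two go trials occur back to back, the
second cue's peak is 39% smaller, because the first one's surprise
boosted model updating. The run writes a per-timestep trial log
(`gonogo_static_trials.csv`), simulated spike times
(`gonogo_static_spikes.csv`) and a summary JSON.

Racing fixed- against flexible-α agents on the bandit with the high arm
moving at random intervals:

```
$ coeruleus bandit --seed 0 --block-length random --repeats 10
alpha-2: mean total reward 56.6/150
alpha-32: mean total reward 66.2/150
flexible: mean total reward 67.6/150
```

The hyper-flexible agent (α = 2) forgets too fast to exploit stable
stretches, the stable agent (α = 32) perseveres after the arm moves, and
the surprise-driven agent adapts its own forgetting rate. Other
subcommands: `coeruleus calibrate`, `coeruleus train`,
`coeruleus gonogo-reversal` (d′ recovery across a cue reversal), and the
same protocols are available as library functions in
`coeruleus.experiments`.

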