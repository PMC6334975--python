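"""One full active-inference update cycle per timestep.

At every timestep the agent (i) infers posterior state trajectories under
each policy still compatible with its actions so far (exact smoothing /
filtering / prediction on the policy-conditioned chain), (ii) scores
policies by accumulated variational free energy F and expected free energy
G (risk + ambiguity - parameter novelty), (iii) updates the policy
posterior and its precision, (iv) forms the Bayesian Model Average over
states for every within-trial time, and (v) selects an action.  The KL
divergence between successive Bayesian Model Averages is the state-action
prediction error handed to :mod:`coeruleus.lc` and
:mod:`coeruleus.learning`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import lc as lc_mod
from .learning import AlphaParams, alpha_from_sape, end_of_trial_learning
from .mdp import EPS, DirichletParams, TaskModel, _floored_log, log_expected_columns


def softmax(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass
class BeliefState:
    """Posterior beliefs after one update cycle.

    ``s`` holds per-policy state posteriors (num_policies x T x num_states)
    spanning past, present and future; ``pi`` the policy posterior (zero on
    policies pruned by executed actions); ``S`` the Bayesian Model Average
    per within-trial time.
    """

    s: np.ndarray
    F: np.ndarray
    G: np.ndarray
    pi: np.ndarray
    gamma: float
    S: np.ndarray
    allowed: np.ndarray


@dataclass
class StateInference:
    s: np.ndarray          # (T, num_states) smoothed/filtered/predicted posteriors
    free_energy: float     # -log evidence of the observations so far under the policy
    converged: bool
    n_iters: int
    f_trace: list[float] = field(default_factory=list)


class _EffectiveModel:
    """Expected model arrays for one trial (counts are fixed within a trial).

    Message passing uses expected *log* parameters (digamma form for
    learnable arrays); outcome prediction and the risk/ambiguity terms use
    the normalised means.  Novelty weights W = (1/count - 1/column-sum)/2
    approximate the information gained about learnable Dirichlet entries.
    """

    def __init__(self, model: TaskModel, counts: DirichletParams, expectation: str):
        self.model = model
        digamma_mode = expectation == "log-expectation"

        if counts.learn_a:
            self.lnA = (
                log_expected_columns(counts.a)
                if digamma_mode
                else _floored_log(counts.a / counts.a.sum(0, keepdims=True))
            )
            self.A_pred = counts.a / counts.a.sum(0, keepdims=True)
            a0 = counts.a.sum(0, keepdims=True)
            self.Wa = 0.5 * (1.0 / counts.a - 1.0 / a0) * counts.mask_for("a")
        else:
            self.lnA = _floored_log(model.A)
            self.A_pred = model.A
            self.Wa = None

        if counts.learn_b:
            b0 = counts.b.sum(0, keepdims=True)
            self.B_msg = (
                np.exp(log_expected_columns(counts.b.reshape(counts.b.shape[0], -1)))
                .reshape(counts.b.shape)
                if digamma_mode
                else counts.b / b0
            )
            self.B_pred = counts.b / b0
            self.Wb = 0.5 * (1.0 / counts.b - 1.0 / b0) * counts.mask_for("b")
        else:
            self.B_msg = model.B
            self.B_pred = model.B
            self.Wb = None

        if counts.learn_d:
            d = counts.d
            self.prior = (
                np.exp(log_expected_columns(d[:, None])[:, 0])
                if digamma_mode
                else d / d.sum()
            )
        else:
            self.prior = model.D

        self.lnC = self.model.C - _log_sum_exp(self.model.C)
        A = np.maximum(self.A_pred, EPS)
        self.H_A = -(A * np.log(A)).sum(axis=0)  # ambiguity per state


def _log_sum_exp(x: np.ndarray) -> float:
    m = float(np.max(x))
    return m + float(np.log(np.sum(np.exp(x - m))))


def infer_states(
    model: TaskModel,
    counts: DirichletParams,
    observations: Sequence[int],
    policy: Sequence[int],
    *,
    expectation: str = "log-expectation",
    max_iters: int = 16,
    tol: float = 1e-6,
    _eff: "_EffectiveModel | None" = None,
) -> StateInference:
    """Posterior state trajectory under one policy given observations so far.

    Returns smoothed posteriors for past times, the filtered posterior for
    the present, and predictions for future times, by exact message passing
    on the policy-conditioned chain under the expected (log-)parameters.
    On a chain the messages are independent of the marginals, so the sweep
    converges in a single pass; the free-energy trace it reports is the
    converged value.
    """
    eff = _eff if _eff is not None else _EffectiveModel(model, counts, expectation)
    T = model.horizon
    ns = model.num_states
    obs = list(observations)
    n_obs = len(obs)
    if n_obs < 1:
        raise ValueError("need at least one observation")
    policy = list(policy)
    if len(policy) < T - 1:
        raise ValueError("policy must define actions for every step of the trial")

    # likelihood vectors: observed timesteps carry exp(expected lnA[o]); the
    # future carries no evidence
    L = np.ones((T, ns))
    for tau in range(min(n_obs, T)):
        L[tau] = np.exp(eff.lnA[obs[tau]])

    # forward (filtering) pass with per-step normalisers -> free energy
    fwd = np.empty((T, ns))
    log_evidence = 0.0
    msg = eff.prior * L[0]
    c = msg.sum()
    log_evidence += np.log(max(c, EPS))
    fwd[0] = msg / max(c, EPS)
    for tau in range(1, T):
        msg = L[tau] * (eff.B_msg[:, :, policy[tau - 1]] @ fwd[tau - 1])
        c = msg.sum()
        if tau < n_obs:
            log_evidence += np.log(max(c, EPS))
        fwd[tau] = msg / max(c, EPS)

    # backward pass
    bwd = np.empty((T, ns))
    bwd[T - 1] = 1.0
    for tau in range(T - 2, -1, -1):
        msg = eff.B_msg[:, :, policy[tau]].T @ (L[tau + 1] * bwd[tau + 1])
        c = msg.sum()
        bwd[tau] = msg / max(c, EPS)

    s = fwd * bwd
    s = s / np.maximum(s.sum(axis=1, keepdims=True), EPS)
    F = -log_evidence
    return StateInference(s=s, free_energy=F, converged=True, n_iters=1, f_trace=[F])


def evaluate_policies(
    model: TaskModel,
    counts: DirichletParams,
    s: np.ndarray,
    t: int,
    allowed: np.ndarray | None = None,
    *,
    expectation: str = "log-expectation",
    _eff: "_EffectiveModel | None" = None,
) -> np.ndarray:
    """Expected free energy G per policy at current (1-based) timestep ``t``.

    For every future time tau the predicted outcome distribution o = A s
    contributes risk o.(ln o - ln C~) plus ambiguity s.H_A, minus the
    expected novelty (information gain about learnable Dirichlet
    parameters).  Policies the agent can no longer follow keep G = 0 and
    are excluded by the caller's mask.
    """
    eff = _eff if _eff is not None else _EffectiveModel(model, counts, expectation)
    npol = model.num_policies
    T = model.horizon
    if allowed is None:
        allowed = np.ones(npol, dtype=bool)
    G = np.zeros(npol)
    for p in range(npol):
        if not allowed[p]:
            continue
        g = 0.0
        for tau in range(t, T):  # future 0-based timesteps
            sv = s[p, tau]
            o = eff.A_pred @ sv
            g += float(o @ (np.log(np.maximum(o, EPS)) - eff.lnC))
            g += float(sv @ eff.H_A)
            if eff.Wa is not None:
                g -= float(o @ eff.Wa @ sv)
            if eff.Wb is not None:
                a = model.policies[p, tau - 1]
                g -= float(sv @ eff.Wb[:, :, a] @ s[p, tau - 1])
        G[p] = g
    return G


def update_policies_and_precision(
    F: np.ndarray,
    G: np.ndarray,
    *,
    beta: float = 1.0,
    max_iters: int = 16,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float, int]:
    """Policy posterior pi = softmax(-F - gamma G) with precision gamma.

    gamma = 1/beta_q is updated by a damped fixed-point iteration against a
    Gamma prior with rate ``beta``: beta_q* = beta + (pi - pi0).G, where
    pi0 = softmax(-gamma G) is the prior preference over policies.  When
    the evidence F favours policies that G disfavours, beta_q rises and
    confidence in G falls.
    """
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    qb = float(beta)
    n_it = 0
    pi = softmax(-F - (1.0 / qb) * G)
    for n_it in range(1, max_iters + 1):
        gamma = 1.0 / qb
        pi = softmax(-F - gamma * G)
        pi0 = softmax(-gamma * G)
        target = beta + float((pi - pi0) @ G)
        new_qb = qb + 0.5 * (target - qb)
        new_qb = max(new_qb, 1e-6)
        if abs(new_qb - qb) < tol * max(abs(qb), 1.0):
            qb = new_qb
            break
        qb = new_qb
    gamma = 1.0 / qb
    pi = softmax(-F - gamma * G)
    return pi, gamma, n_it


def bayesian_model_average(s: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Policy-weighted mixture S[tau] = sum_p pi[p] s[p, tau], renormalised."""
    S = np.einsum("p,pts->ts", pi, s)
    return S / np.maximum(S.sum(axis=1, keepdims=True), EPS)


def select_action(
    pi: np.ndarray,
    policies: np.ndarray,
    t: int,
    rng: np.random.Generator,
    mode: str = "argmax",
) -> int:
    """Marginalise the policy posterior over the action at step ``t``.

    ``argmax`` returns the modal action with a seeded uniform tie-break;
    ``sample`` draws from the marginal.
    """
    num_actions = int(policies.max()) + 1
    marginal = np.zeros(num_actions)
    np.add.at(marginal, policies[:, t], pi)
    marginal = marginal / marginal.sum()
    if mode == "sample":
        return int(rng.choice(num_actions, p=marginal))
    if mode == "argmax":
        best = marginal.max()
        ties = np.flatnonzero(marginal >= best - 1e-12)
        if ties.size == 1:
            return int(ties[0])
        return int(rng.choice(ties))
    raise ValueError(f"unknown action-selection mode {mode!r}")


@dataclass
class AgentConfig:
    """Per-agent settings for a run."""

    alpha: AlphaParams = field(default_factory=AlphaParams)
    lc: lc_mod.LcParams | None = None
    beta: float = 1.0
    action_mode: str = "sample"
    expectation: str = "log-expectation"
    learn: bool = True


@dataclass
class TrialRecord:
    """Everything observable about one trial of a run."""

    trial: int
    label: str
    observations: list[int]
    actions: list[int]
    true_states: list[int]
    sape: list[float]
    gamma: list[float]
    alpha: float
    reward: bool
    firing_p: list[float] = field(default_factory=list)
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    S_final: np.ndarray | None = None


def run_trial(
    model: TaskModel,
    counts: DirichletParams,
    env,
    config: AgentConfig,
    rng: np.random.Generator,
    trial_index: int = 0,
) -> TrialRecord:
    """Execute one full trial and apply end-of-trial learning in place.

    Per timestep: observe, infer states under each still-viable policy,
    evaluate F and G, update the policy posterior and precision, form the
    Bayesian Model Average, compute the state-action prediction error
    (from the second timestep on), then select and execute an action.
    The trial's peak error sets alpha, which drives the Dirichlet
    accretion-with-decay on ``counts``.
    """
    T = model.horizon
    npol = model.num_policies
    ns = model.num_states
    eff = _EffectiveModel(model, counts, config.expectation)

    obs0 = env.reset_trial()
    if not 0 <= obs0 < model.num_obs:
        raise IndexError(f"observation {obs0} out of range")
    observations = [int(obs0)]
    true_states = [int(env.true_state)]
    actions: list[int] = []
    allowed = np.ones(npol, dtype=bool)
    s_all = np.zeros((npol, T, ns))
    F = np.zeros(npol)
    sapes: list[float] = []
    gammas: list[float] = []
    firing: list[float] = []
    spike_times: list[np.ndarray] = []
    spike_rng = rng.spawn(1)[0] if config.lc is not None else None
    prev_S: np.ndarray | None = None
    S = np.zeros((T, ns))

    for t in range(1, T + 1):
        for p in np.flatnonzero(allowed):
            res = infer_states(
                model, counts, observations, model.policies[p],
                expectation=config.expectation, _eff=eff,
            )
            s_all[p] = res.s
            F[p] = res.free_energy
        G = evaluate_policies(
            model, counts, s_all, t, allowed,
            expectation=config.expectation, _eff=eff,
        )
        idx = np.flatnonzero(allowed)
        pi_sub, gamma, _ = update_policies_and_precision(
            F[idx], G[idx], beta=config.beta
        )
        pi = np.zeros(npol)
        pi[idx] = pi_sub
        S = bayesian_model_average(s_all[idx], pi_sub)
        gammas.append(gamma)

        if t >= 2:
            err = lc_mod.sape(S, prev_S)
            sapes.append(err)
            if config.lc is not None:
                p_fire = lc_mod.firing_probability(err, config.lc)
                firing.append(p_fire)
                train = lc_mod.simulate_spikes(
                    p_fire, config.lc, spike_rng,
                    t_offset=(t - 2) * config.lc.step_duration,
                )
                spike_times.append(train.times)
        prev_S = S

        if t < T:
            action = select_action(
                pi, model.policies, t - 1, rng, config.action_mode
            )
            actions.append(action)
            allowed &= model.policies[:, t - 1] == action
            o = env.step(action)
            if not 0 <= o < model.num_obs:
                raise IndexError(f"observation {o} out of range")
            observations.append(int(o))
            true_states.append(int(env.true_state))

    alpha = alpha_from_sape(sapes, config.alpha)
    if config.learn:
        new = end_of_trial_learning(counts, S, observations, actions, alpha)
        counts.a = new.a
        counts.b = new.b
        counts.d = new.d

    return TrialRecord(
        trial=trial_index,
        label=str(getattr(env, "trial_label", "")),
        observations=observations,
        actions=actions,
        true_states=true_states,
        sape=sapes,
        gamma=gammas,
        alpha=alpha,
        reward=bool(getattr(env, "rewarded", False)),
        firing_p=firing,
        spike_times=np.concatenate(spike_times) if spike_times else np.empty(0),
        S_final=S,
    )


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Long-format trial log: one row per (trial, tau)."""
    rows = []
    for rec in records:
        T = len(rec.observations)
        for tau in range(T):
            rows.append(
                {
                    "trial": rec.trial,
                    "tau": tau + 1,
                    "label": rec.label,
                    "true_state": rec.true_states[tau],
                    "action": rec.actions[tau] if tau < len(rec.actions) else np.nan,
                    "observation": rec.observations[tau],
                    "sape": rec.sape[tau - 1] if tau >= 1 else np.nan,
                    "firing_p": (
                        rec.firing_p[tau - 1]
                        if tau >= 1 and len(rec.firing_p) >= tau
                        else np.nan
                    ),
                    "alpha": rec.alpha,
                    "reward": rec.reward,
                    "gamma": rec.gamma[tau] if tau < len(rec.gamma) else np.nan,
                }
            )
    return pd.DataFrame(rows)
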