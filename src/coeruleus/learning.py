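"""End-of-trial Dirichlet learning with surprise-controlled forgetting.

After each trial the learnable concentration parameters receive the usual
accretion (beliefs about visited states / observed mappings) together with
a decay toward 1 controlled by alpha:

    new = counts + increment - (counts - 1) / alpha

Low alpha (fast forgetting) makes the model flexible; high alpha keeps it
stable.  The feedback loop sets alpha from the trial's largest state-action
prediction error through a decreasing logistic — the computational reading
of noradrenaline boosting the impact of recent experience on cortical
models when belief updating is larger than expected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .mdp import DirichletParams


@dataclass
class AlphaParams:
    """Parameters of the SAPE -> alpha logistic.

    alpha = alpha_min + alpha_max / (1 + exp(k (SAPE - m))), so alpha falls
    from near alpha_min + alpha_max (stable model) to alpha_min (maximal
    forgetting) as the trial's peak surprise rises through the midpoint m.
    m is calibrated per task as mean + 1 SD of the SAPE values seen over
    100 trials with alpha fixed at 16.
    """

    alpha_min: float = 2.0
    alpha_max: float = 32.0
    k: float = 8.0
    m: float = 0.5
    mode: str = "flexible"
    fixed_value: float = 16.0

    def __post_init__(self) -> None:
        if self.alpha_min < 1:
            raise ValueError("alpha_min must be >= 1")
        if self.alpha_max <= 0:
            raise ValueError("alpha_max must be > 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.mode not in ("fixed", "flexible"):
            raise ValueError(f"unknown alpha mode {self.mode!r}")


def alpha_from_sape(trial_sape_values: Sequence[float], params: AlphaParams) -> float:
    """Model-decay alpha for one trial.

    In fixed mode returns ``fixed_value``.  In flexible mode the *maximum*
    prediction error of the trial enters the logistic (tasks with several
    errors per trial use the largest one).
    """
    values = np.asarray(trial_sape_values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one SAPE value per trial")
    if params.mode == "fixed":
        return float(params.fixed_value)
    x = params.k * (float(values.max()) - params.m)
    if x > 700:
        return float(params.alpha_min)
    return float(params.alpha_min + params.alpha_max / (1.0 + np.exp(x)))


def m_from_sapes(sape_values: Sequence[float]) -> float:
    """Mean + 1 population SD of a stream of SAPE values."""
    values = np.asarray(sape_values, dtype=float)
    if values.size < 2:
        raise ValueError("calibration needs at least two SAPE values")
    return float(values.mean() + values.std())


def calibrate_m(
    task_factory: Callable[[], tuple],
    n_trials: int = 100,
    calibration_alpha: float = 16.0,
    *,
    rng: np.random.Generator,
    record_log: list | None = None,
) -> float:
    """Run ``n_trials`` with alpha fixed at ``calibration_alpha`` and return
    mean + 1 SD of every per-timestep SAPE encountered.

    ``task_factory`` returns a fresh ``(model, counts, environment)`` triple
    in the state the calibrated run will start from.  The calibration trials
    can be kept via ``record_log``.
    """
    from .inference import AgentConfig, run_trial

    if n_trials < 2:
        raise ValueError("calibration needs at least 2 trials")
    model, counts, env = task_factory()
    config = AgentConfig(
        alpha=AlphaParams(mode="fixed", fixed_value=calibration_alpha)
    )
    sapes: list[float] = []
    for i in range(n_trials):
        record = run_trial(model, counts, env, config, rng, trial_index=i)
        sapes.extend(record.sape)
        if record_log is not None:
            record_log.append(record)
    return m_from_sapes(sapes)


def decay_update(
    counts: np.ndarray,
    increment: np.ndarray,
    alpha: float,
    mask: np.ndarray | None = None,
    exposure: np.ndarray | float | None = None,
    baseline: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Elementwise ``counts + increment - exposure * (counts - baseline)/alpha``.

    Counts decay geometrically toward their baseline — the structural
    prior that forgetting returns the model to (all ones for the
    initial-state prior; task-defined for likelihoods and transitions) —
    and, for alpha >= 1 and nonnegative increments, never fall below it.
    ``mask`` limits the update to learnable entries; the rest pass
    through unchanged.

    ``exposure`` (default 1: the plain time-based rule) scales the decay by
    how strongly each entry's column was re-experienced this trial, so that
    mappings are only forgotten in proportion to fresh evidence about them.
    """
    counts = np.asarray(counts, dtype=float)
    increment = np.asarray(increment, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if alpha < 1:
        raise ValueError("alpha must be >= 1 (smaller values overshoot the fixed point)")
    if np.any(counts < baseline - 1e-12):
        raise ValueError("counts must not lie below their baseline")
    if np.any(increment < 0):
        raise ValueError("increments must be nonnegative")
    if exposure is None:
        exposure = 1.0
    new = counts + increment - np.asarray(exposure, dtype=float) * (counts - baseline) / alpha
    if mask is not None:
        new = np.where(mask, new, counts)
    return new


def end_of_trial_learning(
    counts: DirichletParams,
    S: np.ndarray,
    observations: Sequence[int],
    actions: Sequence[int],
    alpha: float,
) -> DirichletParams:
    """Apply one trial's Dirichlet accretion-with-decay and return new counts.

    Increments use the end-of-trial Bayesian Model Average ``S`` (T x
    num_states): ``d`` receives the state posterior at tau=1; ``a`` the
    outer product of each observed outcome with the state posterior at its
    timestep; ``b`` the tau -> tau+1 coincidence under the action taken
    (by trial end the policy posterior is conditioned on the executed
    actions, so the taken action carries the full transition mass).
    """
    S = np.asarray(S, dtype=float)
    exposure_weighted = counts.decay_mode == "exposure"
    new = counts.copy()
    if counts.learn_d:
        # d is credited on every trial, so both decay modes coincide
        exp_d = S[0].sum() if exposure_weighted else None
        new.d = decay_update(
            counts.d, S[0], alpha, counts.mask_for("d"), exp_d, counts.base_for("d")
        )
    if counts.learn_a:
        inc = np.zeros_like(counts.a)
        for tau, obs in enumerate(observations):
            inc[obs, :] += S[tau]
        exp_a = inc.sum(axis=0, keepdims=True) if exposure_weighted else None
        new.a = decay_update(
            counts.a, inc, alpha, counts.mask_for("a"), exp_a, counts.base_for("a")
        )
    if counts.learn_b:
        inc = np.zeros_like(counts.b)
        for tau, action in enumerate(actions):
            inc[:, :, action] += np.outer(S[tau + 1], S[tau])
        exp_b = inc.sum(axis=0, keepdims=True) if exposure_weighted else None
        new.b = decay_update(
            counts.b, inc, alpha, counts.mask_for("b"), exp_b, counts.base_for("b")
        )
    return new
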