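"""State-action prediction error and simulated locus-coeruleus spiking.

The state-action prediction error (SAPE) is the Bayesian surprise induced
by one new observation: the KL divergence, summed over within-trial times
tau, between the agent's Bayesian Model Average over states before and
after the observation.  A logistic squash of the SAPE gives a per-second
firing probability, realised as Bernoulli spikes in 0.1 s bins so that the
unit saturates at a physiological 10 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mdp import EPS


@dataclass
class LcParams:
    """Spike-generation parameters.

    ``k`` is the logistic gradient, ``m`` its midpoint in nats of SAPE
    (calibrated per task, shared with the adaptive-learning logistic).
    Each within-trial timestep lasts ``step_duration`` seconds, split into
    ``bin_width`` bins with at most one spike per bin.
    """

    k: float = 8.0
    m: float = 0.5
    bin_width: float = 0.1
    step_duration: float = 1.0
    max_one_spike_per_bin: bool = True

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("logistic gradient k must be > 0")
        if self.m < 0:
            raise ValueError("logistic midpoint m must be >= 0")
        n_bins = self.step_duration / self.bin_width
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("bin_width must divide step_duration")

    @property
    def n_bins(self) -> int:
        return int(round(self.step_duration / self.bin_width))


@dataclass
class SpikeTrain:
    """Spike times (s from trial start) and the firing probability used."""

    times: np.ndarray
    p: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("firing probability must lie in [0, 1]")


def sape(S_now: np.ndarray, S_prev: np.ndarray) -> float:
    """Sum over tau of KL[S_now[tau] || S_prev[tau]], in nats.

    Both arguments are (T, num_states) Bayesian Model Averages over the
    whole trial (past, present and future).  Probabilities are floored at
    1e-16 inside the logs, and 0*log(0/q) contributes 0.  Only defined
    from the second timestep of a trial onward — the first observation
    has no predecessor to be surprised relative to.
    """
    S_now = np.asarray(S_now, dtype=float)
    S_prev = np.asarray(S_prev, dtype=float)
    if S_now.shape != S_prev.shape:
        raise ValueError(f"BMA shape mismatch: {S_now.shape} vs {S_prev.shape}")
    ratio = np.log(np.maximum(S_now, EPS)) - np.log(np.maximum(S_prev, EPS))
    return float(np.sum(S_now * ratio))


def firing_probability(sape_value: float, params: LcParams) -> float:
    """Logistic map from SAPE to per-second firing probability.

    Increasing in SAPE: p = 1 / (1 + exp(-k (SAPE - m))).  Large surprise
    drives p toward 1 (phasic burst at the 10 Hz ceiling); SAPE well below
    the midpoint gives near-silent tonic rates.
    """
    x = -params.k * (float(sape_value) - params.m)
    # guard exp overflow for very negative SAPE - m
    if x > 700:
        return 0.0
    return 1.0 / (1.0 + np.exp(x))


def simulate_spikes(
    p: float,
    params: LcParams,
    rng: np.random.Generator,
    t_offset: float = 0.0,
) -> SpikeTrain:
    """Bernoulli(p) spikes in each 0.1 s bin of one 1 s timestep.

    Spike times are bin starts, offset by ``t_offset`` seconds from trial
    start.  With at most one spike per bin the rate ceiling is
    n_bins / step_duration Hz (10 Hz at the defaults).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    hits = rng.random(params.n_bins) < p
    times = t_offset + np.flatnonzero(hits) * params.bin_width
    return SpikeTrain(times=times, p=float(p))
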