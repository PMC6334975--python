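"""The two simulated tasks: Go/No-go and a 3-arm explore/exploit bandit.

Each builder returns the agent's generative model (:class:`TaskModel`),
its learnable Dirichlet counts, and the generative *process* — an
:class:`Environment` holding the true hidden state, the stochastic
cue/reward draws and the block/reversal schedule.

Go/No-go (6 states, 3 timesteps).  The agent starts at location 1 in one
of two contexts (go with probability ``p_go``), moves to location 2 where
it hears a cue, then either approaches location 3 (rewarded only in the
go context; climbing the ramp unrewarded is aversive) or withdraws to
location 1 (neutral).  The cue <-> context mapping is what a reversal
swaps; learning is over the likelihood (a) and the initial-state prior (d).

Explore/exploit (7 states, 2 timesteps).  From a neutral start the agent
picks one of three arms (or stays); one arm pays with probability
``p_high``, the others with ``p_low``.  Observations map 1-to-1 onto
states, so all learning is over the start->arm-outcome transition counts
(b) — the agent's beliefs about where reward lives.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .mdp import DirichletParams, TaskModel

# ---------------------------------------------------------------------------
# go/no-go encoding
GN_STATES = {
    0: "loc1/go-context",
    1: "loc1/nogo-context",
    2: "loc2/go-cue",
    3: "loc2/nogo-cue",
    4: "loc3/rewarded",
    5: "loc3/unrewarded",
}
GN_OBS = {0: "start", 1: "cue-A", 2: "cue-B", 3: "reward", 4: "no-reward"}
APPROACH, WITHDRAW = 0, 1


@dataclass
class GoNogoConfig:
    p_go: float = 0.10
    reward_value: float = 3.0
    aversion_value: float = 3.0
    horizon: int = 3
    # initial concentration parameters: structural (known) mappings, the
    # softly informed cue columns, and the context prior
    known_count: float = 64.0
    cue_base: float = 0.25        # baseline counts for the two cue emissions
    impossible_base: float = 0.05  # baseline for never-emitted outcomes

    def __post_init__(self) -> None:
        if not 0 < self.p_go < 1:
            raise ValueError("p_go must lie in (0, 1)")
        if self.horizon != 3:
            raise ValueError("the go/no-go task has horizon 3")


@dataclass
class BanditConfig:
    p_high: float = 0.9
    p_low: float = 0.1
    block_length: int | str = 50
    reward_value: float = 3.0
    noreward_value: float = -3.0
    horizon: int = 2
    known_count: float = 16.0
    arm_count: float = 1.0  # pseudo-counts added to each arm outcome at build

    def __post_init__(self) -> None:
        if not 0 < self.p_low < self.p_high < 1:
            raise ValueError("need 0 < p_low < p_high < 1")
        if self.horizon != 2:
            raise ValueError("the explore/exploit task has horizon 2")


class Environment:
    """Generative process shared by both tasks.

    ``schedule`` is a list of (trial_index, contingency) change points; the
    contingency switches at the *start* of the named 0-based trial.  The
    true hidden state, reward draws and trial labels live here, driven by
    the environment's own seeded random stream.
    """

    def __init__(self, rng: np.random.Generator, schedule=None, contingency=0):
        self.rng = rng
        self.schedule = sorted(schedule or [])
        self.contingency = contingency
        self.trial = -1
        self.true_state = 0
        self.rewarded = False
        self.trial_label = ""

    def _apply_schedule(self) -> None:
        for when, what in self.schedule:
            if when == self.trial:
                self.contingency = what

    def reset_trial(self) -> int:
        self.trial += 1
        self._apply_schedule()
        self.rewarded = False
        return self._start_trial()

    def _start_trial(self) -> int:  # pragma: no cover - abstract
        raise NotImplementedError

    def step(self, action: int) -> int:  # pragma: no cover - abstract
        raise NotImplementedError


class GoNogoEnvironment(Environment):
    """True go/no-go process; contingency 0 = cue-A means go, 1 = reversed."""

    def __init__(self, rng, p_go=0.10, schedule=None):
        super().__init__(rng, schedule, contingency=0)
        self.p_go = p_go

    def _start_trial(self) -> int:
        go = self.rng.random() < self.p_go
        self.true_state = 0 if go else 1
        self.trial_label = "go" if go else "nogo"
        return 0  # start observation

    def _cue_obs(self, state: int) -> int:
        go_cue, nogo_cue = (1, 2) if self.contingency == 0 else (2, 1)
        return go_cue if state == 2 else nogo_cue

    def step(self, action: int) -> int:
        if action not in (APPROACH, WITHDRAW):
            raise ValueError(f"illegal action {action}")
        s = self.true_state
        if s in (0, 1):  # move to the cue location; context is preserved
            self.true_state = 2 if s == 0 else 3
            return self._cue_obs(self.true_state)
        if s == 2:  # go context at the cue location
            if action == APPROACH:
                self.true_state = 4
                self.rewarded = True
                return 3
            self.true_state = 0
            return 0
        if s == 3:  # no-go context
            if action == APPROACH:
                self.true_state = 5
                return 4
            self.true_state = 1
            return 0
        # absorbing end states simply re-emit their outcome
        return 3 if s == 4 else 4


class BanditEnvironment(Environment):
    """3-arm bandit; contingency = action index (1..3) of the high arm."""

    def __init__(self, rng, p_high=0.9, p_low=0.1, schedule=None, high_arm=1):
        super().__init__(rng, schedule, contingency=high_arm)
        self.p_high = p_high
        self.p_low = p_low

    def _start_trial(self) -> int:
        self.true_state = 0
        self.trial_label = f"high={self.contingency}"
        return 0

    def step(self, action: int) -> int:
        if action not in (0, 1, 2, 3):
            raise ValueError(f"illegal action {action}")
        if action == 0:
            self.true_state = 0
            return 0
        p = self.p_high if action == self.contingency else self.p_low
        if self.rng.random() < p:
            self.true_state = 2 * action - 1
            self.rewarded = True
        else:
            self.true_state = 2 * action
        return self.true_state


def environment_step(env: Environment, action: int) -> int:
    """Apply the true transition for ``action`` and return the observation."""
    return env.step(action)


def _normalise(counts: np.ndarray) -> np.ndarray:
    return counts / counts.sum(axis=0, keepdims=True)


def build_gonogo(
    config: GoNogoConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
    schedule=None,
) -> tuple[TaskModel, DirichletParams, GoNogoEnvironment]:
    """Construct the 6-state go/no-go generative model, counts and process."""
    cfg = config or GoNogoConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    ns, no, na, T = 6, 5, 2, cfg.horizon

    # transitions are part of the task definition and are not learned
    B = np.zeros((ns, ns, na))
    for u in range(na):
        B[2, 0, u] = 1.0  # context carries over to the cue location
        B[3, 1, u] = 1.0
        B[4, 4, u] = 1.0
        B[5, 5, u] = 1.0
    B[4, 2, APPROACH] = 1.0
    B[5, 3, APPROACH] = 1.0
    B[0, 2, WITHDRAW] = 1.0
    B[1, 3, WITHDRAW] = 1.0

    # likelihood counts: structural emissions (start, reward, no-reward)
    # are task knowledge and stay fixed; only the cue columns — which cue
    # sounds in which context — are learnable.  The agent starts naive:
    # both cue emissions share the same small baseline, which is also the
    # fixed point its forgetting returns them to, so a reversal can erase
    # the old mapping.  Never-emitted outcomes keep a tiny floor.
    K = cfg.known_count
    a = np.full((no, ns), cfg.impossible_base)
    a[0, 0] = 1.0 + K
    a[0, 1] = 1.0 + K
    for cue_state in (2, 3):
        a[1, cue_state] = cfg.cue_base
        a[2, cue_state] = cfg.cue_base
    a[3, 4] = 1.0 + K
    a[4, 5] = 1.0 + K
    a_mask = np.zeros((no, ns), dtype=bool)
    a_mask[:, 2] = True
    a_mask[:, 3] = True

    d = np.ones(ns)

    C = np.zeros(no)
    C[3] = cfg.reward_value
    C[4] = -cfg.aversion_value

    policies = np.array(list(product(range(na), repeat=T - 1)))
    model = TaskModel(
        A=_normalise(a), B=B, C=C, D=d / d.sum(), policies=policies, horizon=T
    )
    counts = DirichletParams(
        a=a, b=np.ones((ns, ns, na)), d=d, learn_a=True, learn_d=True,
        a_mask=a_mask, a_base=a.copy(), decay_mode="exposure",
    )
    env = GoNogoEnvironment(rng, p_go=cfg.p_go, schedule=schedule)
    return model, counts, env


def build_explore_exploit(
    config: BanditConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
    schedule=None,
    high_arm: int = 1,
) -> tuple[TaskModel, DirichletParams, BanditEnvironment]:
    """Construct the 7-state explore/exploit model, counts and process."""
    cfg = config or BanditConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    ns, no, na, T = 7, 7, 4, cfg.horizon
    K = cfg.known_count

    b = np.ones((ns, ns, na))
    b_mask = np.zeros((ns, ns, na), dtype=bool)
    b[0, :, 0] += K  # 'stay' returns to the start from anywhere
    for arm in (1, 2, 3):
        r, nr = 2 * arm - 1, 2 * arm
        # learnable: where does this arm lead from the start?
        b[r, 0, arm] += cfg.arm_count
        b[nr, 0, arm] += cfg.arm_count
        b_mask[r, 0, arm] = True
        b_mask[nr, 0, arm] = True
        # structural: from anywhere else the arm's outcome is a coin flip
        for src in range(1, ns):
            b[r, src, arm] += K / 2
            b[nr, src, arm] += K / 2

    A = np.eye(no)
    D = np.zeros(ns)
    D[0] = 1.0
    C = np.zeros(no)
    for arm in (1, 2, 3):
        C[2 * arm - 1] = cfg.reward_value
        C[2 * arm] = cfg.noreward_value

    policies = np.arange(na)[:, None]
    B0 = np.stack([_normalise(b[:, :, u]) for u in range(na)], axis=2)
    model = TaskModel(A=A, B=B0, C=C, D=D, policies=policies, horizon=T)
    counts = DirichletParams(
        a=np.ones((no, ns)), b=b, d=np.ones(ns), learn_b=True, b_mask=b_mask,
        b_base=b.copy(),
    )
    env = BanditEnvironment(
        rng, p_high=cfg.p_high, p_low=cfg.p_low, schedule=schedule, high_arm=high_arm
    )
    return model, counts, env


def make_schedule(
    kind: str,
    *,
    n_trials: int,
    block_length: int | None = None,
    reversal_trial: int = 35,
    interval_range: tuple[int, int] = (10, 60),
    arms: tuple[int, ...] = (1, 2, 3),
    start_arm: int = 1,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Contingency change points for a run.

    ``static`` — none.  ``reversal_at`` — a single cue-meaning flip at
    ``reversal_trial``.  ``blocks`` — the high arm cycles every
    ``block_length`` trials.  ``random_blocks`` — the high arm moves to a
    different random arm after intervals drawn uniformly from
    ``interval_range``.
    """
    if kind == "static":
        return []
    if kind == "reversal_at":
        return [(int(reversal_trial), 1)]
    if kind == "blocks":
        if not block_length or block_length <= 0:
            raise ValueError("blocks schedule needs a positive block_length")
        out = []
        arm_idx = arms.index(start_arm)
        for j, t in enumerate(range(block_length, n_trials, block_length)):
            out.append((t, arms[(arm_idx + 1 + j) % len(arms)]))
        return out
    if kind == "random_blocks":
        if rng is None:
            raise ValueError("random_blocks needs an rng")
        lo, hi = interval_range
        out = []
        current = start_arm
        t = int(rng.integers(lo, hi + 1))
        while t < n_trials:
            current = int(rng.choice([a for a in arms if a != current]))
            out.append((t, current))
            t += int(rng.integers(lo, hi + 1))
        return out
    raise ValueError(f"unknown schedule kind {kind!r}")
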