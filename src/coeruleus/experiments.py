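"""End-to-end simulation protocols and their summary statistics.

The protocols mirror the behavioural studies the model targets: training a
naive agent on the go/no-go task, long static runs probing phasic
surprise peaks, cue-meaning reversals scored with d', and fixed- versus
flexible-forgetting agents racing on a volatile bandit.  Group
comparisons use seeded permutation tests (sign-flip for paired repeat
designs) rather than parametric ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .inference import AgentConfig, TrialRecord, records_to_frame, run_trial
from .lc import LcParams
from .learning import AlphaParams, calibrate_m
from .mdp import DirichletParams, TaskModel
from .tasks import (
    APPROACH,
    BanditConfig,
    GoNogoConfig,
    GoNogoEnvironment,
    build_explore_exploit,
    build_gonogo,
    make_schedule,
)

DEFAULT_BIN = 20


# ---------------------------------------------------------------------------
# generic session loop and summaries

def run_session(
    model: TaskModel,
    counts: DirichletParams,
    env,
    config: AgentConfig,
    n_trials: int,
    rng: np.random.Generator,
    start_trial: int = 0,
) -> list[TrialRecord]:
    """Run ``n_trials`` consecutive trials, learning after each."""
    return [
        run_trial(model, counts, env, config, rng, trial_index=start_trial + i)
        for i in range(n_trials)
    ]


@dataclass
class RunSummary:
    """Trial log of one run plus the metadata needed to replay it."""

    records: list[TrialRecord]
    task: str
    meta: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def peak_table(self) -> pd.DataFrame:
        """Per-trial cue-time (t=2) and feedback-time (t=3) surprise peaks.

        ``prev_label`` is the preceding trial's type, for consecutive-cue
        contrasts.
        """
        rows = []
        prev = None
        for rec in self.records:
            rows.append(
                {
                    "trial": rec.trial,
                    "label": rec.label,
                    "prev_label": prev,
                    "cue_peak": rec.sape[0] if rec.sape else np.nan,
                    "feedback_peak": rec.sape[1] if len(rec.sape) > 1 else np.nan,
                    "alpha": rec.alpha,
                    "reward": rec.reward,
                }
            )
            prev = rec.label
        return pd.DataFrame(rows)

    def alpha_trace(self) -> np.ndarray:
        return np.array([rec.alpha for rec in self.records])

    def reward_series(self) -> np.ndarray:
        return np.array([rec.reward for rec in self.records], dtype=float)


# ---------------------------------------------------------------------------
# signal detection

def dprime(hits: int, misses: int, false_alarms: int, correct_rejections: int) -> float:
    """d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate).

    Rates are clamped to [1/(2n), 1 - 1/(2n)] with n the trial count of
    the corresponding type, so perfect bins stay finite; empty types count
    as chance (rate 0.5).
    """
    for v in (hits, misses, false_alarms, correct_rejections):
        if v < 0:
            raise ValueError("counts must be nonnegative")

    def _rate(k: int, n: int) -> float:
        if n == 0:
            return 0.5
        return min(max(k / n, 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))

    hr = _rate(hits, hits + misses)
    far = _rate(false_alarms, false_alarms + correct_rejections)
    return float(norm.ppf(hr) - norm.ppf(far))


def gonogo_outcomes(records: list[TrialRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(is_go, approached) boolean arrays per trial."""
    is_go = np.array([rec.label == "go" for rec in records])
    approached = np.array(
        [len(rec.actions) > 1 and rec.actions[1] == APPROACH for rec in records]
    )
    return is_go, approached


def dprime_bins(records: list[TrialRecord], bin_size: int = DEFAULT_BIN) -> np.ndarray:
    """d' per complete ``bin_size``-trial bin of a go/no-go run."""
    is_go, approached = gonogo_outcomes(records)
    n_bins = len(records) // bin_size
    out = np.empty(n_bins)
    for b in range(n_bins):
        sl = slice(b * bin_size, (b + 1) * bin_size)
        g, a = is_go[sl], approached[sl]
        out[b] = dprime(
            int((g & a).sum()),
            int((g & ~a).sum()),
            int((~g & a).sum()),
            int((~g & ~a).sum()),
        )
    return out


def mean_sape(records: list[TrialRecord], lo: int, hi: int) -> float:
    """Mean of every per-timestep surprise value in trials [lo, hi)."""
    vals = [v for rec in records[lo:hi] for v in rec.sape]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# permutation tests (replacing parametric group comparisons)

def permutation_pvalue(
    x,
    y,
    n_perm: int = 10_000,
    *,
    rng: np.random.Generator,
    alternative: str = "greater",
) -> float:
    """Unpaired label-shuffling test on the difference of means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    obs = x.mean() - y.mean()
    nx = len(x)
    stats = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        stats[i] = perm[:nx].mean() - perm[nx:].mean()
    if alternative == "greater":
        return float((np.sum(stats >= obs) + 1) / (n_perm + 1))
    if alternative == "less":
        return float((np.sum(stats <= obs) + 1) / (n_perm + 1))
    raise ValueError(f"unknown alternative {alternative!r}")


def sign_flip_pvalue(
    diffs,
    n_perm: int = 10_000,
    *,
    rng: np.random.Generator,
    alternative: str = "greater",
) -> float:
    """Paired sign-flipping test on per-repeat differences."""
    d = np.asarray(diffs, dtype=float)
    obs = d.mean()
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    stats = (signs * d).mean(axis=1)
    if alternative == "greater":
        return float((np.sum(stats >= obs) + 1) / (n_perm + 1))
    if alternative == "less":
        return float((np.sum(stats <= obs) + 1) / (n_perm + 1))
    raise ValueError(f"unknown alternative {alternative!r}")


# ---------------------------------------------------------------------------
# go/no-go protocols

@dataclass
class TrainResult:
    model: TaskModel
    counts: DirichletParams
    m: float
    config: GoNogoConfig
    records: list[TrialRecord] = field(default_factory=list)


def train_agent(
    n: int = 750,
    *,
    rng: np.random.Generator,
    task_config: GoNogoConfig | None = None,
    calibration_trials: int = 100,
) -> TrainResult:
    """Train a naive go/no-go agent for ``n`` trials with flexible alpha.

    The logistic midpoint m is first calibrated (mean + 1 SD of the
    surprise over ``calibration_trials`` trials at alpha = 16, starting
    from the same naive counts).  The learnt counts serve as 'well
    trained' priors for the static and reversal protocols.
    """
    cfg = task_config or GoNogoConfig()
    cal_rng, env_rng, agent_rng = rng.spawn(3)
    model, counts, env = build_gonogo(cfg, rng=env_rng)
    if n == 0:
        return TrainResult(model=model, counts=counts, m=float("nan"), config=cfg)
    m = calibrate_m(
        lambda: build_gonogo(cfg, rng=cal_rng.spawn(1)[0]),
        n_trials=calibration_trials,
        rng=cal_rng,
    )
    config = AgentConfig(alpha=AlphaParams(mode="flexible", m=m))
    records = run_session(model, counts, env, config, n, agent_rng)
    return TrainResult(model=model, counts=counts, m=m, config=cfg, records=records)


def _gonogo_config(
    trained: TrainResult,
    alpha_mode: str,
    fixed_alpha: float,
    m: float,
    lc: bool,
) -> AgentConfig:
    if alpha_mode == "flexible":
        alpha = AlphaParams(mode="flexible", m=m)
    else:
        alpha = AlphaParams(mode="fixed", fixed_value=fixed_alpha)
    return AgentConfig(alpha=alpha, lc=LcParams(m=m) if lc else None)


def run_static_gonogo(
    trained: TrainResult,
    n: int = 2000,
    *,
    rng: np.random.Generator,
    alpha_mode: str = "flexible",
    fixed_alpha: float = 16.0,
    calibration_trials: int = 100,
    simulate_lc: bool = False,
) -> RunSummary:
    """Long static run (no reversal) from well-trained priors.

    m is recalibrated from the trained counts, then ``n`` trials are run
    with fixed cue meanings; the summary tabulates cue- and feedback-time
    surprise peaks by trial type and predecessor type.
    """
    cfg = trained.config
    cal_rng, env_rng, agent_rng = rng.spawn(3)
    m = calibrate_m(
        lambda: (trained.model, trained.counts.copy(),
                 GoNogoEnvironment(cal_rng.spawn(1)[0], p_go=cfg.p_go)),
        n_trials=calibration_trials,
        rng=cal_rng,
    )
    counts = trained.counts.copy()
    env = GoNogoEnvironment(env_rng, p_go=cfg.p_go)
    config = _gonogo_config(trained, alpha_mode, fixed_alpha, m, simulate_lc)
    records = run_session(trained.model, counts, env, config, n, agent_rng)
    return RunSummary(
        records=records,
        task="gonogo-static",
        meta={"m": m, "alpha_mode": alpha_mode, "p_go": cfg.p_go,
              "reward_value": cfg.reward_value, "n": n},
    )


def consecutive_cue_reduction(summary: RunSummary) -> float:
    """Percent reduction of the go-cue peak after a preceding go trial.

    100 * (1 - mean peak on go-after-go / mean peak on go-after-no-go).
    """
    table = summary.peak_table()
    go = table[table.label == "go"]
    after_go = go[go.prev_label == "go"].cue_peak
    after_nogo = go[go.prev_label == "nogo"].cue_peak
    if after_go.empty or after_nogo.empty:
        raise ValueError("run too short: need go trials after both trial types")
    return float(100.0 * (1.0 - after_go.mean() / after_nogo.mean()))


DEFAULT_REVERSAL_AGENTS = {
    "flexible": None,
    "fixed-2": 2.0,
    "fixed-16": 16.0,
    "fixed-32": 32.0,
}


@dataclass
class ReversalResult:
    """Per-agent outcome of repeated reversal sessions."""

    dprime: np.ndarray          # (repeats, bins)
    sape_pre: np.ndarray        # (repeats,) mean surprise 20 trials before reversal
    sape_post: np.ndarray       # (repeats,) mean surprise 20 trials after
    go_cue_peaks: list[np.ndarray]       # per repeat, go trials post-reversal
    go_feedback_peaks: list[np.ndarray]
    records: list[list[TrialRecord]] | None = None


def run_reversal(
    trained: TrainResult,
    n: int = 300,
    reversal_trial: int = 35,
    repeats: int = 50,
    agents: dict[str, float | None] | None = None,
    *,
    rng: np.random.Generator,
    bin_size: int = DEFAULT_BIN,
    calibration_trials: int = 100,
    keep_records: bool = False,
) -> dict[str, ReversalResult]:
    """Cue-meaning reversal at ``reversal_trial``, repeated and scored.

    Every agent starts each repeat from a copy of the same well-trained
    counts; repeats are paired (one environment seed per repeat shared by
    all agents).  d' is measured over ``bin_size``-trial bins.
    """
    agents = agents if agents is not None else DEFAULT_REVERSAL_AGENTS
    cfg = trained.config
    cal_rng = rng.spawn(1)[0]
    m = calibrate_m(
        lambda: (trained.model, trained.counts.copy(),
                 GoNogoEnvironment(cal_rng.spawn(1)[0], p_go=cfg.p_go)),
        n_trials=calibration_trials,
        rng=cal_rng,
    )
    schedule = make_schedule("reversal_at", n_trials=n, reversal_trial=reversal_trial)
    n_bins = n // bin_size
    results: dict[str, ReversalResult] = {}
    repeat_seeds = rng.spawn(repeats)
    for label, fixed in agents.items():
        dp = np.empty((repeats, n_bins))
        pre = np.empty(repeats)
        post = np.empty(repeats)
        cue_peaks, fb_peaks = [], []
        all_records = [] if keep_records else None
        for r in range(repeats):
            env_rng, agent_rng = repeat_seeds[r].spawn(2)
            env = GoNogoEnvironment(env_rng, p_go=cfg.p_go, schedule=schedule)
            counts = trained.counts.copy()
            config = _gonogo_config(
                trained, "flexible" if fixed is None else "fixed",
                fixed if fixed is not None else 16.0, m, False,
            )
            records = run_session(trained.model, counts, env, config, n, agent_rng)
            dp[r] = dprime_bins(records, bin_size)
            pre[r] = mean_sape(records, reversal_trial - bin_size, reversal_trial)
            post[r] = mean_sape(records, reversal_trial, reversal_trial + bin_size)
            go_post = [rec for rec in records[reversal_trial:] if rec.label == "go"]
            cue_peaks.append(np.array([rec.sape[0] for rec in go_post]))
            fb_peaks.append(np.array([rec.sape[1] for rec in go_post]))
            if keep_records:
                all_records.append(records)
        results[label] = ReversalResult(
            dprime=dp, sape_pre=pre, sape_post=post,
            go_cue_peaks=cue_peaks, go_feedback_peaks=fb_peaks,
            records=all_records,
        )
    return results


def cs_transfer_crossover(
    result: ReversalResult, window: int = 5
) -> tuple[int | None, np.ndarray, np.ndarray]:
    """Trial ordinal at which the cue-time peak overtakes the feedback peak.

    Go-trial peaks after the reversal are averaged across repeats by
    ordinal position (shorter repeats contribute to the positions they
    reach) and smoothed with a ``window``-point moving average.  Returns
    (crossover index or None, smoothed cue curve, smoothed feedback
    curve) — the conditioned-stimulus transfer seen as phasic responses
    migrate from the reward to the predictive cue.
    """

    def _ragged_mean(arrays):
        n_max = max(len(a) for a in arrays)
        stack = np.full((len(arrays), n_max), np.nan)
        for i, a in enumerate(arrays):
            stack[i, : len(a)] = a
        # keep positions reached by at least half the repeats
        valid = (~np.isnan(stack)).sum(axis=0) >= len(arrays) / 2
        return np.nanmean(stack[:, valid], axis=0)

    cue = _ragged_mean(result.go_cue_peaks)
    fb = _ragged_mean(result.go_feedback_peaks)
    kernel = np.ones(window) / window
    cue_s = np.convolve(cue, kernel, mode="valid")
    fb_s = np.convolve(fb, kernel, mode="valid")
    above = np.flatnonzero(cue_s >= fb_s)
    crossover = int(above[0]) if above.size else None
    return crossover, cue_s, fb_s


# ---------------------------------------------------------------------------
# explore/exploit protocols

DEFAULT_BANDIT_AGENTS = {"alpha-2": 2.0, "alpha-32": 32.0, "flexible": None}


@dataclass
class BanditResult:
    rewards: np.ndarray   # (repeats, trials) 0/1
    totals: np.ndarray    # (repeats,)

    def binned(self, bin_size: int = DEFAULT_BIN) -> np.ndarray:
        n_bins = self.rewards.shape[1] // bin_size
        r = self.rewards[:, : n_bins * bin_size]
        return r.reshape(r.shape[0], n_bins, bin_size).mean(axis=2)


def run_bandit_comparison(
    n: int = 150,
    block_length: int | str = 15,
    repeats: int = 50,
    agents: dict[str, float | None] | None = None,
    *,
    rng: np.random.Generator,
    bandit_config: BanditConfig | None = None,
    calibration_trials: int = 100,
    interval_range: tuple[int, int] = (10, 60),
) -> dict[str, BanditResult]:
    """Fixed- versus flexible-forgetting agents on the volatile bandit.

    ``block_length`` is 15, 50, or ``"random"``; the high arm moves
    accordingly.  Fresh agents per repeat; repeats are paired across
    agents (same environment seed, hence the same schedule and reward
    stream given the same choices).
    """
    agents = agents if agents is not None else DEFAULT_BANDIT_AGENTS
    cfg = bandit_config or BanditConfig()
    cal_rng = rng.spawn(1)[0]

    def _schedule(sched_rng) -> list[tuple[int, int]]:
        if block_length == "random":
            return make_schedule(
                "random_blocks", n_trials=n, interval_range=interval_range,
                rng=sched_rng,
            )
        return make_schedule("blocks", n_trials=n, block_length=int(block_length))

    m = calibrate_m(
        lambda: build_explore_exploit(
            cfg, rng=cal_rng.spawn(1)[0],
            schedule=_schedule(cal_rng.spawn(1)[0]),
        ),
        n_trials=calibration_trials,
        rng=cal_rng,
    )
    repeat_seeds = rng.spawn(repeats)
    results: dict[str, BanditResult] = {}
    for label, fixed in agents.items():
        rewards = np.empty((repeats, n))
        for r in range(repeats):
            env_rng, agent_rng, sched_rng = repeat_seeds[r].spawn(3)
            model, counts, env = build_explore_exploit(
                cfg, rng=env_rng, schedule=_schedule(sched_rng)
            )
            alpha = (
                AlphaParams(mode="flexible", m=m)
                if fixed is None
                else AlphaParams(mode="fixed", fixed_value=fixed)
            )
            records = run_session(
                model, counts, env, AgentConfig(alpha=alpha), n, agent_rng
            )
            rewards[r] = [rec.reward for rec in records]
        results[label] = BanditResult(rewards=rewards, totals=rewards.sum(axis=1))
    return results


# ---------------------------------------------------------------------------
# parameter sweeps over the static task

def run_peak_sweep(
    p_go_values=(0.10, 0.50, 0.55),
    c_values=(1.0, 2.0, 3.0, 4.0),
    *,
    rng: np.random.Generator,
    n_train: int = 750,
    n_static: int = 2000,
    base_p_go: float = 0.10,
    base_c: float = 3.0,
) -> dict[tuple[float, float], RunSummary]:
    """Static-run summaries over cue-probability and reward-value sweeps.

    The cue-probability sweep holds the reward value at ``base_c``; the
    reward sweep holds p(go) at ``base_p_go``.  Each condition trains its
    own agent (priors depend on both parameters).
    """
    conditions = [(p, base_c) for p in p_go_values]
    conditions += [(base_p_go, c) for c in c_values if (base_p_go, c) not in conditions]
    out: dict[tuple[float, float], RunSummary] = {}
    for p_go, c in conditions:
        cond_rng = rng.spawn(1)[0]
        cfg = GoNogoConfig(p_go=p_go, reward_value=c)
        trained = train_agent(n_train, rng=cond_rng, task_config=cfg)
        out[(p_go, c)] = run_static_gonogo(trained, n_static, rng=cond_rng)
    return out


def peak_statistics(summaries: dict[tuple[float, float], RunSummary]) -> pd.DataFrame:
    """Mean +/- SE of cue-time peaks per condition, split by trial type."""
    rows = []
    for (p_go, c), summary in summaries.items():
        table = summary.peak_table()
        for label in ("go", "nogo"):
            peaks = table[table.label == label].cue_peak.dropna()
            rows.append(
                {
                    "p_go": p_go,
                    "reward_value": c,
                    "trial_type": label,
                    "mean_peak": peaks.mean(),
                    "se_peak": peaks.std(ddof=1) / np.sqrt(len(peaks)),
                    "n_trials": len(peaks),
                }
            )
    return pd.DataFrame(rows)
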