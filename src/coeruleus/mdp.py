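"""Discrete generative models (POMDPs) and their Dirichlet parameterisations.

A task is specified by the usual four arrays of discrete active inference:

* ``A`` (num_obs x num_states) — likelihood of each observation given each
  hidden state, column-stochastic;
* ``B`` (num_states x num_states x num_actions) — action-conditioned
  transition probabilities, column-stochastic per action slice;
* ``C`` (num_obs,) — log-preferences (utilities) over observations;
* ``D`` (num_states,) — prior over the hidden state at the first timestep.

Learnable arrays have Dirichlet concentration-parameter counterparts
(``a``, ``b``, ``d``).  Counts are floats bounded below by 1 — the fixed
point of the forgetting rule in :mod:`coeruleus.learning` — and the agent
works with their expected distributions (mean or digamma log-expectation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import digamma

EPS = 1e-16
_COLSUM_TOL = 1e-10


def _floored_log(x: np.ndarray | float) -> np.ndarray:
    """Natural log with probabilities floored at ``EPS``."""
    return np.log(np.maximum(x, EPS))


@dataclass
class TaskModel:
    """The agent's generative model of one task.

    ``policies`` is an ordered ``(num_policies, horizon - 1)`` integer array
    of action sequences; each trial lasts ``horizon`` timesteps of 1 s each.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    policies: np.ndarray
    horizon: int

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.policies = np.asarray(self.policies, dtype=int)
        if self.policies.ndim == 1:
            self.policies = self.policies[:, None]

    @property
    def num_obs(self) -> int:
        return self.A.shape[0]

    @property
    def num_states(self) -> int:
        return self.A.shape[1]

    @property
    def num_actions(self) -> int:
        return self.B.shape[2]

    @property
    def num_policies(self) -> int:
        return self.policies.shape[0]

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "C": self.C.tolist(),
            "D": self.D.tolist(),
            "policies": self.policies.tolist(),
            "horizon": int(self.horizon),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "TaskModel":
        return cls(
            A=np.asarray(doc["A"], dtype=float),
            B=np.asarray(doc["B"], dtype=float),
            C=np.asarray(doc["C"], dtype=float),
            D=np.asarray(doc["D"], dtype=float),
            policies=np.asarray(doc["policies"], dtype=int),
            horizon=int(doc["horizon"]),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "TaskModel":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class DirichletParams:
    """Concentration-parameter counterparts of the learnable model arrays.

    ``learn_*`` flags mark which arrays the task treats as learnable.  The
    optional boolean masks restrict learning (increment and decay) to the
    entries that the task genuinely treats as uncertain; entries outside a
    mask keep their construction-time counts.

    Each learnable array decays toward its *baseline* concentration — the
    agent's structural prior, which forgetting returns it to.  The
    baseline for the initial-state prior ``d`` is all ones (a flat
    context prior); likelihood and transition baselines are set by the
    task and may lie below 1 for mappings the task treats as (nearly)
    impossible.  Counts must never fall below their baseline, and all
    counts and baselines must be positive.
    """

    a: np.ndarray
    b: np.ndarray
    d: np.ndarray
    learn_a: bool = False
    learn_b: bool = False
    learn_d: bool = False
    a_mask: np.ndarray | None = None
    b_mask: np.ndarray | None = None
    d_mask: np.ndarray | None = None
    a_base: np.ndarray | None = None
    b_base: np.ndarray | None = None
    d_base: np.ndarray | None = None
    decay_mode: str = "global"

    def __post_init__(self) -> None:
        if self.decay_mode not in ("global", "exposure"):
            raise ValueError(f"unknown decay mode {self.decay_mode!r}")
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        for name in ("a_mask", "b_mask", "d_mask"):
            mask = getattr(self, name)
            if mask is not None:
                setattr(self, name, np.asarray(mask, dtype=bool))
        for name in ("a", "b", "d"):
            arr = getattr(self, name)
            if np.any(arr <= 0):
                raise ValueError(f"Dirichlet counts '{name}' must be positive")
            base = getattr(self, f"{name}_base")
            if base is None:
                # default: the printed fixed point 1, or the counts
                # themselves where they are constructed below it
                base = np.minimum(np.ones_like(arr), arr)
                setattr(self, f"{name}_base", base)
            else:
                base = np.asarray(base, dtype=float)
                setattr(self, f"{name}_base", base)
            if np.any(base <= 0):
                raise ValueError(f"baseline counts '{name}_base' must be positive")
            if np.any(arr < base - 1e-12):
                raise ValueError(
                    f"counts '{name}' must not lie below their baseline "
                    f"(the decay fixed point)"
                )

    def mask_for(self, name: str) -> np.ndarray:
        """Boolean learnability mask for array ``name`` ('a', 'b' or 'd')."""
        mask = getattr(self, f"{name}_mask")
        if mask is None:
            return np.ones_like(getattr(self, name), dtype=bool)
        return mask

    def base_for(self, name: str) -> np.ndarray:
        """Baseline (decay fixed-point) counts for array ``name``."""
        return getattr(self, f"{name}_base")

    def copy(self) -> "DirichletParams":
        return DirichletParams(
            a=self.a.copy(),
            b=self.b.copy(),
            d=self.d.copy(),
            learn_a=self.learn_a,
            learn_b=self.learn_b,
            learn_d=self.learn_d,
            a_mask=None if self.a_mask is None else self.a_mask.copy(),
            b_mask=None if self.b_mask is None else self.b_mask.copy(),
            d_mask=None if self.d_mask is None else self.d_mask.copy(),
            a_base=self.a_base.copy(),
            b_base=self.b_base.copy(),
            d_base=self.d_base.copy(),
            decay_mode=self.decay_mode,
        )

    def to_dict(self) -> dict:
        doc = {
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "d": self.d.tolist(),
            "learn_a": self.learn_a,
            "learn_b": self.learn_b,
            "learn_d": self.learn_d,
            "decay_mode": self.decay_mode,
        }
        for name in ("a_mask", "b_mask", "d_mask"):
            mask = getattr(self, name)
            doc[name] = None if mask is None else mask.tolist()
        for name in ("a_base", "b_base", "d_base"):
            doc[name] = getattr(self, name).tolist()
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "DirichletParams":
        return cls(
            a=np.asarray(doc["a"], dtype=float),
            b=np.asarray(doc["b"], dtype=float),
            d=np.asarray(doc["d"], dtype=float),
            learn_a=bool(doc["learn_a"]),
            learn_b=bool(doc["learn_b"]),
            learn_d=bool(doc["learn_d"]),
            a_mask=None if doc.get("a_mask") is None else np.asarray(doc["a_mask"], bool),
            b_mask=None if doc.get("b_mask") is None else np.asarray(doc["b_mask"], bool),
            d_mask=None if doc.get("d_mask") is None else np.asarray(doc["d_mask"], bool),
            a_base=None if doc.get("a_base") is None else np.asarray(doc["a_base"], float),
            b_base=None if doc.get("b_base") is None else np.asarray(doc["b_base"], float),
            d_base=None if doc.get("d_base") is None else np.asarray(doc["d_base"], float),
            decay_mode=doc.get("decay_mode", "global"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "DirichletParams":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class ValidationReport:
    ok: bool
    messages: list[str] = field(default_factory=list)


def validate_model(model: TaskModel) -> ValidationReport:
    """Collect every normalisation / shape / index violation in ``model``.

    Reports rather than raises: content violations never interrupt a caller
    that merely wants the diagnosis.
    """
    msgs: list[str] = []
    no, ns = model.A.shape

    if model.horizon < 2:
        msgs.append(f"horizon must be >= 2, got {model.horizon}")
    if model.B.shape[:2] != (ns, ns):
        msgs.append(f"B state dimensions {model.B.shape[:2]} != ({ns}, {ns})")
    if model.C.shape != (no,):
        msgs.append(f"C shape {model.C.shape} != ({no},)")
    if model.D.shape != (ns,):
        msgs.append(f"D shape {model.D.shape} != ({ns},)")

    if np.any(model.A < 0):
        msgs.append("A has negative entries")
    if np.any(model.B < 0):
        msgs.append("B has negative entries")
    if np.any(model.D < 0):
        msgs.append("D has negative entries")

    bad_a = np.flatnonzero(np.abs(model.A.sum(axis=0) - 1.0) > _COLSUM_TOL)
    for j in bad_a:
        msgs.append(f"A column {j} sums to {model.A[:, j].sum():.12g}, not 1")
    if model.B.shape[:2] == (ns, ns):
        for u in range(model.B.shape[2]):
            bad_b = np.flatnonzero(np.abs(model.B[:, :, u].sum(axis=0) - 1.0) > _COLSUM_TOL)
            for j in bad_b:
                msgs.append(
                    f"B[:, {j}, {u}] sums to {model.B[:, j, u].sum():.12g}, not 1"
                )
    if model.D.shape == (ns,) and abs(model.D.sum() - 1.0) > _COLSUM_TOL:
        msgs.append(f"D sums to {model.D.sum():.12g}, not 1")

    if model.policies.shape[1] != model.horizon - 1:
        msgs.append(
            f"policies have length {model.policies.shape[1]}, expected horizon-1={model.horizon - 1}"
        )
    if model.policies.size and (
        model.policies.min() < 0 or model.policies.max() >= model.num_actions
    ):
        msgs.append(
            f"policy action indices must lie in [0, {model.num_actions}); "
            f"found range [{model.policies.min()}, {model.policies.max()}]"
        )

    return ValidationReport(ok=not msgs, messages=msgs)


def _expect_columns(counts: np.ndarray, mode: str) -> np.ndarray:
    """Column-wise expected distribution of a Dirichlet count array."""
    counts = np.asarray(counts, dtype=float)
    colsum = counts.sum(axis=0, keepdims=True)
    if np.any(colsum <= 0):
        raise ValueError("degenerate Dirichlet counts: zero column sum")
    if mode == "mean":
        return counts / colsum
    if mode == "log-expectation":
        out = np.exp(digamma(counts) - digamma(colsum))
        return out / out.sum(axis=0, keepdims=True)
    raise ValueError(f"unknown expectation mode {mode!r}")


def expected_distributions(
    counts: DirichletParams, mode: str = "log-expectation"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised (A, B, D) expectations of Dirichlet counts.

    ``mode='mean'`` returns count / column-sum; ``mode='log-expectation'``
    returns exp(psi(count) - psi(column-sum)) renormalised, the geometric
    expectation used in the belief-update messages.
    """
    A = _expect_columns(counts.a, mode)
    B = np.stack(
        [_expect_columns(counts.b[:, :, u], mode) for u in range(counts.b.shape[2])],
        axis=2,
    )
    D = _expect_columns(counts.d[:, None], mode)[:, 0]
    return A, B, D


def log_expected_columns(counts: np.ndarray) -> np.ndarray:
    """psi(count) - psi(column-sum): the expected log-probability columns.

    Unlike :func:`expected_distributions` the result is *not* renormalised;
    these are the quantities that enter log-space messages directly.
    """
    counts = np.asarray(counts, dtype=float)
    return digamma(counts) - digamma(counts.sum(axis=0, keepdims=True))
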