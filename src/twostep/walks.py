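"""Reward schedules for two-step bandit tasks.

Three generative processes cover every task variant in the package:

* reflecting Gaussian random walks over reward probabilities or scalar
  payoffs (the Daw task and all factorial variants),
* a jump process in which each arm sits at a high or a low win
  probability and is occasionally reassigned (the Dezfouli task),
* fixed-length block alternation between complementary probability
  pairs (the Akam task).

A schedule is a ``(n_trials, n_arms)`` grid of outcome parameters; arm
``k`` is the ``k``-th ``(second-stage state, action)`` pair in row-major
order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WalkConfig",
    "RewardSchedule",
    "step_reflect",
    "reflect",
    "generate_walk",
    "generate_jump_schedule",
    "generate_block_schedule",
]


def reflect(x, lower: float, upper: float):
    """Fold values into ``[lower, upper]`` by mirroring at the bounds.

    Overshoot past a bound is reflected back (``v -> 2*bound - v``),
    repeatedly if the excursion spans the interval more than once.  The
    fold is the quotient map of the line onto the interval under the
    group generated by the two mirror reflections, so applying it to a
    free (unbounded) cumulative walk yields exactly the trajectory of
    the step-by-step reflected walk.
    """
    width = upper - lower
    if width <= 0:
        raise ValueError("upper must exceed lower")
    z = np.mod(np.asarray(x, dtype=float) - lower, 2.0 * width)
    folded = np.where(z > width, 2.0 * width - z, z)
    out = lower + folded
    if np.ndim(x) == 0:
        return float(out)
    return out


def step_reflect(value: float, increment: float, lower: float, upper: float) -> float:
    """Advance a reflecting walk by one step.

    Returns ``value + increment`` mirrored about whichever bound is
    crossed.  ``value`` must already lie inside ``[lower, upper]``.
    """
    if not (lower <= value <= upper):
        raise ValueError(
            f"walk state {value} outside reflecting bounds [{lower}, {upper}]"
        )
    return reflect(value + increment, lower, upper)


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of a bounded Gaussian random walk.

    Parameters
    ----------
    n_arms, n_trials
        Grid dimensions of the schedule.
    sigma
        Standard deviation of the per-trial Gaussian step (probability
        units, or points for scalar payoffs).  ``sigma=0`` freezes the
        schedule at its initial values.
    lower, upper
        Reflecting bounds.
    init
        Initial value per arm.  Each entry may be a scalar (used as is)
        or a ``(lo, hi)`` pair (sampled uniformly).  ``None`` samples
        every arm uniformly within the walk bounds, the stationary
        regime used for all simulation analyses.
    seed
        Seed for the schedule's private random stream.
    """

    n_arms: int
    n_trials: int
    sigma: float
    lower: float
    upper: float
    init: Sequence | float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n_arms < 1 or self.n_trials < 1:
            raise ValueError("n_arms and n_trials must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")

    def resolve_init(self, rng: np.random.Generator) -> np.ndarray:
        """Materialize per-arm initial values, sampling ranges if needed."""
        if self.init is None:
            return rng.uniform(self.lower, self.upper, size=self.n_arms)
        init = self.init
        if np.ndim(init) == 0:
            init = [init] * self.n_arms
        if len(init) != self.n_arms:
            raise ValueError("init must provide one entry per arm")
        out = np.empty(self.n_arms)
        for k, entry in enumerate(init):
            if np.ndim(entry) == 0:
                out[k] = float(entry)
            else:
                lo, hi = entry
                out[k] = rng.uniform(lo, hi)
        if np.any(out < self.lower) or np.any(out > self.upper):
            raise ValueError("initial values must lie within the walk bounds")
        return out

    def to_json(self) -> str:
        d = {
            "n_arms": self.n_arms,
            "n_trials": self.n_trials,
            "sigma": self.sigma,
            "lower": self.lower,
            "upper": self.upper,
            "init": self.init if self.init is None or np.ndim(self.init) == 0
            else [list(e) if np.ndim(e) else e for e in self.init],
            "seed": self.seed,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "WalkConfig":
        d = json.loads(s)
        init = d["init"]
        if isinstance(init, list):
            init = [tuple(e) if isinstance(e, list) else e for e in init]
        return cls(
            n_arms=d["n_arms"], n_trials=d["n_trials"], sigma=d["sigma"],
            lower=d["lower"], upper=d["upper"], init=init, seed=d["seed"],
        )


@dataclass
class RewardSchedule:
    """Per-trial outcome parameters for every terminal arm.

    ``kind="probability"`` entries are Bernoulli win probabilities;
    ``kind="scalar"`` entries are delivered verbatim as point payoffs.
    """

    values: np.ndarray
    kind: str = "probability"
    arm_to_state_action: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a (n_trials, n_arms) grid")
        if self.kind not in ("probability", "scalar"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "probability" and (
            self.values.min() < 0 or self.values.max() > 1
        ):
            raise ValueError("probability schedules must lie in [0, 1]")
        if not self.arm_to_state_action:
            n_arms = self.values.shape[1]
            n_actions = max(1, n_arms // 2)
            self.arm_to_state_action = [
                (k // n_actions, k % n_actions) for k in range(n_arms)
            ]

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_arms(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"arm_s{s}_a{a}" for s, a in self.arm_to_state_action]
        return pd.DataFrame(self.values, columns=cols)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, kind: str = "probability") -> "RewardSchedule":
        frame = pd.read_csv(path, sep="\t")
        mapping = []
        for col in frame.columns:
            _, s, a = col.split("_")
            mapping.append((int(s[1:]), int(a[1:])))
        return cls(frame.to_numpy(), kind=kind, arm_to_state_action=mapping)


def generate_walk(config: WalkConfig, kind: str = "probability") -> RewardSchedule:
    """Generate independently drifting arms under a reflecting walk.

    Trial 0 equals the (possibly sampled) initial values; each later
    trial adds a ``N(0, sigma)`` step per arm and folds at the bounds.
    """
    rng = np.random.default_rng(config.seed)
    init = config.resolve_init(rng)
    steps = rng.normal(0.0, config.sigma, size=(config.n_trials - 1, config.n_arms))
    free = init[None, :] + np.vstack(
        [np.zeros((1, config.n_arms)), np.cumsum(steps, axis=0)]
    )
    values = reflect(free, config.lower, config.upper)
    return RewardSchedule(values, kind=kind)


def generate_jump_schedule(
    n_arms: int,
    n_trials: int,
    p_high: float = 0.7,
    p_low: float = 0.2,
    switch_prob: float = 0.2,
    seed: int | None = None,
) -> RewardSchedule:
    """Two-level jump process: each arm sits at ``p_high`` or ``p_low``.

    On every trial after the first, each arm is independently
    reassigned, with probability ``switch_prob``, to a level drawn
    uniformly from the two (so a "switch" keeps the level half the
    time).  Initial levels are drawn uniformly.
    """
    if not (0 <= p_low < p_high <= 1):
        raise ValueError("need 0 <= p_low < p_high <= 1")
    if not (0 <= switch_prob <= 1):
        raise ValueError("switch_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    levels = np.array([p_low, p_high])
    state = rng.integers(0, 2, size=n_arms)
    values = np.empty((n_trials, n_arms))
    values[0] = levels[state]
    for t in range(1, n_trials):
        hit = rng.random(n_arms) < switch_prob
        redraw = rng.integers(0, 2, size=n_arms)
        state = np.where(hit, redraw, state)
        values[t] = levels[state]
    return RewardSchedule(values, kind="probability")


def generate_block_schedule(
    n_trials: int,
    block_length: int,
    levels: tuple[float, float] = (0.8, 0.2),
    seed: int | None = None,
) -> RewardSchedule:
    """Two arms alternating between ``(hi, lo)`` and ``(lo, hi)`` blocks.

    The assignment flips every ``block_length`` trials, starting from
    ``(levels[0], levels[1])``.  ``seed`` is accepted for interface
    uniformity; the process is deterministic.
    """
    if block_length < 1:
        raise ValueError("block_length must be at least 1")
    hi, lo = levels
    block_index = np.arange(n_trials) // block_length
    flipped = block_index % 2 == 1
    values = np.where(flipped[:, None], [lo, hi], [hi, lo])
    return RewardSchedule(values.astype(float), kind="probability")
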