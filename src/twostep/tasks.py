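"""Structural space of two-stage decision tasks.

Every task in the package is a two-stage Markov decision process: a
first-stage choice between two actions leads (stochastically or
deterministically) to one of two second-stage states, where an action
(a real choice, or a single forced response) delivers an outcome drawn
from a drifting schedule.

The variants the literature has studied are spanned by five binary
design factors applied to the classic Daw task:

0. ``broad_range``    — widen the probability walk bounds to [0, 1]
1. ``fast_drift``     — raise the walk step s.d. to 0.2
2. ``deterministic_transitions`` — two equivalent start states with
   deterministic transitions (the Doll structure)
3. ``single_second_action``     — one forced response per second-stage
   state instead of a binary choice
4. ``scalar_payoff``  — deliver the scheduled value as points instead
   of using it as a Bernoulli win probability

The all-false vector is the Daw task; the all-true vector is the
"novel" task whose design maximizes the accuracy-demand trade-off.
Named presets additionally cover the Dezfouli, Doll, and Akam variants
and the human-calibrated versions of the Daw and novel paradigms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np

from .walks import (
    RewardSchedule,
    WalkConfig,
    generate_block_schedule,
    generate_jump_schedule,
    generate_walk,
)

__all__ = [
    "TaskSpec",
    "TrialOutcome",
    "FACTOR_NAMES",
    "PRESETS",
    "make_task",
    "enumerate_factorial_tasks",
    "make_schedule",
    "sample_transition",
    "sample_outcome",
]

FACTOR_NAMES = (
    "broad_range",
    "fast_drift",
    "deterministic_transitions",
    "single_second_action",
    "scalar_payoff",
)


@dataclass(frozen=True)
class TrialOutcome:
    second_state: int
    transition_was_common: bool
    reward: float


@dataclass(frozen=True)
class TaskSpec:
    """Complete structural definition of a two-stage task.

    ``common_dest[s][a]`` is the second-stage state that first-stage
    action ``a`` in start state ``s`` reaches on a common transition
    (with probability ``common_prob`` for stochastic tasks, always for
    deterministic ones).  ``schedule_kind`` selects the generative
    process for the outcome schedule; ``walk`` holds its parameters for
    walk schedules, ``schedule_params`` for jump/block processes.
    """

    name: str
    n_start_states: int
    transition_kind: str  # "stochastic" | "deterministic"
    n_second_actions: int
    outcome_kind: str  # "probability" | "scalar"
    walk: WalkConfig | None = None
    schedule_kind: str = "walk"  # "walk" | "jump" | "block"
    schedule_params: dict = field(default_factory=dict, hash=False, compare=False)
    common_prob: float = 0.7
    factors: tuple | None = None
    n_trials: int = 201

    def __post_init__(self):
        if self.n_start_states not in (1, 2):
            raise ValueError("n_start_states must be 1 or 2")
        if self.transition_kind not in ("stochastic", "deterministic"):
            raise ValueError(f"unknown transition_kind {self.transition_kind!r}")
        if self.n_second_actions not in (1, 2):
            raise ValueError("n_second_actions must be 1 or 2")
        if self.outcome_kind not in ("probability", "scalar"):
            raise ValueError(f"unknown outcome_kind {self.outcome_kind!r}")

    @property
    def n_arms(self) -> int:
        return 2 * self.n_second_actions

    @property
    def common_dest(self) -> np.ndarray:
        """(n_start_states, 2) map of first-stage action -> common state.

        With two start states the mappings are crossed (action 0 from
        start 0 and action 1 from start 1 both reach state 0), so the
        start states afford the same destinations through different
        action labels, which is what defeats model-free generalization.
        """
        if self.n_start_states == 1:
            return np.array([[0, 1]])
        return np.array([[0, 1], [1, 0]])

    def transition_matrix(self) -> np.ndarray:
        """P(second state | start state, action), shape (n_start, 2, 2)."""
        p = np.empty((self.n_start_states, 2, 2))
        common = self.common_prob if self.transition_kind == "stochastic" else 1.0
        for s in range(self.n_start_states):
            for a in range(2):
                dest = self.common_dest[s, a]
                p[s, a, dest] = common
                p[s, a, 1 - dest] = 1.0 - common
        return p

    def arm_index(self, second_state: int, action: int) -> int:
        return second_state * self.n_second_actions + action


def _daw_walk(sigma=0.025, lower=0.25, upper=0.75, n_arms=4, n_trials=201, init=None):
    return WalkConfig(
        n_arms=n_arms, n_trials=n_trials, sigma=sigma, lower=lower, upper=upper,
        init=init,
    )


def _factor_task(bits: tuple) -> TaskSpec:
    broad, fast, determ, single, scalar = (bool(b) for b in bits)
    lower, upper = (0.0, 1.0) if broad else (0.25, 0.75)
    sigma = 0.2 if fast else 0.025
    n_second = 1 if single else 2
    name = "factors_" + "".join(str(int(b)) for b in bits)
    return TaskSpec(
        name=name,
        n_start_states=2 if determ else 1,
        transition_kind="deterministic" if determ else "stochastic",
        n_second_actions=n_second,
        outcome_kind="scalar" if scalar else "probability",
        walk=_daw_walk(sigma=sigma, lower=lower, upper=upper, n_arms=2 * n_second),
        factors=(broad, fast, determ, single, scalar),
    )


def _preset_daw() -> TaskSpec:
    return replace(_factor_task((0, 0, 0, 0, 0)), name="daw")


def _preset_daw_human() -> TaskSpec:
    # Human-calibrated variant: 125 trials, fixed initial probabilities.
    walk = _daw_walk(init=[0.25, 0.75, 0.4, 0.6], n_trials=125)
    return replace(_preset_daw(), name="daw_human", walk=walk, n_trials=125)


def _preset_dezfouli() -> TaskSpec:
    return TaskSpec(
        name="dezfouli",
        n_start_states=1,
        transition_kind="stochastic",
        n_second_actions=2,
        outcome_kind="probability",
        schedule_kind="jump",
        schedule_params=dict(p_high=0.7, p_low=0.2, switch_prob=0.2),
    )


def _preset_doll() -> TaskSpec:
    return TaskSpec(
        name="doll",
        n_start_states=2,
        transition_kind="deterministic",
        n_second_actions=2,
        outcome_kind="probability",
        walk=_daw_walk(),
    )


def _preset_doll_stochastic_hybrid() -> TaskSpec:
    # Two start states but with 70/30 transitions, on the improved
    # (broad-range, fast-drift) schedules: isolates the contribution of
    # rare transitions from that of start-state generalization.
    return TaskSpec(
        name="doll_stochastic_hybrid",
        n_start_states=2,
        transition_kind="stochastic",
        n_second_actions=2,
        outcome_kind="probability",
        walk=_daw_walk(sigma=0.2, lower=0.0, upper=1.0),
    )


def _preset_akam() -> TaskSpec:
    return TaskSpec(
        name="akam",
        n_start_states=1,
        transition_kind="stochastic",
        common_prob=0.8,
        n_second_actions=1,
        outcome_kind="probability",
        schedule_kind="block",
        schedule_params=dict(block_length=25, levels=(0.8, 0.2)),
    )


def _preset_novel() -> TaskSpec:
    return replace(_factor_task((1, 1, 1, 1, 1)), name="novel")


def _preset_novel_human() -> TaskSpec:
    # Human-calibrated scalar task: payoffs in points on [-4, +5] with a
    # sigma=2 walk; one schedule initialized negative, the other
    # positive, 125 trials.
    walk = WalkConfig(
        n_arms=2, n_trials=125, sigma=2.0, lower=-4.0, upper=5.0,
        init=[(-4.0, -1.0), (1.0, 5.0)],
    )
    return replace(
        _preset_novel(), name="novel_human", walk=walk, n_trials=125, factors=None,
    )


PRESETS = {
    "daw": _preset_daw,
    "daw_human": _preset_daw_human,
    "dezfouli": _preset_dezfouli,
    "doll": _preset_doll,
    "doll_stochastic_hybrid": _preset_doll_stochastic_hybrid,
    "akam": _preset_akam,
    "novel": _preset_novel,
    "novel_human": _preset_novel_human,
}


def make_task(preset) -> TaskSpec:
    """Build a TaskSpec from a preset name, factor 5-tuple, or bitstring.

    ``make_task("daw") == make_task((0, 0, 0, 0, 0))`` up to the name;
    likewise ``"novel"`` and the all-true tuple.
    """
    if isinstance(preset, str):
        if set(preset) <= {"0", "1"} and len(preset) == 5:
            return _factor_task(tuple(int(c) for c in preset))
        try:
            return PRESETS[preset]()
        except KeyError:
            raise ValueError(
                f"unknown task {preset!r}; expected one of {sorted(PRESETS)} "
                "or a 5-bit factor string"
            ) from None
    bits = tuple(preset)
    if len(bits) != 5:
        raise ValueError("factor vector must have exactly 5 entries")
    return _factor_task(bits)


def enumerate_factorial_tasks() -> list[TaskSpec]:
    """All 32 tasks of the 2^5 design-factor grid, in binary order."""
    return [_factor_task(bits) for bits in product((0, 1), repeat=5)]


def make_schedule(task: TaskSpec, seed=None, n_trials: int | None = None) -> RewardSchedule:
    """Generate the outcome schedule a session of this task runs on."""
    n_trials = n_trials or task.n_trials
    if task.schedule_kind == "walk":
        cfg = replace(task.walk, n_trials=n_trials, seed=seed)
        return generate_walk(cfg, kind=task.outcome_kind)
    if task.schedule_kind == "jump":
        return generate_jump_schedule(
            n_arms=task.n_arms, n_trials=n_trials, seed=seed, **task.schedule_params
        )
    if task.schedule_kind == "block":
        return generate_block_schedule(
            n_trials=n_trials, seed=seed, **task.schedule_params
        )
    raise ValueError(f"unknown schedule kind {task.schedule_kind!r}")


def sample_transition(task: TaskSpec, start_state: int, action: int, rng) -> tuple[int, bool]:
    """Draw the second-stage state reached by a first-stage action."""
    if not 0 <= start_state < task.n_start_states:
        raise ValueError(f"invalid start state {start_state}")
    if action not in (0, 1):
        raise ValueError(f"invalid first-stage action {action}")
    dest = int(task.common_dest[start_state, action])
    if task.transition_kind == "deterministic":
        return dest, True
    common = rng.random() < task.common_prob
    return (dest, True) if common else (1 - dest, False)


def sample_outcome(
    task: TaskSpec,
    schedule: RewardSchedule,
    second_state: int,
    action: int,
    trial: int,
    rng,
) -> float:
    """Draw (probability kind) or read off (scalar kind) the reward."""
    if trial >= schedule.n_trials:
        raise ValueError("trial index beyond schedule length")
    value = schedule.values[trial, task.arm_index(second_state, action)]
    if task.outcome_kind == "scalar":
        return float(value)
    return float(rng.random() < value)
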