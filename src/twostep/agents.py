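"""The dual-system (hybrid) reinforcement-learning agent.

The agent combines two valuation systems:

* a **model-free** SARSA(λ) learner that maintains a lookup table
  Q_MF(s, a) updated by temporal-difference errors with per-trial
  eligibility traces, and
* a **model-based** planner that recomputes first-stage action values
  on every trial by a one-step Bellman backup through its transition
  beliefs onto the maxima of the second-stage Q_MF values (at the
  second stage the two systems coincide, so Q_MB = Q_MF there).

First-stage choice follows a softmax over the convex mixture
Q_net = w·Q_MB + (1−w)·Q_MF, optionally biased toward repeating the
previous stimulus choice (stickiness π) or the previous response key
(response stickiness ρ).  Second-stage choice uses the model-free
values alone.

``run_session`` simulates a full session through the compiled kernel in
``_core``; the module-level operations (``mf_update``, ``mb_values``,
``choice_probabilities``, ...) are a plain-Python implementation of the
same machinery, used for scalar work and as a cross-check of the
compiled path (``engine="python"``).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import _core
from .session import SessionData
from .tasks import TaskSpec
from .walks import RewardSchedule

__all__ = [
    "AgentParams",
    "AgentState",
    "BELIEF_MODES",
    "new_state",
    "mf_update",
    "mb_values",
    "net_values",
    "choice_probabilities",
    "update_transition_belief",
    "run_session",
]

BELIEF_MODES = {
    "known": _core.BELIEF_KNOWN,
    "one_shot": _core.BELIEF_ONE_SHOT,
    "three_structure": _core.BELIEF_THREE_STRUCTURE,
}


@dataclass(frozen=True)
class AgentParams:
    """The six free parameters of the hybrid agent.

    alpha : learning rate in [0, 1]
    beta  : softmax inverse temperature, >= 0
    lam   : eligibility-trace decay λ in [0, 1]
    w     : model-based weight in [0, 1] (0 = pure MF, 1 = pure MB)
    pi    : first-stage choice stickiness (perseveration when > 0)
    rho   : first-stage response-key stickiness
    """

    alpha: float
    beta: float
    lam: float
    w: float
    pi: float = 0.0
    rho: float = 0.0

    def __post_init__(self):
        for name in ("alpha", "lam", "w"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.beta < 0:
            raise ValueError(f"beta={self.beta} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AgentParams":
        return cls(**d)


@dataclass
class AgentState:
    """Mutable learning state of one agent on one task.

    ``q_first[s, a]`` are model-free first-stage values per start state
    (kept separate per start state: this is what prevents model-free
    generalization across equivalent start states), ``q_second[s2, a]``
    the second-stage values shared by both systems.  ``belief_p0[s, a]``
    is the believed probability that action ``a`` in start state ``s``
    leads to second-stage state 0.
    """

    task: TaskSpec
    belief_mode: str = "known"
    q_first: np.ndarray = None
    q_second: np.ndarray = None
    e_first: np.ndarray = None
    e_second: np.ndarray = None
    belief_p0: np.ndarray = None
    seen: np.ndarray = None
    transition_counts: np.ndarray = None
    last_first_choice: int | None = None
    last_key: int | None = None

    def reset_eligibility(self) -> None:
        self.e_first[:] = 0.0
        self.e_second[:] = 0.0


def new_state(task: TaskSpec, belief_mode: str = "known") -> AgentState:
    """Fresh agent state: all Q values zero, beliefs per the mode."""
    if belief_mode not in BELIEF_MODES:
        raise ValueError(
            f"unknown belief mode {belief_mode!r}; expected one of {sorted(BELIEF_MODES)}"
        )
    if belief_mode == "three_structure" and (
        task.n_start_states != 1 or task.transition_kind != "stochastic"
    ):
        raise ValueError(
            "three_structure belief applies to single-start stochastic tasks"
        )
    n_start, n_sec = task.n_start_states, task.n_second_actions
    belief_p0 = _core._init_belief_p0(
        n_start,
        BELIEF_MODES[belief_mode],
        task.transition_kind == "deterministic",
        task.common_prob,
        task.common_dest,
    )
    return AgentState(
        task=task,
        belief_mode=belief_mode,
        q_first=np.zeros((n_start, 2)),
        q_second=np.zeros((2, n_sec)),
        e_first=np.zeros((n_start, 2)),
        e_second=np.zeros((2, n_sec)),
        belief_p0=belief_p0,
        seen=np.zeros(n_start, dtype=int),
        transition_counts=np.zeros((2, 2)),
    )


def mf_update(
    state: AgentState,
    params: AgentParams,
    stage_1: tuple[int, int],
    stage_2: tuple[int, int],
    reward: float,
) -> AgentState:
    """Apply one trial's SARSA(λ) updates for both visited pairs.

    Eligibilities must be freshly reset at trial start.  Each visited
    pair's trace is incremented before that stage's update and all
    traces decay by λ after each update, so the first-stage pair
    receives the second-stage reward prediction error scaled by λ.
    """
    s1, a1 = stage_1
    s2, a2 = stage_2
    alpha, lam = params.alpha, params.lam

    # first-stage update, driven by the selected second-stage value
    state.e_first[s1, a1] += 1.0
    delta1 = state.q_second[s2, a2] - state.q_first[s1, a1]
    state.q_first += alpha * delta1 * state.e_first
    state.q_second += alpha * delta1 * state.e_second
    state.e_first *= lam
    state.e_second *= lam

    # second-stage update, driven by the obtained reward
    state.e_second[s2, a2] += 1.0
    delta2 = reward - state.q_second[s2, a2]
    state.q_first += alpha * delta2 * state.e_first
    state.q_second += alpha * delta2 * state.e_second
    state.e_first *= lam
    state.e_second *= lam
    return state


def mb_values(state: AgentState, start_state: int) -> np.ndarray:
    """Bellman first-stage values under the current transition belief."""
    maxima = state.q_second.max(axis=1)
    p0 = state.belief_p0[start_state]
    return p0 * maxima[0] + (1.0 - p0) * maxima[1]


def net_values(q_mb: np.ndarray, q_mf: np.ndarray, w: float) -> np.ndarray:
    """Convex w-mixture of model-based and model-free action values."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    return w * np.asarray(q_mb, dtype=float) + (1.0 - w) * np.asarray(q_mf, dtype=float)


def choice_probabilities(
    values,
    params: AgentParams,
    last_first_choice: int | None = None,
    last_key: int | None = None,
    action_keys=None,
) -> np.ndarray:
    """Softmax choice probabilities with first-stage stickiness biases.

    ``action_keys[a]`` gives the response key mapped to action ``a`` on
    the current trial; stickiness terms apply only when the previous
    references are provided (first stage).  Probabilities are invariant
    to adding a constant to all values.
    """
    v = np.asarray(values, dtype=float).copy()
    if not np.all(np.isfinite(v)):
        raise ValueError("action values must be finite")
    if last_first_choice is not None:
        v[last_first_choice] += params.pi
    if last_key is not None and action_keys is not None:
        for a, key in enumerate(action_keys):
            if key == last_key:
                v[a] += params.rho
    z = params.beta * v
    z -= z.max()
    expz = np.exp(z)
    return expz / expz.sum()


def update_transition_belief(
    state: AgentState, mode: str, observed: tuple[int, int, int]
) -> AgentState:
    """Update transition beliefs from one observed (s, a, s') triple.

    known — beliefs stay at the veridical transition matrix.
    one_shot — the first observed transition from a start state reveals
    that state's full deterministic mapping (the other action must lead
    to the other second-stage state).
    three_structure — tally the observation and adopt the maximum-
    likelihood structure among the flat and the two symmetric
    common/rare structures, preferring flat on ties.
    """
    if mode not in BELIEF_MODES:
        raise ValueError(f"unknown belief mode {mode!r}")
    start, action, second = observed
    if mode == "one_shot":
        if not state.seen[start]:
            state.belief_p0[start, action] = 1.0 if second == 0 else 0.0
            state.belief_p0[start, 1 - action] = 0.0 if second == 0 else 1.0
            state.seen[start] = 1
    elif mode == "three_structure":
        state.transition_counts[action, second] += 1.0
        p00, p01 = _core._select_structure(
            state.transition_counts, state.task.common_prob
        )
        state.belief_p0[0, 0] = p00
        state.belief_p0[0, 1] = p01
    return state


def session_uniforms(rng, n_trials: int) -> np.ndarray:
    """The (n_trials, 6) uniform block driving one session.

    Columns: start state, key layout, first choice, transition, second
    choice, outcome.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.random((n_trials, 6))


def _kernel_args(task: TaskSpec, schedule: RewardSchedule):
    return (
        np.ascontiguousarray(schedule.values),
        task.outcome_kind == "scalar",
        task.n_start_states,
        task.n_second_actions,
        task.transition_kind == "deterministic",
        task.common_prob,
        np.ascontiguousarray(task.common_dest),
    )


def run_session(
    task: TaskSpec,
    schedule: RewardSchedule,
    params: AgentParams,
    n_trials: int | None = None,
    belief_mode: str = "known",
    seed=None,
    engine: str = "numba",
) -> SessionData:
    """Simulate one full session of the hybrid agent on a task.

    The session is a deterministic function of (task, schedule, params,
    seed).  ``engine="python"`` runs the uncompiled reference loop,
    which must produce an identical record.
    """
    n_trials = n_trials or task.n_trials
    if schedule.n_trials < n_trials:
        raise ValueError("schedule shorter than requested session")
    if schedule.n_arms != task.n_arms:
        raise ValueError(
            f"schedule has {schedule.n_arms} arms but task needs {task.n_arms}"
        )
    if belief_mode not in BELIEF_MODES:
        raise ValueError(f"unknown belief mode {belief_mode!r}")
    u = session_uniforms(seed, n_trials)

    if engine == "python":
        return _run_session_python(task, schedule, params, n_trials, belief_mode, u)
    if engine != "numba":
        raise ValueError(f"unknown engine {engine!r}")

    out_i = np.zeros((6, n_trials), dtype=np.int64)
    out_r = np.zeros(n_trials)
    values, scalar, n_start, n_sec, det, cp, dest = _kernel_args(task, schedule)
    _core._simulate(
        values[:n_trials], scalar, n_start, n_sec, det, cp, dest,
        params.alpha, params.beta, params.lam, params.w, params.pi, params.rho,
        BELIEF_MODES[belief_mode], u,
        out_i[0], out_i[1], out_i[2], out_i[3], out_i[4], out_i[5], out_r,
    )
    return SessionData.from_arrays(
        out_i[0], out_i[1], out_i[2], out_i[3], out_i[4], out_i[5], out_r,
        schedule=schedule, task_name=task.name,
    )


def _run_session_python(task, schedule, params, n_trials, belief_mode, u):
    """Uncompiled reference session loop built from the scalar operations."""
    state = new_state(task, belief_mode)
    rec = {k: [] for k in ("start", "c1", "key1", "common", "s2", "c2", "reward")}
    for t in range(n_trials):
        s = int(u[t, 0] >= 0.5) if task.n_start_states == 2 else 0
        flip = int(u[t, 1] >= 0.5)
        action_keys = [0 ^ flip, 1 ^ flip]
        state.reset_eligibility()

        q_net = net_values(mb_values(state, s), state.q_first[s], params.w)
        p = choice_probabilities(
            q_net, params, state.last_first_choice, state.last_key, action_keys
        )
        c1 = 0 if u[t, 2] < p[0] else 1

        dest = int(task.common_dest[s, c1])
        if task.transition_kind == "deterministic":
            s2, common = dest, 1
        elif u[t, 3] < task.common_prob:
            s2, common = dest, 1
        else:
            s2, common = 1 - dest, 0

        if task.n_second_actions == 2:
            p2 = choice_probabilities(state.q_second[s2], params)
            c2 = 0 if u[t, 4] < p2[0] else 1
        else:
            c2 = 0

        scheduled = schedule.values[t, task.arm_index(s2, c2)]
        if task.outcome_kind == "scalar":
            r = float(scheduled)
        else:
            r = float(u[t, 5] < scheduled)

        mf_update(state, params, (s, c1), (s2, c2), r)
        update_transition_belief(state, belief_mode, (s, c1, s2))
        state.last_first_choice = c1
        state.last_key = c1 ^ flip

        rec["start"].append(s)
        rec["c1"].append(c1)
        rec["key1"].append(c1 ^ flip)
        rec["common"].append(common)
        rec["s2"].append(s2)
        rec["c2"].append(c2)
        rec["reward"].append(r)
    return SessionData.from_arrays(
        rec["start"], rec["c1"], rec["key1"], rec["common"], rec["s2"], rec["c2"],
        rec["reward"], schedule=schedule, task_name=task.name,
    )
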