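"""Seeded synthetic cohorts: sessions with known ground-truth parameters.

No public behavioral dataset accompanies the task family, so cohorts of
simulated agents stand in for human samples everywhere one is needed:
testing the analysis pipeline end to end, exercising the exclusion
rules, and driving parameter-recovery studies.  Each subject gets an
independent schedule (as each participant did) and an independent
session stream, all derived from one master seed so regeneration is
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import AgentParams, run_session
from .fitting import default_belief_for_fitting
from .session import SessionData
from .tasks import TaskSpec, make_task, make_schedule

__all__ = [
    "TABLE1_MEDIANS",
    "CohortSpec",
    "Cohort",
    "generate_cohort",
    "inject_timeouts",
    "write_cohort",
    "read_cohort",
]

# Median fitted parameters of the human cohorts, used to center
# synthetic populations on realistic operating points.
TABLE1_MEDIANS = {
    "daw": dict(beta=3.35, alpha=0.34, lam=0.65, pi=0.21, rho=0.05, w=0.27),
    "novel": dict(beta=0.72, alpha=0.67, lam=0.62, pi=0.0, rho=-0.06, w=0.48),
}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``scheme`` selects how per-subject parameters are drawn:
    "fixed" uses ``params`` for everyone; "uniform" draws α, λ, w
    uniformly on [0, 1] and β uniformly on [0, 10] (stickiness 0);
    "median" uses the fitted human medians for the task family but
    draws w uniformly, the heterogeneity the w-reward correlation
    analyses rely on.
    """

    task: str
    n_subjects: int
    n_trials: int | None = None
    scheme: str = "median"
    params: AgentParams | None = None
    timeout_rate: float = 0.0
    seed: int = 0
    belief_mode: str | None = None

    def __post_init__(self):
        if self.scheme not in ("fixed", "uniform", "median"):
            raise ValueError(f"unknown parameter scheme {self.scheme!r}")
        if self.scheme == "fixed" and self.params is None:
            raise ValueError("fixed scheme requires explicit params")
        if not 0.0 <= self.timeout_rate < 1.0:
            raise ValueError("timeout_rate must lie in [0, 1)")


@dataclass
class Cohort:
    spec: CohortSpec
    task: TaskSpec
    sessions: list
    truth: pd.DataFrame
    schedules: list = field(default_factory=list)


def _sample_params(spec: CohortSpec, task: TaskSpec, rng) -> AgentParams:
    if spec.scheme == "fixed":
        return spec.params
    if spec.scheme == "uniform":
        return AgentParams(
            alpha=rng.uniform(0, 1), beta=rng.uniform(0, 10),
            lam=rng.uniform(0, 1), w=rng.uniform(0, 1),
        )
    key = "novel" if task.outcome_kind == "scalar" else "daw"
    med = TABLE1_MEDIANS[key]
    return AgentParams(
        alpha=med["alpha"], beta=med["beta"], lam=med["lam"],
        w=rng.uniform(0, 1), pi=med["pi"], rho=med["rho"],
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate one cohort: per-subject sessions, truth table, schedules."""
    task = make_task(spec.task)
    n_trials = spec.n_trials or task.n_trials
    belief_mode = spec.belief_mode or default_belief_for_fitting(task)
    sessions, schedules, rows = [], [], []
    for i in range(spec.n_subjects):
        ss = np.random.SeedSequence([int(spec.seed), i])
        samp, sched, sess, tmo = ss.spawn(4)
        params = _sample_params(spec, task, np.random.default_rng(samp))
        schedule = make_schedule(task, seed=sched, n_trials=n_trials)
        session = run_session(
            task, schedule, params, n_trials=n_trials,
            belief_mode=belief_mode, seed=sess,
        )
        if spec.timeout_rate > 0:
            session = inject_timeouts(session, spec.timeout_rate, seed=tmo)
        session.meta["subject"] = i
        sessions.append(session)
        schedules.append(schedule)
        rows.append({"subject": i, **params.to_dict()})
    truth = pd.DataFrame(rows, columns=["subject", *AgentParams(0, 0, 0, 0).to_dict()])
    return Cohort(spec=spec, task=task, sessions=sessions, truth=truth,
                  schedules=schedules)


def inject_timeouts(session: SessionData, rate: float, seed=None) -> SessionData:
    """Flag a Bernoulli(rate) subset of trials as timed out.

    Timed-out trials lose their choices and reward (as when a
    participant fails to respond in time), letting the exclusion rules
    downstream be exercised on synthetic data.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return session
    rng = np.random.default_rng(seed)
    table = session.table.copy()
    hit = rng.random(len(table)) < rate
    table.loc[hit, "timeout"] = 1
    for col in ("choice1", "key1", "common", "state2", "choice2"):
        table.loc[hit, col] = -1
    table.loc[hit, "reward"] = np.nan
    return SessionData(
        table, schedule=session.schedule, task_name=session.task_name,
        meta=dict(session.meta),
    )


def write_cohort(cohort: Cohort, directory) -> None:
    """Persist a cohort as flat text: one session CSV per subject, a
    truth table, per-subject schedules, and a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, (session, schedule) in enumerate(zip(cohort.sessions, cohort.schedules)):
        session.write_csv(directory / f"subject_{i:04d}.csv")
        schedule.write_tsv(directory / f"schedule_{i:04d}.tsv")
    cohort.truth.to_csv(directory / "truth.csv", index=False)
    spec = cohort.spec
    manifest = {
        "task": spec.task,
        "n_subjects": spec.n_subjects,
        "n_trials": spec.n_trials,
        "scheme": spec.scheme,
        "params": spec.params.to_dict() if spec.params else None,
        "timeout_rate": spec.timeout_rate,
        "seed": spec.seed,
        "belief_mode": spec.belief_mode,
        "outcome_kind": cohort.task.outcome_kind,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(directory) -> Cohort:
    """Round-trip counterpart of ``write_cohort``."""
    from .walks import RewardSchedule

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    params = manifest.pop("params")
    outcome_kind = manifest.pop("outcome_kind")
    spec = CohortSpec(
        params=AgentParams.from_dict(params) if params else None, **manifest
    )
    task = make_task(spec.task)
    truth = pd.read_csv(directory / "truth.csv")
    sessions, schedules = [], []
    for i in range(spec.n_subjects):
        schedule = RewardSchedule.read_tsv(
            directory / f"schedule_{i:04d}.tsv", kind=outcome_kind
        )
        session = SessionData.read_csv(
            directory / f"subject_{i:04d}.csv", schedule=schedule
        )
        session.meta["subject"] = i
        sessions.append(session)
        schedules.append(schedule)
    return Cohort(spec=spec, task=task, sessions=sessions, truth=truth,
                  schedules=schedules)
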