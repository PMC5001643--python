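"""Maximum a posteriori fitting of the hybrid agent to session data.

Parameters are estimated per session by maximizing the log posterior
(log likelihood plus weak empirical priors: a Gamma prior on the
inverse temperature and Normal priors on the stickiness parameters,
flat priors within bounds for everything else) with multiple randomly
initialized restarts of a bounded quasi-Newton optimizer.

Model variants pin the model-based weight at 0 (pure model-free) or 1
(pure model-based) and toggle the stickiness terms; variants are
compared by BIC and AIC.  A parameter-recovery harness simulates
cohorts with known parameters and reports per-parameter correlations
between truth and estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

from . import _core
from .agents import AgentParams, BELIEF_MODES, run_session
from .session import SessionData
from .tasks import TaskSpec, make_schedule

__all__ = [
    "PriorSpec",
    "ModelVariant",
    "FitResult",
    "default_belief_for_fitting",
    "session_log_likelihood",
    "fit_session",
    "compare_models",
    "parameter_recovery",
]

PARAM_ORDER = ("alpha", "beta", "lam", "w", "pi", "rho")

_BOUNDS = {
    "alpha": (0.0, 1.0),
    "beta": (0.0, 20.0),
    "lam": (0.0, 1.0),
    "w": (0.0, 1.0),
    "pi": (-20.0, 20.0),
    "rho": (-20.0, 20.0),
}


@dataclass(frozen=True)
class PriorSpec:
    """Weak empirical priors used for MAP estimation.

    The inverse temperature gets a Gamma(shape, scale) prior and the
    stickiness parameters share a Normal(mean, sd) prior; all other
    parameters are flat on their bounds.
    """

    beta_shape: float = 4.82
    beta_scale: float = 0.88
    stickiness_mean: float = 0.15
    stickiness_sd: float = 1.42

    def log_prior(self, name: str, value: float) -> float:
        if name == "beta":
            # Gamma(shape, scale) log density in closed form (the
            # optimizer evaluates this in its inner loop)
            a, s = self.beta_shape, self.beta_scale
            if value <= 0:
                return -np.inf
            return float(
                (a - 1.0) * math.log(value) - value / s - a * math.log(s) - gammaln(a)
            )
        if name in ("pi", "rho"):
            m, sd = self.stickiness_mean, self.stickiness_sd
            z = (value - m) / sd
            return float(-0.5 * z * z - math.log(sd) - 0.5 * math.log(2.0 * math.pi))
        return 0.0

    def sample(self, name: str, rng: np.random.Generator) -> float:
        """Draw a restart initialization: priors where informative,
        uniform within bounds otherwise."""
        if name == "beta":
            return float(rng.gamma(self.beta_shape, self.beta_scale))
        if name in ("pi", "rho"):
            return float(rng.normal(self.stickiness_mean, self.stickiness_sd))
        lo, hi = _BOUNDS[name]
        return float(rng.uniform(lo, hi))


@dataclass(frozen=True)
class ModelVariant:
    """One nested variant of the hybrid model.

    ``w_mode`` is "free" (hybrid), "mf" (w pinned at 0) or "mb"
    (w pinned at 1); the stickiness flags control whether π and ρ are
    estimated or pinned at 0.
    """

    w_mode: str = "free"
    include_pi: bool = True
    include_rho: bool = True

    def __post_init__(self):
        if self.w_mode not in ("free", "mf", "mb"):
            raise ValueError(f"unknown w_mode {self.w_mode!r}")

    @property
    def name(self) -> str:
        tag = {"free": "hybrid", "mf": "pure_mf", "mb": "pure_mb"}[self.w_mode]
        sticky = ("pi" if self.include_pi else "") + ("rho" if self.include_rho else "")
        return f"{tag}_{sticky or 'nosticky'}"

    @property
    def free_params(self) -> tuple[str, ...]:
        names = ["alpha", "beta", "lam"]
        if self.w_mode == "free":
            names.append("w")
        if self.include_pi:
            names.append("pi")
        if self.include_rho:
            names.append("rho")
        return tuple(names)

    def to_agent_params(self, values: dict) -> AgentParams:
        full = {"alpha": 0.0, "beta": 0.0, "lam": 0.0, "pi": 0.0, "rho": 0.0}
        full["w"] = {"free": values.get("w", 0.0), "mf": 0.0, "mb": 1.0}[self.w_mode]
        for name in self.free_params:
            full[name] = values[name]
        return AgentParams(**full)


@dataclass
class FitResult:
    params: AgentParams
    variant: ModelVariant
    log_posterior: float
    log_likelihood: float
    n_params: int
    n_obs: int
    bic: float
    aic: float
    best_restart: int
    restart_log_posteriors: np.ndarray = field(repr=False, default=None)

    @property
    def restart_spread(self) -> float:
        """Range of restart optima; large values flag identifiability trouble."""
        return float(np.ptp(self.restart_log_posteriors))


def default_belief_for_fitting(task: TaskSpec) -> str:
    """Transition-learning assumption matching how participants were
    trained: one-shot inference for deterministic two-start tasks,
    selection among the three candidate structures for single-start
    stochastic tasks."""
    if task.transition_kind == "deterministic" and task.n_start_states == 2:
        return "one_shot"
    if task.transition_kind == "stochastic" and task.n_start_states == 1:
        return "three_structure"
    return "known"


def _session_arrays(session: SessionData):
    t = session.table
    return (
        np.ascontiguousarray(t["start_state"].to_numpy(np.int64)),
        np.ascontiguousarray(t["choice1"].to_numpy(np.int64)),
        np.ascontiguousarray(t["key1"].to_numpy(np.int64)),
        np.ascontiguousarray(t["state2"].to_numpy(np.int64)),
        np.ascontiguousarray(t["choice2"].to_numpy(np.int64)),
        np.ascontiguousarray(np.nan_to_num(t["reward"].to_numpy(float))),
        np.ascontiguousarray(t["timeout"].to_numpy(np.int64)),
    )


def session_log_likelihood(
    params: AgentParams,
    session: SessionData,
    task: TaskSpec,
    belief_mode: str | None = None,
    second_stage_choice: bool | None = None,
) -> float:
    """Log likelihood of the observed choices under the hybrid model.

    The agent's internal state is rolled forward on the participant's
    actual choices and rewards.  Second-stage choices enter the
    likelihood only when the task affords a real second-stage choice;
    forced responses contribute nothing.
    """
    belief_mode = belief_mode or default_belief_for_fitting(task)
    if second_stage_choice is None:
        second_stage_choice = task.n_second_actions == 2
    schedule = session.schedule
    if schedule is not None and schedule.n_arms != task.n_arms:
        raise ValueError("schedule/task arm mismatch")
    arrays = _session_arrays(session)
    return float(
        _core._log_likelihood(
            task.n_start_states,
            task.n_second_actions,
            task.transition_kind == "deterministic",
            task.common_prob,
            np.ascontiguousarray(task.common_dest),
            params.alpha, params.beta, params.lam, params.w, params.pi, params.rho,
            BELIEF_MODES[belief_mode],
            *arrays,
            second_stage_choice,
        )
    )


def _n_observations(session: SessionData, second_stage_choice: bool) -> int:
    n_valid = len(session.valid())
    return n_valid * (2 if second_stage_choice else 1)


def fit_session(
    session: SessionData,
    task: TaskSpec,
    priors: PriorSpec | None = None,
    variant: ModelVariant | None = None,
    n_restarts: int = 25,
    seed=None,
    belief_mode: str | None = None,
    max_timeout_frac: float = 0.2,
) -> FitResult:
    """MAP-fit one session, returning the best of ``n_restarts`` starts.

    Sessions with more than ``max_timeout_frac`` timed-out trials are
    rejected (the exclusion criterion applied to human data).
    """
    priors = priors or PriorSpec()
    variant = variant or ModelVariant()
    belief_mode = belief_mode or default_belief_for_fitting(task)
    second_stage_choice = task.n_second_actions == 2
    if session.n_timeouts > max_timeout_frac * len(session):
        raise ValueError(
            f"session excluded: {session.n_timeouts}/{len(session)} trials timed out"
        )

    names = variant.free_params
    bounds = [_BOUNDS[n] for n in names]
    rng = np.random.default_rng(seed)

    # hoist the per-trial arrays and kernel constants out of the
    # objective: the optimizer calls it thousands of times per session
    arrays = _session_arrays(session)
    kernel_const = (
        task.n_start_states,
        task.n_second_actions,
        task.transition_kind == "deterministic",
        task.common_prob,
        np.ascontiguousarray(task.common_dest),
    )
    belief_code = BELIEF_MODES[belief_mode]

    def neg_log_post(x):
        values = dict(zip(names, x))
        params = variant.to_agent_params(values)
        ll = _core._log_likelihood(
            *kernel_const,
            params.alpha, params.beta, params.lam, params.w, params.pi, params.rho,
            belief_code, *arrays, second_stage_choice,
        )
        lp = sum(priors.log_prior(n, v) for n, v in values.items())
        obj = -(ll + lp)
        # the Gamma prior is -inf at beta = 0; keep the objective finite
        # so bounded quasi-Newton steps remain well defined
        return obj if np.isfinite(obj) else 1e12

    best = None
    log_posts = np.full(n_restarts, -np.inf)
    failures = []
    for k in range(n_restarts):
        x0 = np.array([
            np.clip(priors.sample(n, rng), *_BOUNDS[n]) for n in names
        ])
        try:
            res = optimize.minimize(
                neg_log_post, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-6, "maxiter": 500},
            )
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover
            failures.append(str(exc))
            continue
        log_posts[k] = -res.fun
        if best is None or -res.fun > -best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {n_restarts} restarts failed; last errors: {failures[-3:]}"
        )

    values = dict(zip(names, best.x))
    params = variant.to_agent_params(values)
    ll = session_log_likelihood(params, session, task, belief_mode, second_stage_choice)
    k_free = len(names)
    n_obs = _n_observations(session, second_stage_choice)
    return FitResult(
        params=params,
        variant=variant,
        log_posterior=-float(best.fun),
        log_likelihood=ll,
        n_params=k_free,
        n_obs=n_obs,
        bic=-2.0 * ll + k_free * np.log(n_obs),
        aic=-2.0 * ll + 2.0 * k_free,
        best_restart=int(np.argmax(log_posts)),
        restart_log_posteriors=log_posts,
    )


def compare_models(
    session: SessionData,
    task: TaskSpec,
    variants=None,
    priors: PriorSpec | None = None,
    n_restarts: int = 25,
    seed=None,
    belief_mode: str | None = None,
) -> pd.DataFrame:
    """Fit several nested variants and tabulate their BIC/AIC."""
    if variants is None:
        variants = [
            ModelVariant("free", True, True),
            ModelVariant("mf", True, True),
            ModelVariant("mb", True, True),
        ]
    rows = []
    ss = np.random.SeedSequence(seed)
    for variant, child in zip(variants, ss.spawn(len(variants))):
        fit = fit_session(
            session, task, priors=priors, variant=variant,
            n_restarts=n_restarts, seed=child, belief_mode=belief_mode,
        )
        rows.append(
            {
                "variant": variant.name,
                "log_lik": fit.log_likelihood,
                "k": fit.n_params,
                "bic": fit.bic,
                "aic": fit.aic,
            }
        )
    return pd.DataFrame(rows)


def default_param_sampler(variant: ModelVariant, priors: PriorSpec | None = None):
    """Truth sampler for recovery studies.

    Each free parameter is drawn from its prior where one is
    informative (β from the Gamma prior, stickiness from the Normal
    prior) and uniformly within its bounds otherwise — the same
    population the MAP machinery assumes.
    """
    priors = priors or PriorSpec()

    def sample(rng: np.random.Generator) -> AgentParams:
        values = {
            n: float(np.clip(priors.sample(n, rng), *_BOUNDS[n]))
            for n in variant.free_params
        }
        return variant.to_agent_params(values)

    return sample


def parameter_recovery(
    task: TaskSpec,
    n_agents: int = 200,
    n_trials: int | None = None,
    param_sampler=None,
    seed=0,
    n_restarts: int = 25,
    variant: ModelVariant | None = None,
    priors: PriorSpec | None = None,
    belief_mode: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate agents with known parameters, refit them, correlate.

    Returns ``(summary, detail)``: the summary has one row per free
    parameter with the Pearson r between truth and estimate; the detail
    table has the per-agent true and estimated values.
    """
    variant = variant or ModelVariant()
    param_sampler = param_sampler or default_param_sampler(variant)
    n_trials = n_trials or task.n_trials
    belief_mode = belief_mode or default_belief_for_fitting(task)
    names = variant.free_params

    records = []
    for i in range(n_agents):
        agent_ss = np.random.SeedSequence([int(seed), i])
        sched_seed, sess_seed, fit_seed, samp_seed = agent_ss.spawn(4)
        truth = param_sampler(np.random.default_rng(samp_seed))
        schedule = make_schedule(task, seed=sched_seed, n_trials=n_trials)
        session = run_session(
            task, schedule, truth, n_trials=n_trials,
            belief_mode=belief_mode, seed=sess_seed,
        )
        fit = fit_session(
            session, task, priors=priors, variant=variant,
            n_restarts=n_restarts, seed=fit_seed, belief_mode=belief_mode,
        )
        row = {"agent": i}
        for n in names:
            row[f"true_{n}"] = getattr(truth, n)
            row[f"est_{n}"] = getattr(fit.params, n)
        records.append(row)
    detail = pd.DataFrame(records)

    rows = []
    for n in names:
        r = float(np.corrcoef(detail[f"true_{n}"], detail[f"est_{n}"])[0, 1])
        rows.append({"parameter": n, "r": r})
    return pd.DataFrame(rows), detail
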