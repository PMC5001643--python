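"""Monte-Carlo estimation of the accuracy-demand trade-off.

A task embodies an accuracy-demand trade-off to the extent that the
reward rate an agent obtains increases with its model-based weight w.
The analysis estimates this as the standardized slope (equivalently the
Pearson correlation) of reward rate on w across a grid of w values,
holding the reward schedule fixed within each replicate so that the
contrast is driven purely by w and not by schedule variation.

Slopes are averaged over many replicates for every (β, α) cell of a
parameter grid, yielding a coefficient surface; the volume under the
surface (excluding the degenerate β = 0 and α = 0 edges) summarizes a
task's overall trade-off strength, and is compared across the 2^5
factorial of task design factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _core
from .agents import BELIEF_MODES, _kernel_args
from .tasks import TaskSpec, enumerate_factorial_tasks, make_schedule
from .walks import RewardSchedule

__all__ = [
    "SurfaceConfig",
    "SlopeSurface",
    "standardized_slope",
    "slope_one_replicate",
    "build_surface",
    "volume_under_surface",
    "drift_sweep",
    "factor_analysis",
]

DEFAULT_W_GRID = np.linspace(0.0, 1.0, 11)
DEFAULT_BETA_GRID = np.linspace(0.0, 10.0, 11)
DEFAULT_ALPHA_GRID = np.linspace(0.0, 1.0, 11)


@dataclass(frozen=True)
class SurfaceConfig:
    """Grids and replication settings for one coefficient surface."""

    task: TaskSpec
    w_grid: np.ndarray = field(default_factory=lambda: DEFAULT_W_GRID.copy())
    beta_grid: np.ndarray = field(default_factory=lambda: DEFAULT_BETA_GRID.copy())
    alpha_grid: np.ndarray = field(default_factory=lambda: DEFAULT_ALPHA_GRID.copy())
    lam: float = 0.5
    n_reps: int = 1000
    n_trials: int = 201
    seed: int = 0
    belief_mode: str = "known"

    def __post_init__(self):
        for name in ("w_grid", "beta_grid", "alpha_grid"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.w_grid) < 2:
            raise ValueError("w_grid needs at least 2 points")
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")


@dataclass
class SlopeSurface:
    """Averaged standardized slopes over a (β, α) grid.

    ``coefficients[i, j]`` is the mean over replicates of the
    standardized slope of reward rate on w at ``beta_grid[i]``,
    ``alpha_grid[j]``; ``rep_std`` is the across-replicate standard
    deviation (so the Monte-Carlo s.e. is ``rep_std / sqrt(n_reps)``).
    """

    coefficients: np.ndarray
    beta_grid: np.ndarray
    alpha_grid: np.ndarray
    n_reps: int
    rep_std: np.ndarray | None = None
    config: SurfaceConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coefficients,
            index=pd.Index(self.beta_grid, name="beta"),
            columns=pd.Index(self.alpha_grid, name="alpha"),
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def standardized_slope(w_values, reward_rates) -> float:
    """Slope of z-scored reward rate on z-scored w (the Pearson r).

    Returns 0 when the reward rates have zero variance, the convention
    for replicates in which w had no effect at all.
    """
    w = np.asarray(w_values, dtype=float)
    r = np.asarray(reward_rates, dtype=float)
    sw = w.std()
    sr = r.std()
    if sw == 0:
        raise ValueError("w grid has zero variance")
    if sr == 0:
        return 0.0
    return float(((w - w.mean()) * (r - r.mean())).mean() / (sw * sr))


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    """Per-replicate stream, identical regardless of evaluation order."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(rep)]))


def _batch_rates(task, schedule, alphas, betas, lams, ws, belief_mode, u):
    values, scalar, n_start, n_sec, det, cp, dest = _kernel_args(task, schedule)
    n_trials = u.shape[1]
    return _core._reward_rates_batch(
        values[:n_trials], scalar, n_start, n_sec, det, cp, dest,
        np.asarray(alphas, float), np.asarray(betas, float),
        np.asarray(lams, float), np.asarray(ws, float),
        BELIEF_MODES[belief_mode], u,
    )


def slope_one_replicate(
    task: TaskSpec,
    schedule: RewardSchedule,
    beta: float,
    alpha: float,
    lam: float,
    w_grid=DEFAULT_W_GRID,
    seed=None,
    n_trials: int | None = None,
    belief_mode: str = "known",
) -> float:
    """Standardized slope of reward rate on w for one shared schedule."""
    w_grid = np.asarray(w_grid, dtype=float)
    n_trials = n_trials or min(task.n_trials, schedule.n_trials)
    rng = np.random.default_rng(seed)
    u = rng.random((len(w_grid), n_trials, 6))
    rates = _batch_rates(
        task, schedule,
        np.full(len(w_grid), alpha), np.full(len(w_grid), beta),
        np.full(len(w_grid), lam), w_grid, belief_mode, u,
    )
    return standardized_slope(w_grid, rates)


def build_surface(config: SurfaceConfig) -> SlopeSurface:
    """Mean standardized-slope surface over the (β, α) grid.

    Every replicate draws a fresh schedule that is shared by all grid
    cells and all w values; each (cell, w) session gets its own stream
    from the replicate's generator.  The result is reproducible under
    the config seed and independent of evaluation order.
    """
    task = config.task
    n_b, n_a, n_w = len(config.beta_grid), len(config.alpha_grid), len(config.w_grid)
    n_cells = n_b * n_a
    betas = np.repeat(config.beta_grid, n_a * n_w)
    alphas = np.tile(np.repeat(config.alpha_grid, n_w), n_b)
    ws = np.tile(config.w_grid, n_cells)
    lams = np.full(n_cells * n_w, config.lam)

    w_z = (config.w_grid - config.w_grid.mean())
    w_norm = w_z / np.sqrt((w_z**2).sum())

    mean = np.zeros(n_cells)
    m2 = np.zeros(n_cells)
    for rep in range(config.n_reps):
        rng = _rep_rng(config.seed, rep)
        schedule = make_schedule(task, seed=rng, n_trials=config.n_trials)
        u = rng.random((n_cells * n_w, config.n_trials, 6))
        rates = _batch_rates(task, schedule, alphas, betas, lams, ws,
                             config.belief_mode, u).reshape(n_cells, n_w)
        centered = rates - rates.mean(axis=1, keepdims=True)
        denom = np.sqrt((centered**2).sum(axis=1))
        slopes = np.where(denom > 0, centered @ w_norm / np.where(denom > 0, denom, 1.0), 0.0)
        delta = slopes - mean
        mean += delta / (rep + 1)
        m2 += delta * (slopes - mean)
    std = np.sqrt(m2 / config.n_reps) if config.n_reps > 1 else None
    return SlopeSurface(
        coefficients=mean.reshape(n_b, n_a),
        beta_grid=config.beta_grid,
        alpha_grid=config.alpha_grid,
        n_reps=config.n_reps,
        rep_std=None if std is None else std.reshape(n_b, n_a),
        config=config,
    )


def volume_under_surface(surface: SlopeSurface) -> float:
    """Riemann-sum volume over the retained (β > 0, α > 0) grid.

    Cells on the β = 0 or α = 0 edges are omitted (a β = 0 agent
    chooses at random and an α = 0 agent never learns, so their slopes
    are pure noise).  The retained cells are treated as a regular
    tiling of (0, β_max] x (0, α_max], so the volume is their mean
    coefficient times that area.
    """
    keep_b = surface.beta_grid > 0
    keep_a = surface.alpha_grid > 0
    if not keep_b.any() or not keep_a.any():
        raise ValueError("no grid cells retained after excluding zero edges")
    retained = surface.coefficients[np.ix_(keep_b, keep_a)]
    area = surface.beta_grid.max() * surface.alpha_grid.max()
    return float(retained.mean() * area)


def drift_sweep(
    task_base: TaskSpec,
    sigmas,
    beta: float = 5.0,
    alpha: float = 0.5,
    lam: float = 0.5,
    n_reps: int = 10_000,
    w_grid=DEFAULT_W_GRID,
    n_trials: int = 201,
    seed: int = 0,
    belief_mode: str = "known",
) -> pd.Series:
    """Mean standardized slope as a function of the walk drift rate σ.

    The (β, α) operating point defaults to (5, 0.5), the median
    parameter regime reported for the original task.  The effects are
    subtle (slope differences of order 0.003 between neighbouring σ),
    so replicate ``rep`` reuses one random stream across all σ values:
    the walks share standard-normal steps scaled by σ and the sessions
    share choice/outcome variates, a common-random-numbers pairing that
    sharpens the comparison *between* drift rates without biasing any
    single estimate.
    """
    if task_base.schedule_kind != "walk":
        raise ValueError("drift sweep requires a walk-schedule task")
    w_grid = np.asarray(w_grid, dtype=float)
    n_w = len(w_grid)
    alphas = np.full(n_w, alpha)
    betas = np.full(n_w, beta)
    lams = np.full(n_w, lam)
    tasks = [
        replace(task_base, walk=replace(task_base.walk, sigma=float(s)))
        for s in sigmas
    ]
    totals = np.zeros(len(tasks))
    for rep in range(n_reps):
        for k, task in enumerate(tasks):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), rep]))
            schedule = make_schedule(task, seed=rng, n_trials=n_trials)
            u = rng.random((n_w, n_trials, 6))
            rates = _batch_rates(task, schedule, alphas, betas, lams, w_grid,
                                 belief_mode, u)
            totals[k] += standardized_slope(w_grid, rates)
    out = {float(s): totals[k] / n_reps for k, s in enumerate(sigmas)}
    return pd.Series(out, name="mean_slope").rename_axis("sigma")


def factor_analysis(
    n_reps: int = 1000,
    seed: int = 0,
    w_grid=DEFAULT_W_GRID,
    beta_grid=DEFAULT_BETA_GRID,
    alpha_grid=DEFAULT_ALPHA_GRID,
    lam: float = 0.5,
    n_trials: int = 201,
    tasks: list[TaskSpec] | None = None,
) -> pd.DataFrame:
    """Volume under the surface for all 32 factorial task designs.

    Returns one row per task with its factor bits, factor count and
    volume.  All tasks share identical grids so volumes are directly
    comparable; the endpoint rows reproduce the zero-factor (Daw
    structure) and five-factor (novel structure) volumes.
    """
    tasks = tasks if tasks is not None else enumerate_factorial_tasks()
    rows = []
    for task in tasks:
        cfg = SurfaceConfig(
            task=task, w_grid=w_grid, beta_grid=beta_grid, alpha_grid=alpha_grid,
            lam=lam, n_reps=n_reps, n_trials=n_trials, seed=seed,
        )
        surface = build_surface(cfg)
        bits = "".join(str(int(b)) for b in task.factors)
        rows.append(
            {
                "factors": bits,
                "n_factors": sum(task.factors),
                "volume": volume_under_surface(surface),
            }
        )
    return pd.DataFrame(rows)
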