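"""Descriptive session analyses: stay probabilities and reward metrics.

The classic diagnostic for dissociating model-free and model-based
control is the probability of repeating the previous first-stage choice
("staying") conditioned on the previous trial's outcome and, depending
on the task family, either the previous transition type (common vs
rare) or whether the current start state matches the previous one.

A pure model-free agent stays more after reward regardless of the
transition; a pure model-based agent shows the crossover interaction —
after a rare transition, reward makes it *switch*, because the other
first-stage action more reliably reaches the rewarded state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session import SessionData
from .tasks import TaskSpec
from .walks import RewardSchedule

__all__ = [
    "StayTable",
    "stay_table_daw",
    "stay_table_equivalence",
    "corrected_reward_rate",
    "correlate_w_reward",
]


@dataclass
class StayTable:
    """Stay probabilities in the 2 x 2 (previous reward, condition) design.

    ``probs[r, c]`` is the stay fraction for previous-reward status
    ``r`` (0 = unrewarded, 1 = rewarded) and condition ``c`` — common vs
    rare previous transition in the Daw-style analysis (1 = common), or
    same vs different start state in the equivalence-style analysis
    (1 = same).  Cells with no usable pairs are NaN, never 0.
    """

    probs: np.ndarray
    counts: np.ndarray
    condition: str  # "transition" | "start_state"

    def cell(self, rewarded: bool, flag: bool) -> float:
        return float(self.probs[int(rewarded), int(flag)])

    def to_frame(self) -> pd.DataFrame:
        labels = (
            ("rare", "common") if self.condition == "transition" else ("different", "same")
        )
        rows = []
        for r in (0, 1):
            for c in (0, 1):
                rows.append(
                    {
                        "prev_reward": "rewarded" if r else "unrewarded",
                        "condition": labels[c],
                        "stay_prob": self.probs[r, c],
                        "n_pairs": int(self.counts[r, c]),
                    }
                )
        return pd.DataFrame(rows)


def _consecutive_pairs(session: SessionData) -> pd.DataFrame:
    """Adjacent non-timeout trial pairs; pairs spanning a gap are dropped."""
    valid = session.valid()
    prev = valid.iloc[:-1].reset_index(drop=True)
    cur = valid.iloc[1:].reset_index(drop=True)
    adjacent = cur["trial"].to_numpy() == prev["trial"].to_numpy() + 1
    return pd.DataFrame(
        {
            "prev_reward": prev["reward"].to_numpy()[adjacent],
            "prev_common": prev["common"].to_numpy()[adjacent],
            "prev_start": prev["start_state"].to_numpy()[adjacent],
            "prev_choice": prev["choice1"].to_numpy()[adjacent],
            "cur_start": cur["start_state"].to_numpy()[adjacent],
            "cur_choice": cur["choice1"].to_numpy()[adjacent],
        }
    )


def _tabulate(rewarded, flag, stay) -> StayTable:
    probs = np.full((2, 2), np.nan)
    counts = np.zeros((2, 2), dtype=int)
    for r in (0, 1):
        for c in (0, 1):
            mask = (rewarded == r) & (flag == c)
            counts[r, c] = mask.sum()
            if counts[r, c]:
                probs[r, c] = stay[mask].mean()
    return StayTable(probs, counts, condition="")


def _binarize_reward(reward: np.ndarray) -> np.ndarray:
    """Rewarded means reward > 0: identity for binary rewards, and the
    win/loss (treasure vs antimatter) framing for scalar payoffs."""
    return (np.asarray(reward) > 0).astype(int)


def stay_table_daw(session: SessionData) -> StayTable:
    """Stay probability by previous reward x previous transition type."""
    pairs = _consecutive_pairs(session)
    stay = (pairs["cur_choice"] == pairs["prev_choice"]).to_numpy().astype(float)
    table = _tabulate(
        _binarize_reward(pairs["prev_reward"]),
        pairs["prev_common"].to_numpy().astype(int),
        stay,
    )
    table.condition = "transition"
    return table


def stay_table_equivalence(session: SessionData, task: TaskSpec) -> StayTable:
    """Stay probability by previous reward x start-state similarity.

    In two-start-state tasks "staying" means choosing the action that
    leads to the same second-stage state as the previous trial's choice,
    not repeating the same action label.  Destinations are resolved
    through the task's common-transition map.
    """
    if task.n_start_states != 2:
        raise ValueError("equivalence analysis requires a 2-start-state task")
    pairs = _consecutive_pairs(session)
    dest = task.common_dest
    prev_dest = dest[pairs["prev_start"], pairs["prev_choice"]]
    cur_dest = dest[pairs["cur_start"], pairs["cur_choice"]]
    stay = (cur_dest == prev_dest).astype(float)
    same_start = (pairs["cur_start"] == pairs["prev_start"]).to_numpy().astype(int)
    table = _tabulate(_binarize_reward(pairs["prev_reward"]), same_start, stay)
    table.condition = "start_state"
    return table


def corrected_reward_rate(
    session: SessionData, schedule: RewardSchedule | None = None
) -> float:
    """Obtained reward rate minus chance performance.

    Chance is the average value across the task's reward distributions
    over the session, i.e. the expected reward per trial of a policy
    choosing uniformly among all terminal arms.  Correcting by it makes
    reward rates comparable across subjects who faced different
    schedules.
    """
    schedule = schedule if schedule is not None else session.schedule
    if schedule is None:
        raise ValueError("no schedule attached to session and none provided")
    rate = session.reward_rate()  # raises on all-timeout sessions
    chance = float(schedule.values[: len(session)].mean())
    return rate - chance


def correlate_w_reward(pairs) -> tuple[float, float]:
    """Pearson correlation between w estimates and corrected reward rates.

    ``pairs`` is an iterable of (w, corrected_rate).  Returns (r, p)
    from the standard two-sided test.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (w, rate) pairs")
    w, rate = arr[:, 0], arr[:, 1]
    if np.ptp(w) == 0 or np.ptp(rate) == 0:
        raise ValueError("correlation undefined: zero variance in inputs")
    res = stats.pearsonr(w, rate)
    return float(res.statistic), float(res.pvalue)
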