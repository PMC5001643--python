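"""Per-trial behavioral records and their flat tabular text format."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .walks import RewardSchedule

__all__ = ["SESSION_COLUMNS", "SessionData"]

SESSION_COLUMNS = [
    "trial",
    "start_state",
    "choice1",
    "key1",
    "common",
    "state2",
    "choice2",
    "reward",
    "timeout",
]

_INT_COLUMNS = [c for c in SESSION_COLUMNS if c != "reward"]


@dataclass
class SessionData:
    """One agent's (or participant's) trial-by-trial record on one task.

    ``table`` has one row per trial with the columns in
    ``SESSION_COLUMNS``.  On timed-out trials the choice fields hold -1
    and the reward is NaN.  The generating schedule travels with the
    session when available, since chance-corrected reward rates need it.
    """

    table: pd.DataFrame
    schedule: RewardSchedule | None = None
    task_name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in SESSION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"session table missing columns: {missing}")
        self.table = self.table[SESSION_COLUMNS].reset_index(drop=True)
        trials = self.table["trial"].to_numpy()
        if len(trials) > 1 and not (np.diff(trials) > 0).all():
            raise ValueError("trial indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_timeouts(self) -> int:
        return int(self.table["timeout"].sum())

    def valid(self) -> pd.DataFrame:
        """Rows for trials with a recorded (non-timeout) response."""
        return self.table[self.table["timeout"] == 0]

    def reward_rate(self) -> float:
        """Mean reward per responded trial."""
        rewards = self.valid()["reward"]
        if rewards.empty:
            raise ValueError("session has no responded trials")
        return float(rewards.mean())

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, schedule: RewardSchedule | None = None) -> "SessionData":
        table = pd.read_csv(path)
        for col in _INT_COLUMNS:
            table[col] = table[col].astype(int)
        return cls(table, schedule=schedule)

    @classmethod
    def from_arrays(
        cls,
        start_state,
        choice1,
        key1,
        common,
        state2,
        choice2,
        reward,
        timeout=None,
        schedule=None,
        task_name="",
    ) -> "SessionData":
        n = len(choice1)
        if timeout is None:
            timeout = np.zeros(n, dtype=int)
        table = pd.DataFrame(
            {
                "trial": np.arange(n),
                "start_state": np.asarray(start_state, dtype=int),
                "choice1": np.asarray(choice1, dtype=int),
                "key1": np.asarray(key1, dtype=int),
                "common": np.asarray(common, dtype=int),
                "state2": np.asarray(state2, dtype=int),
                "choice2": np.asarray(choice2, dtype=int),
                "reward": np.asarray(reward, dtype=float),
                "timeout": np.asarray(timeout, dtype=int),
            }
        )
        return cls(table, schedule=schedule, task_name=task_name)
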