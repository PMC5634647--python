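"""Trial-level dataset container shared by the analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

from .task import (S0, S1, S3, TaskConfig, TrialRecord, STATE_LABELS,
                   ACTION_LABELS)

__all__ = ["Dataset", "records_to_frame", "frame_to_records"]

COLUMNS = ["subject", "trial", "block", "start_state", "first_choice",
           "second_state", "terminal_state", "reward", "contingency_id",
           "contingency_changed", "reward_flip", "high_state"]


@dataclass
class Dataset:
    """One subject's sequence of trials plus the task configuration.

    The configuration matters to the analyses through the block structure
    and, for frequency-indexed models, the block order (which block was
    fast/medium/slow).
    """

    subject: str
    trials: List[TrialRecord]
    config: TaskConfig = field(default_factory=TaskConfig)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_choice_trials(self) -> int:
        return sum(1 for t in self.trials
                   if t.start_state == S0 and t.first_choice is not None)

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.trials)

    def arrays(self) -> dict:
        """Trial fields as flat numpy arrays (for the likelihood core).

        ``choice`` is -1 where no first-level choice was made; ``s2`` and
        ``ter`` are 0/1 indices of the second-level and terminal states.
        """
        n = len(self.trials)
        out = {
            "start": np.empty(n, dtype=np.int64),
            "choice": np.empty(n, dtype=np.int64),
            "s2": np.empty(n, dtype=np.int64),
            "ter": np.empty(n, dtype=np.int64),
            "reward": np.empty(n, dtype=np.float64),
            "block": np.empty(n, dtype=np.int64),
        }
        for i, t in enumerate(self.trials):
            out["start"][i] = t.start_state
            out["choice"][i] = -1 if t.first_choice is None else t.first_choice
            out["s2"][i] = t.second_state - S1
            out["ter"][i] = t.terminal_state - S3
            out["reward"][i] = t.reward
            out["block"][i] = t.block
        return out


def records_to_frame(trials: List[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append({
            "subject": t.subject,
            "trial": t.trial,
            "block": t.block,
            "start_state": STATE_LABELS[t.start_state],
            "first_choice": ("" if t.first_choice is None
                             else ACTION_LABELS[t.first_choice]),
            "second_state": STATE_LABELS[t.second_state],
            "terminal_state": STATE_LABELS[t.terminal_state],
            "reward": t.reward,
            "contingency_id": t.contingency_id,
            "contingency_changed": int(t.contingency_changed),
            "reward_flip": int(t.reward_flip),
            "high_state": STATE_LABELS[t.high_state],
        })
    return pd.DataFrame(rows, columns=COLUMNS)


_STATE_CODES = {v: k for k, v in STATE_LABELS.items()}
_ACTION_CODES = {v: k for k, v in ACTION_LABELS.items()}


def frame_to_records(df: pd.DataFrame) -> List[TrialRecord]:
    records = []
    for _, row in df.iterrows():
        fc = row["first_choice"]
        missing = pd.isna(fc) or fc == ""
        records.append(TrialRecord(
            subject=str(row["subject"]),
            trial=int(row["trial"]),
            block=int(row["block"]),
            start_state=_STATE_CODES[row["start_state"]],
            first_choice=None if missing else _ACTION_CODES[fc],
            second_state=_STATE_CODES[row["second_state"]],
            terminal_state=_STATE_CODES[row["terminal_state"]],
            reward=float(row["reward"]),
            contingency_id=int(row["contingency_id"]),
            contingency_changed=bool(int(row["contingency_changed"])),
            reward_flip=bool(int(row["reward_flip"])),
            high_state=_STATE_CODES[row["high_state"]],
        ))
    return records
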