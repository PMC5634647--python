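"""Model-agnostic behavioral analyses.

The central index is the *stay probability*: the probability of choosing the
first-level action that leads to the same second-level state as was visited
on the previous trial.  It is tabulated in a 2x2 design over the previous
trial's outcome (high vs low reward) and the previous trial's transition
relative to the trial before it (contingency changed vs fixed).

Two variants restrict which previous trials enter the analysis:

* ``"second-level-start"`` (the main analysis): the previous trial started
  at the second level, so no first-level action was experienced there.
  Only these trials separate model-based from model-free control.
* ``"first-level-start"``: the previous trial started at the first level,
  where both systems experience the action leading to the new contingency.

A trial enters the analysis only if it starts at the first level with a
recorded choice and its predecessor is at least the second trial of the
session (so "changed vs fixed" is defined).  Trials following a missed
first-level trial are ineligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .data import Dataset
from .task import A1, S0, S1, S2, terminal_for

__all__ = ["StayProbTable", "stay_probabilities", "condition_anova",
           "performance_summaries"]

REWARD_LEVELS = ("high", "low")
CONTINGENCY_LEVELS = ("changed", "fixed")


@dataclass
class StayProbTable:
    """Per-subject 2x2 stay probabilities and cell trial counts.

    Rows index the previous trial's reward (high, low); columns index the
    previous trial's contingency condition (changed, fixed).  Cells with no
    eligible trials hold probability NaN and count 0.
    """

    subject: str
    variant: str
    probs: np.ndarray   # (2, 2) float, NaN where undefined
    counts: np.ndarray  # (2, 2) int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(REWARD_LEVELS):
            for j, c in enumerate(CONTINGENCY_LEVELS):
                rows.append({"subject": self.subject, "reward": r,
                             "contingency": c,
                             "stay_prob": self.probs[i, j],
                             "n_trials": int(self.counts[i, j])})
        return pd.DataFrame(rows)

    @property
    def complete(self) -> bool:
        return bool(np.all(self.counts > 0))


def stay_probabilities(dataset: Dataset,
                       variant: str = "second-level-start") -> StayProbTable:
    """Tabulate stay probabilities for one subject."""
    if variant not in ("second-level-start", "first-level-start"):
        raise ValueError(f"unknown variant {variant!r}")
    if len(dataset) < 2:
        raise ValueError("need at least two trials")
    stays = np.zeros((2, 2))
    counts = np.zeros((2, 2), dtype=int)
    trials = dataset.trials
    for i in range(1, len(trials)):
        cur, prev = trials[i], trials[i - 1]
        if cur.start_state != S0 or cur.first_choice is None:
            continue
        if prev.trial < 2:
            continue  # "changed vs fixed" undefined for the session's first trial
        if variant == "second-level-start":
            if prev.start_state not in (S1, S2):
                continue
        else:
            if prev.start_state != S0 or prev.first_choice is None:
                continue
        ri = 0 if prev.terminal_state == prev.high_state else 1
        ci = 0 if prev.contingency_changed else 1
        chosen_second = S1 if cur.first_choice == A1 else S2
        counts[ri, ci] += 1
        if chosen_second == prev.second_state:
            stays[ri, ci] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(counts > 0, stays / np.maximum(counts, 1), np.nan)
    return StayProbTable(subject=dataset.subject, variant=variant,
                         probs=probs, counts=counts)


def condition_anova(tables: Sequence[StayProbTable],
                    repeated_measures: bool = False) -> pd.DataFrame:
    """Two-way ANOVA (reward x contingency) on per-subject condition means.

    The default treats each subject's four cell means as independent
    observations (error df = 4N - 4).  With ``repeated_measures=True`` a
    within-subject ANOVA is run instead.  Subjects with undefined cells are
    excluded with a warning.
    """
    used = [t for t in tables if t.complete]
    dropped = len(tables) - len(used)
    if dropped:
        warnings.warn(f"excluded {dropped} subject(s) with empty cells")
    if len(used) < 2:
        raise ValueError("need at least two subjects with complete tables")
    long = pd.concat([t.to_frame() for t in used], ignore_index=True)
    if repeated_measures:
        from statsmodels.stats.anova import AnovaRM
        res = AnovaRM(long, depvar="stay_prob", subject="subject",
                      within=["reward", "contingency"]).fit()
        return res.anova_table
    model = ols("stay_prob ~ C(reward) * C(contingency)", data=long).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table.index = ["reward", "contingency", "reward:contingency", "residual"]
    return table


def performance_summaries(dataset: Dataset) -> pd.DataFrame:
    """Per-block high-reward choice probability and reward rate.

    The high-reward choice probability is the fraction of first-level choice
    trials whose chosen action leads, under the contingency in force on that
    trial, to the terminal state currently carrying the high payoff.  The
    reward rate is the mean reward over all trials of the block.
    """
    rows = []
    df_blocks: dict = {}
    for t in dataset.trials:
        df_blocks.setdefault(t.block, []).append(t)
    for block in sorted(df_blocks):
        trials = df_blocks[block]
        n_choice = high = 0
        for t in trials:
            if t.start_state == S0 and t.first_choice is not None:
                n_choice += 1
                chosen_second = S1 if t.first_choice == A1 else S2
                if terminal_for(chosen_second, t.contingency_id) == t.high_state:
                    high += 1
        rows.append({
            "subject": dataset.subject,
            "block": block,
            "n_trials": len(trials),
            "n_choice_trials": n_choice,
            "high_choice_prob": high / n_choice if n_choice else np.nan,
            "reward_rate": float(np.mean([t.reward for t in trials])),
        })
    return pd.DataFrame(rows)
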