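"""Two-level contingency-change task environment.

The task is a sequential decision problem on five states.  A trial starts
either at the first level ``S0`` (probability 0.5), where two actions ``A1``
and ``A2`` are available, or directly at one of the second-level states
``S1``/``S2`` (probability 0.25 each), where a single forced response is
required.  First-level transitions are deterministic (``A1 -> S1``,
``A2 -> S2``).  The mapping from second-level states to terminal states
``S3``/``S4`` flips between two contingencies every few trials, unsignalled:

* mapping A: ``S1 -> S3``, ``S2 -> S4``
* mapping B: ``S1 -> S4``, ``S2 -> S3``

One terminal state carries a high payoff, the other the complementary low
payoff (the two always sum to 1).  The high payoff drifts across trials as a
bounded Gaussian random walk, and the assignment of high/low to ``S3``/``S4``
swaps on a fixed grid (every 40 trials), never on the same trial as a
contingency flip.

Contingency-flip frequency is manipulated in three 200-trial blocks: fast
(every 3-6 trials), medium (7-10) and slow (11-14), with the order of the
fast and medium blocks counterbalanced across subject groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "S0", "S1", "S2", "S3", "S4", "A1", "A2",
    "MAPPING_A", "MAPPING_B",
    "TaskConfig", "TaskState", "TrialRecord", "Environment",
    "schedule_contingency_changes", "step_reward_walk", "advance_trial",
    "run_episode", "terminal_for",
]

# State / action codes used throughout the package.
S0, S1, S2, S3, S4 = 0, 1, 2, 3, 4
A1, A2 = 0, 1
MAPPING_A, MAPPING_B = 0, 1

STATE_LABELS = {S0: "S0", S1: "S1", S2: "S2", S3: "S3", S4: "S4"}
ACTION_LABELS = {A1: "A1", A2: "A2"}

#: canonical frequency classes, indexing block_change_ranges
FAST, MEDIUM, SLOW = 0, 1, 2

_BLOCK_ORDERS = {
    "fast-medium-slow": (FAST, MEDIUM, SLOW),
    "medium-fast-slow": (MEDIUM, FAST, SLOW),
}


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the contingency-change environment.

    Attributes
    ----------
    n_trials : total trials per subject (blocks * block_length).
    block_length : trials per block.
    block_change_ranges : inclusive (min, max) gap ranges between contingency
        flips for the fast, medium and slow conditions, in that canonical
        order; ``block_order`` maps them onto the three session blocks.
    block_order : ``"fast-medium-slow"`` or ``"medium-fast-slow"``.
    start_probs : probabilities of a trial starting at S0, S1, S2.
    reward_flip_period : the high/low reward assignment swaps every this many
        trials (on trials that are multiples of the period).
    walk_mean, walk_sd : mean and sd of the initial high payoff draw.
    walk_drift : sd of the per-trial Gaussian increment of the payoff walk.
    reward_bounds : support of the payoffs (low payoff = upper bound minus
        high payoff).
    high_payoff_bounds : reflection bounds of the high payoff's walk.  The
        default keeps the high payoff above the midpoint, so the high-reward
        state always pays the unambiguously larger of the two complementary
        payoffs (otherwise a plain reflected walk on the full support would
        spend half its time below the midpoint and the high/low distinction
        would dissolve).
    """

    n_trials: int = 600
    block_length: int = 200
    block_change_ranges: tuple = ((3, 6), (7, 10), (11, 14))
    block_order: str = "fast-medium-slow"
    start_probs: tuple = (0.5, 0.25, 0.25)
    reward_flip_period: int = 40
    walk_mean: float = 0.5
    walk_sd: float = 0.2
    walk_drift: float = 0.15
    reward_bounds: tuple = (0.0, 1.0)
    high_payoff_bounds: tuple = (0.5, 1.0)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.block_order not in _BLOCK_ORDERS:
            raise ValueError(f"unknown block_order {self.block_order!r}")
        if abs(sum(self.start_probs) - 1.0) > 1e-12:
            raise ValueError("start_probs must sum to 1")
        for lo, hi in self.block_change_ranges:
            if lo < 2 or hi < lo:
                raise ValueError("change ranges need min >= 2 and max >= min")
        if self.n_trials % self.block_length != 0:
            raise ValueError("n_trials must be a multiple of block_length")
        if self.n_trials // self.block_length != len(self.block_change_ranges):
            raise ValueError("need one change range per block")
        lo, hi = self.reward_bounds
        hlo, hhi = self.high_payoff_bounds
        if not (lo <= hlo < hhi <= hi):
            raise ValueError("high_payoff_bounds must nest inside reward_bounds")

    @property
    def n_blocks(self) -> int:
        return self.n_trials // self.block_length

    @property
    def frequency_by_block(self) -> tuple:
        """Frequency class (FAST/MEDIUM/SLOW) of each session block.

        For non-standard designs with other than three blocks the order tag
        is moot and blocks map to change-range entries one to one.
        """
        if self.n_blocks != 3:
            return tuple(range(self.n_blocks))
        return _BLOCK_ORDERS[self.block_order]

    @property
    def ordered_ranges(self) -> tuple:
        """Gap ranges in session-block order."""
        return tuple(self.block_change_ranges[f] for f in self.frequency_by_block)

    def block_of(self, trial: int) -> int:
        """1-based block index of a 1-based trial number."""
        return (trial - 1) // self.block_length + 1


@dataclass
class TaskState:
    """Mutable state of the environment between trials."""

    trial_index: int = 0                 # last completed trial (1-based; 0 = none)
    contingency: int = MAPPING_A
    high_reward_state: int = S3
    payoff_high: float = 0.5

    @property
    def payoff_low(self) -> float:
        return 1.0 - self.payoff_high


@dataclass(frozen=True)
class TrialRecord:
    """One trial of the task, as stored in trial logs.

    ``first_choice`` is ``None`` on trials that start at the second level
    (no choice is possible there) and on missed first-level trials in real
    logs.  ``contingency_changed`` marks trials whose transition mapping
    differs from the previous trial; ``reward_flip`` marks trials on which
    the high/low reward assignment swapped; ``high_state`` is the terminal
    state carrying the high payoff on this trial.
    """

    subject: str
    trial: int
    block: int
    start_state: int
    first_choice: Optional[int]
    second_state: int
    terminal_state: int
    reward: float
    contingency_id: int
    contingency_changed: bool
    reward_flip: bool
    high_state: int


def terminal_for(second_state: int, contingency: int) -> int:
    """Terminal state reached from a second-level state under a contingency."""
    if second_state not in (S1, S2):
        raise ValueError(f"not a second-level state: {second_state}")
    return S3 + ((second_state - S1) ^ contingency)


def schedule_contingency_changes(config: TaskConfig, rng: np.random.Generator) -> list:
    """Draw the 1-based trial indices at which the contingency flips.

    Successive gaps are uniform on the active block's inclusive range.  A
    flip that would land on a reward-assignment-flip trial (a multiple of
    ``reward_flip_period``) is re-drawn so the two events never coincide;
    if the range is degenerate and cannot avoid the collision, the gap is
    extended by one trial.
    """
    ranges = config.ordered_ranges
    flips: list = []
    t = 0
    while True:
        block = min(t // config.block_length, config.n_blocks - 1)
        lo, hi = ranges[block]
        gap = int(rng.integers(lo, hi + 1))
        if (t + gap) % config.reward_flip_period == 0:
            for _ in range(100):
                gap = int(rng.integers(lo, hi + 1))
                if (t + gap) % config.reward_flip_period != 0:
                    break
            else:
                gap += 1
        t += gap
        if t > config.n_trials:
            break
        flips.append(t)
    return flips


def step_reward_walk(state: TaskState, config: TaskConfig,
                     rng: np.random.Generator) -> TaskState:
    """Advance the high payoff by one Gaussian step, reflected at the bounds."""
    lo, hi = config.high_payoff_bounds
    x = state.payoff_high + rng.normal(0.0, config.walk_drift)
    # reflect until inside [lo, hi]
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        else:
            x = 2 * hi - x
    return replace(state, payoff_high=x)


def _initial_payoff(config: TaskConfig, rng: np.random.Generator) -> float:
    lo, hi = config.high_payoff_bounds
    while True:  # truncated-normal initial draw
        x = rng.normal(config.walk_mean, config.walk_sd)
        if lo <= x <= hi:
            return x


class Environment:
    """A single subject's episode of the contingency-change task.

    The environment pre-draws the contingency-flip schedule, then advances
    trial by trial.  Use :meth:`advance` with a policy callable (or a fixed
    action), or drive it manually with :meth:`begin_trial` /
    :meth:`finish_trial` when the caller needs to interleave its own logic.
    """

    def __init__(self, config: TaskConfig,
                 rng: Optional[np.random.Generator] = None,
                 subject: str = "sim"):
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.subject = subject
        self.flip_trials = frozenset(schedule_contingency_changes(config, self.rng))
        self.state = TaskState(
            trial_index=0,
            contingency=int(self.rng.integers(2)),
            high_reward_state=S3 if self.rng.random() < 0.5 else S4,
            payoff_high=_initial_payoff(config, self.rng),
        )
        self._pending = None  # (trial, changed, reward_flip, start_state)

    def begin_trial(self):
        """Apply trial-onset events and sample the start state.

        Returns ``(start_state, needs_choice)``.  The contingency flip and
        reward-assignment swap are applied at trial onset, so the flip trial
        itself already exhibits the new mapping.
        """
        if self._pending is not None:
            raise RuntimeError("finish_trial not called for previous trial")
        cfg = self.config
        t = self.state.trial_index + 1
        if t > cfg.n_trials:
            raise RuntimeError("episode finished")
        changed = t in self.flip_trials
        if changed:
            self.state.contingency ^= 1
        reward_flip = t % cfg.reward_flip_period == 0
        if reward_flip:
            self.state.high_reward_state = S3 + S4 - self.state.high_reward_state
        if t > 1:
            self.state = step_reward_walk(self.state, cfg, self.rng)
        start = int(self.rng.choice([S0, S1, S2], p=cfg.start_probs))
        self._pending = (t, changed, reward_flip, start)
        return start, start == S0

    def finish_trial(self, first_choice: Optional[int]) -> TrialRecord:
        """Resolve the transition and reward for the pending trial."""
        if self._pending is None:
            raise RuntimeError("begin_trial must be called first")
        t, changed, reward_flip, start = self._pending
        self._pending = None
        if start == S0:
            if first_choice not in (A1, A2):
                raise ValueError("a first-level trial requires a choice (A1 or A2)")
            second = S1 if first_choice == A1 else S2
        else:
            if first_choice is not None:
                raise ValueError("no choice is possible on a second-level-start trial")
            second = start
        terminal = terminal_for(second, self.state.contingency)
        reward = (self.state.payoff_high if terminal == self.state.high_reward_state
                  else self.state.payoff_low)
        self.state.trial_index = t
        return TrialRecord(
            subject=self.subject,
            trial=t,
            block=self.config.block_of(t),
            start_state=start,
            first_choice=first_choice,
            second_state=second,
            terminal_state=terminal,
            reward=reward,
            contingency_id=self.state.contingency,
            contingency_changed=changed,
            reward_flip=reward_flip,
            high_state=self.state.high_reward_state,
        )

    def advance(self, first_choice) -> TrialRecord:
        """Run one full trial.

        ``first_choice`` is an action (A1/A2), ``None``, or a callable
        ``policy(start_state) -> action-or-None`` invoked after the start
        state is sampled.
        """
        start, needs_choice = self.begin_trial()
        if callable(first_choice):
            choice = first_choice(start) if needs_choice else None
        else:
            choice = first_choice
        return self.finish_trial(choice)

    @property
    def done(self) -> bool:
        return self.state.trial_index >= self.config.n_trials


def advance_trial(env: Environment, first_choice) -> TrialRecord:
    """Functional alias for :meth:`Environment.advance`."""
    return env.advance(first_choice)


def run_episode(config: TaskConfig, policy: Callable[[int], Optional[int]],
                rng: Optional[np.random.Generator] = None,
                subject: str = "sim") -> list:
    """Run a full episode under ``policy`` and return its TrialRecords."""
    env = Environment(config, rng=rng, subject=subject)
    records = []
    while not env.done:
        records.append(env.advance(policy))
    return records
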