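"""Reinforcement-learning agents for the contingency-change task.

Two value-learning systems are implemented:

* A model-free (MF) temporal-difference learner that caches action values
  through reward prediction errors, with an eligibility trace ``lam``
  controlling how directly terminal rewards credit first-level actions
  (``lam = 0``: first-level values are updated only through second-level
  values; ``lam = 1``: the terminal reward updates the first-level action
  directly within the trial).
* A model-based (MB) planner that learns the second-level-to-terminal
  transition contingency and a subjective reward per terminal state, and
  computes first-level action values by expectation over the learned model.

Because the two terminal payoffs always sum to 1, both systems apply a
*fictive* (mirror) update: whenever a visited entry is updated, the paired
unvisited entry is set to one minus the new value.

A hybrid agent mixes the two systems' first-level action values with a
weight ``w`` (``w = 1`` fully model-based) and selects actions by a softmax
with inverse temperature ``beta``, after transiently adding a perseveration
(stay) bias to the previously chosen action's value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .task import A1, A2, S0, S1, S2, S3, TaskConfig, TrialRecord

__all__ = [
    "AgentParams", "MFSystem", "MBSystem", "HybridAgent",
    "mirror_update", "action_probabilities", "weight_index_by_block",
]


@dataclass
class AgentParams:
    """Free parameters of the hybrid agent.

    ``w_mb`` may be a scalar (one constant weight) or a 3-vector indexed per
    session block or per contingency-change frequency class, depending on the
    model variant.  ``alpha_mb_transition`` is the learning rate of the MB
    transition update; the default 1 makes transition knowledge jump to the
    last observed contingency.
    """

    w_mb: Union[float, Sequence[float]] = 0.5
    alpha_mf: float = 0.5
    alpha_mb: float = 0.5
    beta: float = 5.0
    lam: float = 0.5
    stay_bias: float = 0.2
    alpha_mb_transition: float = 1.0
    fictive: bool = True

    def __post_init__(self) -> None:
        w = np.atleast_1d(np.asarray(self.w_mb, dtype=float))
        if np.any((w < 0) | (w > 1)):
            raise ValueError("w_mb must lie in [0, 1]")
        for name in ("alpha_mf", "alpha_mb", "lam", "alpha_mb_transition"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    def w_vector(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.w_mb, dtype=float))


def mirror_update(values: np.ndarray, index: int) -> None:
    """Fictive update: set the paired entry to 1 minus the updated entry."""
    values[1 - index] = 1.0 - values[index]


def action_probabilities(q: np.ndarray, beta: float, stay_bias: float = 0.0,
                         prev_choice: Optional[int] = None) -> np.ndarray:
    """Softmax over two first-level action values with a transient stay bias.

    The bias is added to the previously chosen action's value at decision
    time only; it is never written back into stored values.
    """
    q = np.asarray(q, dtype=float).copy()
    if not np.all(np.isfinite(q)):
        raise ValueError("action values must be finite")
    if prev_choice is not None:
        q[prev_choice] += stay_bias
    z = beta * q
    z -= z.max()  # overflow-safe
    e = np.exp(z)
    return e / e.sum()


class MFSystem:
    """Model-free TD learner over first- and second-level values.

    State: ``q0`` holds Q(S0, A1/A2); ``q2`` holds the single-action values
    of S1 and S2.  All entries start at 0.5, the indifference point of the
    mirrored [0, 1] reward scale.
    """

    def __init__(self, alpha: float, lam: float, fictive: bool = True):
        self.alpha = alpha
        self.lam = lam
        self.fictive = fictive
        self.q0 = np.full(2, 0.5)
        self.q2 = np.full(2, 0.5)

    def observe(self, trial: TrialRecord) -> None:
        s2 = trial.second_state - S1
        delta2 = trial.reward - self.q2[s2]
        if trial.start_state == S0 and trial.first_choice is not None:
            # one-step error at the first level (no reward there), plus the
            # trace-discounted second-stage error
            delta1 = self.q2[s2] - self.q0[trial.first_choice]
            self.q0[trial.first_choice] += self.alpha * delta1 + self.alpha * self.lam * delta2
        self.q2[s2] += self.alpha * delta2
        if self.fictive:
            mirror_update(self.q2, s2)

    def q_first(self) -> np.ndarray:
        return self.q0.copy()


class MBSystem:
    """Model-based planner with transition and reward learning.

    ``p_consistent`` is the probability assigned to mapping A
    (``S1 -> S3``, ``S2 -> S4``); the complement equations tie the two
    transition rows together, so one scalar suffices.  Observing either
    transition updates knowledge of both.  ``r`` holds the subjective reward
    of S3 and S4.
    """

    def __init__(self, alpha: float, alpha_transition: float = 1.0,
                 fictive: bool = True):
        self.alpha = alpha
        self.alpha_transition = alpha_transition
        self.fictive = fictive
        self.p_consistent = 1.0
        self.r = np.full(2, 0.5)

    @property
    def transition_matrix(self) -> np.ndarray:
        """Rows: from S1, S2; columns: to S3, S4."""
        p = self.p_consistent
        return np.array([[p, 1.0 - p], [1.0 - p, p]])

    def observe(self, trial: TrialRecord) -> None:
        ter = trial.terminal_state - S3
        observed_a = 1.0 if ter == (trial.second_state - S1) else 0.0
        self.p_consistent += self.alpha_transition * (observed_a - self.p_consistent)
        self.r[ter] += self.alpha * (trial.reward - self.r[ter])
        if self.fictive:
            mirror_update(self.r, ter)

    def q_first(self) -> np.ndarray:
        p = self.p_consistent
        return np.array([
            p * self.r[0] + (1.0 - p) * self.r[1],        # A1 -> S1
            (1.0 - p) * self.r[0] + p * self.r[1],        # A2 -> S2
        ])


def weight_index_by_block(structure: str,
                          config: Optional[TaskConfig] = None) -> list:
    """Map each session block (1..n) to a weight-vector component.

    ``"single"``: one shared component; ``"by_block"``: one component per
    block; ``"by_frequency"``: one component per contingency-change
    frequency class (fast/medium/slow), looked up from the config's block
    order so counterbalanced orders map correctly.
    """
    n_blocks = config.n_blocks if config is not None else 3
    if structure == "single":
        return [0] * n_blocks
    if structure == "by_block":
        return list(range(n_blocks))
    if structure == "by_frequency":
        if config is None:
            raise ValueError("by_frequency indexing requires a TaskConfig")
        return list(config.frequency_by_block)
    raise ValueError(f"unknown weight structure {structure!r}")


class HybridAgent:
    """Weighted mixture of a high-level and a low-level value system.

    The standard agent mixes MB and MF systems:
    ``Q = w * Q_MB + (1 - w) * Q_MF``.  Control variants mix two MF or two
    MB systems with fixed learning rates and a free mixing weight; build
    them with :meth:`two_mf`, :meth:`two_mf_traced` or :meth:`two_mb`.
    """

    def __init__(self, params: AgentParams,
                 weight_structure: str = "single",
                 config: Optional[TaskConfig] = None,
                 system_hi=None, system_lo=None):
        self.params = params
        self.system_hi = system_hi if system_hi is not None else MBSystem(
            params.alpha_mb, params.alpha_mb_transition, params.fictive)
        self.system_lo = system_lo if system_lo is not None else MFSystem(
            params.alpha_mf, params.lam, params.fictive)
        self._w = params.w_vector()
        self._widx = weight_index_by_block(weight_structure, config)
        if max(self._widx) >= len(self._w):
            raise ValueError("w_mb vector shorter than weight structure requires")
        self.prev_first_choice: Optional[int] = None

    # -- control-hybrid factories ------------------------------------------
    @classmethod
    def two_mf(cls, mix_weight: float, beta: float, stay_bias: float,
               alpha_lo: float = 0.25, alpha_hi: float = 0.75,
               lam: float = 0.5, fictive: bool = True) -> "HybridAgent":
        p = AgentParams(w_mb=mix_weight, beta=beta, stay_bias=stay_bias,
                        lam=lam, fictive=fictive)
        return cls(p, system_hi=MFSystem(alpha_hi, lam, fictive),
                   system_lo=MFSystem(alpha_lo, lam, fictive))

    @classmethod
    def two_mf_traced(cls, mix_weight: float, beta: float, stay_bias: float,
                      fictive: bool = True) -> "HybridAgent":
        """MF(alpha=0.25, lam=0) mixed with MF(alpha=0.75, lam=1)."""
        p = AgentParams(w_mb=mix_weight, beta=beta, stay_bias=stay_bias,
                        fictive=fictive)
        return cls(p, system_hi=MFSystem(0.75, 1.0, fictive),
                   system_lo=MFSystem(0.25, 0.0, fictive))

    @classmethod
    def two_mb(cls, mix_weight: float, beta: float, stay_bias: float,
               alpha_lo: float = 0.25, alpha_hi: float = 0.75,
               fictive: bool = True) -> "HybridAgent":
        p = AgentParams(w_mb=mix_weight, beta=beta, stay_bias=stay_bias,
                        fictive=fictive)
        return cls(p, system_hi=MBSystem(alpha_hi, 1.0, fictive),
                   system_lo=MBSystem(alpha_lo, 1.0, fictive))

    # -- decision and learning ---------------------------------------------
    def weight(self, block: int) -> float:
        return float(self._w[self._widx[block - 1]])

    def q_values(self, block: int):
        """Return (hybrid, high-system, low-system) first-level values."""
        q_hi = self.system_hi.q_first()
        q_lo = self.system_lo.q_first()
        w = self.weight(block)
        return w * q_hi + (1.0 - w) * q_lo, q_hi, q_lo

    def choice_probabilities(self, block: int) -> np.ndarray:
        q, _, _ = self.q_values(block)
        return action_probabilities(q, self.params.beta, self.params.stay_bias,
                                    self.prev_first_choice)

    def act(self, block: int, rng: np.random.Generator) -> int:
        p = self.choice_probabilities(block)
        return A1 if rng.random() < p[A1] else A2

    def observe(self, trial: TrialRecord) -> None:
        self.system_hi.observe(trial)
        self.system_lo.observe(trial)
        if trial.start_state == S0 and trial.first_choice is not None:
            self.prev_first_choice = trial.first_choice
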