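"""Synthetic-data generation: agents playing the contingency-change task.

The generator reproduces the study conditions: cohorts of 16 subjects, 600
trials each, with the block structure, contingency-flip schedules and
drifting complementary rewards of the task module.  Reference parameter
values for simulations (used wherever a cohort needs a single documented
parameter set) are ``alpha_MF = alpha_MB = 0.5``, ``beta = 5``,
``lam = 0.5``, ``stay_bias = 0.2`` and a reference weight ``w = 0.56``, the
median model-based weight of the fitted hybrid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Union

import numpy as np

from .agents import AgentParams, HybridAgent
from .data import Dataset
from .task import S0, Environment, TaskConfig

__all__ = [
    "REFERENCE_PARAMS", "REFERENCE_W", "Cohort", "RecoverySetting",
    "simulate_subject", "simulate_cohort", "recovery_grid",
]

#: reference model-based weight (median fitted weight of the hybrid model)
REFERENCE_W = 0.56

#: reference values for parameters held constant in simulations
REFERENCE_PARAMS = AgentParams(w_mb=REFERENCE_W, alpha_mf=0.5, alpha_mb=0.5,
                               beta=5.0, lam=0.5, stay_bias=0.2)


@dataclass
class Cohort:
    """A simulated group of subjects with known generating parameters."""

    datasets: List[Dataset]
    true_params: List[AgentParams]
    config: TaskConfig
    model: str  # weight structure tag ("single", "by_block", "by_frequency")
    seed: int

    def __len__(self) -> int:
        return len(self.datasets)


@dataclass
class RecoverySetting:
    """One cell of the parameter-recovery grid."""

    varied_block: int       # 1-based block whose weight is varied
    true_w: float           # the varied block's generating weight
    cohort: Cohort


def simulate_subject(params: AgentParams, config: TaskConfig,
                     rng: np.random.Generator, subject: str = "sim",
                     weight_structure: str = "single",
                     agent_factory: Optional[Callable[[], HybridAgent]] = None,
                     ) -> Dataset:
    """Run one agent through one full episode of the task."""
    env = Environment(config, rng=rng, subject=subject)
    if agent_factory is not None:
        agent = agent_factory()
    else:
        agent = HybridAgent(params, weight_structure, config)
    trials = []
    while not env.done:
        start, needs_choice = env.begin_trial()
        block = config.block_of(len(trials) + 1)
        choice = agent.act(block, rng) if needs_choice else None
        rec = env.finish_trial(choice)
        agent.observe(rec)
        trials.append(rec)
    return Dataset(subject=subject, trials=trials, config=config)


def simulate_cohort(params: Union[AgentParams, Sequence[AgentParams]],
                    config: Optional[TaskConfig] = None,
                    n_subjects: int = 16, seed: int = 0,
                    weight_structure: str = "single",
                    agent_factory: Optional[Callable[[], HybridAgent]] = None,
                    ) -> Cohort:
    """Simulate a cohort of independent subjects.

    ``params`` is either a single parameter set shared by all subjects or a
    per-subject sequence.  Per-subject random streams are spawned
    deterministically from ``seed``, so a cohort is reproducible bit for bit.
    """
    if config is None:
        config = TaskConfig()
    if isinstance(params, AgentParams):
        params = [params] * n_subjects
    else:
        params = list(params)
        if len(params) != n_subjects:
            raise ValueError("need one AgentParams per subject")
    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    datasets = []
    for i, (p, ss) in enumerate(zip(params, streams)):
        rng = np.random.default_rng(ss)
        datasets.append(simulate_subject(
            p, config, rng, subject=f"sub{i + 1:02d}",
            weight_structure=weight_structure, agent_factory=agent_factory))
    return Cohort(datasets=datasets, true_params=params, config=config,
                  model=weight_structure, seed=seed)


def recovery_grid(seed: int = 0,
                  values: Optional[Sequence[float]] = None,
                  n_subjects: int = 16,
                  config: Optional[TaskConfig] = None,
                  reference: AgentParams = REFERENCE_PARAMS,
                  reference_w: float = REFERENCE_W) -> List[RecoverySetting]:
    """Build the parameter-recovery grid for the block-indexed hybrid.

    One block's weight at a time is set to each grid value (default 0, 0.1,
    ..., 1 — 11 values x 3 blocks = 33 settings) while the other two blocks
    are held at the reference weight; each setting is a full cohort
    (default 16 subjects) with the remaining parameters at the reference
    values.
    """
    if values is None:
        values = np.round(np.linspace(0.0, 1.0, 11), 10)
    if config is None:
        config = TaskConfig()
    settings = []
    root = np.random.SeedSequence(seed)
    sub_seeds = root.generate_state(3 * len(values)) % (2 ** 31)
    k = 0
    for block in (1, 2, 3):
        for v in values:
            w = [reference_w] * config.n_blocks
            w[block - 1] = float(v)
            p = replace(reference, w_mb=tuple(w))
            cohort = simulate_cohort(p, config, n_subjects,
                                     seed=int(sub_seeds[k]),
                                     weight_structure="by_block")
            settings.append(RecoverySetting(varied_block=block,
                                            true_w=float(v), cohort=cohort))
            k += 1
    return settings
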