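import dataclasses

import numpy as np
import pytest

from contingencyrl import (AgentParams, REFERENCE_PARAMS, TaskConfig,
                           simulate_cohort)


@pytest.fixture(scope="session")
def reference_params() -> AgentParams:
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def small_config() -> TaskConfig:
    """A three-block task at reduced length for fitting-heavy tests."""
    return TaskConfig(n_trials=150, block_length=50)


@pytest.fixture(scope="session")
def hybrid_cohort():
    """16 hybrid agents at the reference weight on the full task."""
    return simulate_cohort(REFERENCE_PARAMS, n_subjects=16, seed=11)


@pytest.fixture(scope="session")
def mb_cohort():
    params = dataclasses.replace(REFERENCE_PARAMS, w_mb=1.0)
    return simulate_cohort(params, n_subjects=16, seed=11)


@pytest.fixture(scope="session")
def mf_cohort():
    params = dataclasses.replace(REFERENCE_PARAMS, w_mb=0.0)
    return simulate_cohort(params, n_subjects=16, seed=11)
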