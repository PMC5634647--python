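"""Behavioral-analysis tests: stay probabilities, ANOVA, summaries."""

import dataclasses

import numpy as np
import pytest

from contingencyrl import (AgentParams, REFERENCE_PARAMS, TaskConfig,
                           condition_anova, performance_summaries,
                           simulate_cohort, stay_probabilities)
from contingencyrl.behavior import StayProbTable
from contingencyrl.data import Dataset
from contingencyrl.io import stay_fixture
from contingencyrl.task import (A1, A2, S0, S1, S2, Environment, run_episode,
                                terminal_for)


# ---------------------------------------------------------------------------
# enumeration oracle on the hand-built fixture

def enumerate_stay_table(dataset, variant):
    """Independent brute-force enumeration of the 2x2 stay table."""
    stays = np.zeros((2, 2))
    counts = np.zeros((2, 2))
    trials = dataset.trials
    for i in range(1, len(trials)):
        cur, prev = trials[i], trials[i - 1]
        eligible = (cur.start_state == S0 and cur.first_choice is not None
                    and prev.trial >= 2)
        if variant == "second-level-start":
            eligible = eligible and prev.start_state in (S1, S2)
        else:
            eligible = (eligible and prev.start_state == S0
                        and prev.first_choice is not None)
        if not eligible:
            continue
        ri = 0 if prev.terminal_state == prev.high_state else 1
        ci = 0 if prev.contingency_changed else 1
        counts[ri, ci] += 1
        if (S1 if cur.first_choice == A1 else S2) == prev.second_state:
            stays[ri, ci] += 1
    probs = np.where(counts > 0, stays / np.maximum(counts, 1), np.nan)
    return probs, counts


def test_fixture_matches_hand_enumeration_exactly():
    ds = stay_fixture()
    table = stay_probabilities(ds)
    # the fixture was built so each cell holds exactly one eligible trial:
    # high/fixed: trial 3 stays; high/changed: trial 5 stays;
    # low/fixed: trial 7 stays; low/changed: trial 9 switches
    assert np.array_equal(table.counts, np.ones((2, 2), dtype=int))
    expected = np.array([[1.0, 1.0], [0.0, 1.0]])
    assert np.array_equal(table.probs, expected)
    probs, counts = enumerate_stay_table(ds, "second-level-start")
    assert np.array_equal(table.probs, probs)
    assert np.array_equal(table.counts, counts.astype(int))


def test_simulated_table_matches_enumeration(hybrid_cohort):
    for ds in hybrid_cohort.datasets[:4]:
        for variant in ("second-level-start", "first-level-start"):
            t = stay_probabilities(ds, variant)
            probs, counts = enumerate_stay_table(ds, variant)
            assert np.array_equal(t.counts, counts.astype(int))
            assert np.allclose(t.probs, probs, equal_nan=True)


def test_perseverating_agent_always_stays():
    cfg = TaskConfig()
    records = run_episode(cfg, lambda s: A1, rng=np.random.default_rng(3))
    ds = Dataset("persev", records, cfg)
    t = stay_probabilities(ds, variant="first-level-start")
    defined = t.counts > 0
    assert defined.any()
    assert np.all(t.probs[defined] == 1.0)


def test_pure_planner_with_greedy_choices_tracks_reward(mb_cohort):
    """A nearly-greedy model-based agent stays after high reward and
    switches after low reward, in both contingency conditions."""
    params = dataclasses.replace(REFERENCE_PARAMS, w_mb=1.0, beta=20.0,
                                 stay_bias=0.0)
    cohort = simulate_cohort(params, n_subjects=8, seed=5)
    P = np.nanmean([stay_probabilities(d).probs for d in cohort.datasets],
                   axis=0)
    assert np.all(P[0, :] > 0.9)   # high-reward cells
    assert np.all(P[1, :] < 0.1)   # low-reward cells


def test_empty_cells_are_nan_with_zero_count():
    ds = stay_fixture()
    short = Dataset("s", ds.trials[:3], ds.config)
    t = stay_probabilities(short)
    assert t.counts[1, 0] == 0 and np.isnan(t.probs[1, 0])


# ---------------------------------------------------------------------------
# condition ANOVA

def anova_oracle(cell_matrix):
    """Textbook balanced two-way ANOVA with replication.

    ``cell_matrix``: (n_subjects, 2, 2) of cell means; factors reward (rows)
    and contingency (columns), subjects as replicates."""
    y = np.asarray(cell_matrix, dtype=float)
    n = y.shape[0]
    grand = y.mean()
    a_means = y.mean(axis=(0, 2))   # reward levels
    b_means = y.mean(axis=(0, 1))   # contingency levels
    ab_means = y.mean(axis=0)
    ss_a = 2 * n * np.sum((a_means - grand) ** 2)
    ss_b = 2 * n * np.sum((b_means - grand) ** 2)
    ss_ab = n * np.sum((ab_means - a_means[:, None] - b_means[None, :]
                        + grand) ** 2)
    ss_e = np.sum((y - ab_means[None]) ** 2)
    df_e = 4 * n - 4
    return {"reward": (ss_a / 1) / (ss_e / df_e),
            "contingency": (ss_b / 1) / (ss_e / df_e),
            "reward:contingency": (ss_ab / 1) / (ss_e / df_e)}


def make_tables(cells):
    return [StayProbTable(subject=f"s{i}", variant="second-level-start",
                          probs=np.asarray(c, dtype=float),
                          counts=np.full((2, 2), 5))
            for i, c in enumerate(cells)]


def test_anova_matches_sum_of_squares_oracle():
    rng = np.random.default_rng(8)
    cells = rng.uniform(0.2, 0.8, size=(12, 2, 2))
    table = condition_anova(make_tables(cells))
    expect = anova_oracle(cells)
    for term, f in expect.items():
        assert table.loc[term, "F"] == pytest.approx(f, rel=1e-8)
    assert table.loc["residual", "df"] == 4 * 12 - 4


def test_identical_cells_give_zero_f():
    cells = [np.full((2, 2), 0.6) + np.eye(2) * 0.0 for _ in range(6)]
    # add subject-level noise that is constant across conditions
    cells = [c + 0.01 * i for i, c in enumerate(cells)]
    table = condition_anova(make_tables(cells))
    for term in ("reward", "contingency", "reward:contingency"):
        assert table.loc[term, "F"] == pytest.approx(0.0, abs=1e-12)


def test_subjects_with_empty_cells_are_excluded():
    tables = make_tables(np.random.default_rng(0).uniform(size=(4, 2, 2)))
    bad = StayProbTable(subject="bad", variant="second-level-start",
                        probs=np.array([[np.nan, 0.5], [0.5, 0.5]]),
                        counts=np.array([[0, 5], [5, 5]]))
    with pytest.warns(UserWarning, match="excluded 1 subject"):
        condition_anova(tables + [bad])


# ---------------------------------------------------------------------------
# performance summaries

def test_omniscient_policy_reaches_ceiling():
    cfg = TaskConfig()
    env = Environment(cfg, rng=np.random.default_rng(4), subject="oracle")
    records = []
    while not env.done:
        start, needs_choice = env.begin_trial()
        choice = None
        if needs_choice:
            # read the environment's current mapping and high state
            want = env.state.high_reward_state
            choice = A1 if terminal_for(S1, env.state.contingency) == want else A2
        records.append(env.finish_trial(choice))
    ds = Dataset("oracle", records, cfg)
    perf = performance_summaries(ds)
    assert np.all(perf["high_choice_prob"] == 1.0)
    assert np.all(perf["reward_rate"] > 0.5)


def test_uniform_random_policy_is_at_chance():
    cfg = TaskConfig()
    rng = np.random.default_rng(6)
    all_perf = []
    for seed in range(8):
        records = run_episode(cfg, lambda s: int(rng.integers(2)),
                              rng=np.random.default_rng(60 + seed))
        all_perf.append(performance_summaries(Dataset("r", records, cfg)))
    mean_p = np.mean([p["high_choice_prob"].mean() for p in all_perf])
    assert abs(mean_p - 0.5) < 0.05


def test_repeated_measures_variant_runs():
    rng = np.random.default_rng(9)
    cells = rng.uniform(0.2, 0.8, size=(8, 2, 2))
    table = condition_anova(make_tables(cells), repeated_measures=True)
    assert {"reward", "contingency"} <= {i.split(":")[0] for i in table.index}
    assert np.all(table["F Value"] >= 0)
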