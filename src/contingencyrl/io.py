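"""Readers and writers for trial logs, configurations and cohorts.

Trial logs are UTF-8 comma-separated files with a header row and one row per
trial; a missing first-level choice (second-level-start or missed trial) is
an empty field.  Cohorts are written as one CSV per subject plus a YAML
manifest holding the task configuration, the generating parameters (for
simulated cohorts) and the seeds needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .agents import AgentParams
from .data import COLUMNS, Dataset, frame_to_records, records_to_frame
from .simulate import Cohort
from .task import S0, S1, S2, A1, TaskConfig, TrialRecord, terminal_for

__all__ = ["read_trials", "write_trials", "read_config", "write_config",
           "write_cohort", "read_cohort", "make_fixtures", "ValidationError"]


class ValidationError(ValueError):
    """A trial log violated the schema or the task's transition structure."""


def write_trials(path: Union[str, Path], dataset: Dataset) -> None:
    records_to_frame(dataset.trials).to_csv(path, index=False,
                                            float_format="%.17g")


def read_trials(path: Union[str, Path],
                config: Optional[TaskConfig] = None) -> Dataset:
    """Load and validate a trial log.

    Raises :class:`ValidationError` listing offending row numbers when the
    schema is violated or a row's state path is inconsistent (choice vs
    second-level state, or terminal state vs contingency)."""
    df = pd.read_csv(path, dtype={"first_choice": "string"},
                     keep_default_na=True, float_precision="round_trip")
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {missing_cols}")
    try:
        records = frame_to_records(df)
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"{path}: malformed value ({exc})") from exc
    bad: List[str] = []
    prev: Optional[TrialRecord] = None
    for i, r in enumerate(records, start=2):  # header is line 1
        if r.start_state == S0 and r.first_choice is not None:
            expect = S1 if r.first_choice == A1 else S2
            if r.second_state != expect:
                bad.append(f"line {i}: first_choice inconsistent with second_state")
        elif r.start_state in (S1, S2):
            if r.first_choice is not None:
                bad.append(f"line {i}: choice recorded on a second-level-start trial")
            if r.second_state != r.start_state:
                bad.append(f"line {i}: second_state differs from start_state")
        if terminal_for(r.second_state, r.contingency_id) != r.terminal_state:
            bad.append(f"line {i}: terminal_state inconsistent with contingency")
        if prev is not None and r.contingency_changed != (
                r.contingency_id != prev.contingency_id):
            bad.append(f"line {i}: contingency_changed flag inconsistent")
        prev = r
    if bad:
        raise ValidationError(f"{path}: " + "; ".join(bad))
    subject = records[0].subject if records else Path(path).stem
    return Dataset(subject=subject, trials=records,
                   config=config if config is not None else TaskConfig())


# ---------------------------------------------------------------------------
# configuration files

def write_config(path: Union[str, Path], config: TaskConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_dict(config), fh, sort_keys=False)


def read_config(path: Union[str, Path]) -> TaskConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _config_from_dict(raw)


def _config_dict(config: TaskConfig) -> dict:
    d = dataclasses.asdict(config)
    d["block_change_ranges"] = [list(r) for r in d["block_change_ranges"]]
    for key in ("start_probs", "reward_bounds", "high_payoff_bounds"):
        d[key] = list(d[key])
    return d


def _config_from_dict(raw: dict) -> TaskConfig:
    kw = dict(raw)
    for key in ("block_change_ranges",):
        if key in kw:
            kw[key] = tuple(tuple(r) for r in kw[key])
    for key in ("start_probs", "reward_bounds", "high_payoff_bounds"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return TaskConfig(**kw)


# ---------------------------------------------------------------------------
# cohorts

def write_cohort(out_dir: Union[str, Path], cohort: Cohort) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "model": cohort.model,
        "seed": cohort.seed,
        "config": _config_dict(cohort.config),
        "subjects": [],
    }
    for ds, params in zip(cohort.datasets, cohort.true_params):
        fname = f"{ds.subject}.csv"
        write_trials(out / fname, ds)
        p = dataclasses.asdict(params)
        if isinstance(p["w_mb"], tuple):
            p["w_mb"] = list(p["w_mb"])
        manifest["subjects"].append({"subject": ds.subject, "file": fname,
                                     "true_params": p})
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_cohort(out_dir: Union[str, Path]) -> Cohort:
    out = Path(out_dir)
    with open(out / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    config = _config_from_dict(manifest["config"])
    datasets, params = [], []
    for entry in manifest["subjects"]:
        datasets.append(read_trials(out / entry["file"], config=config))
        p = dict(entry["true_params"])
        if isinstance(p["w_mb"], list):
            p["w_mb"] = tuple(p["w_mb"])
        params.append(AgentParams(**p))
    return Cohort(datasets=datasets, true_params=params, config=config,
                  model=manifest["model"], seed=manifest["seed"])


# ---------------------------------------------------------------------------
# fixtures

def make_fixtures(out_dir: Union[str, Path], seed: int = 7) -> dict:
    """Write the small, regenerable test fixtures.

    Contents: the hand-enumerable 6-trial stay-probability log, a 10-trial
    likelihood-trace log with the replay-computed negative log-likelihood,
    and one small simulated cohort per main candidate model.  Identical
    seeds regenerate identical files.
    """
    from .fitting import model, replay_nll
    from .simulate import REFERENCE_PARAMS, simulate_cohort

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    stay = stay_fixture()
    write_trials(out / "stay_fixture.csv", stay)
    paths["stay_fixture"] = out / "stay_fixture.csv"

    trace = trace_fixture(seed)
    write_trials(out / "trace_fixture.csv", trace)
    spec = model("hybrid_1w")
    nll = replay_nll(trace, spec, REFERENCE_PARAMS)
    with open(out / "trace_fixture_nll.yaml", "w") as fh:
        yaml.safe_dump({"model": "hybrid_1w",
                        "params": {"w_mb": REFERENCE_PARAMS.w_mb,
                                   "alpha_mf": REFERENCE_PARAMS.alpha_mf,
                                   "alpha_mb": REFERENCE_PARAMS.alpha_mb,
                                   "beta": REFERENCE_PARAMS.beta,
                                   "lam": REFERENCE_PARAMS.lam,
                                   "stay_bias": REFERENCE_PARAMS.stay_bias},
                        "neg_loglik": float(nll)}, fh)
    paths["trace_fixture"] = out / "trace_fixture.csv"
    paths["trace_fixture_nll"] = out / "trace_fixture_nll.yaml"

    cfg = TaskConfig(n_trials=60, block_length=20)
    cohort_specs = (
        ("pure_mf", 0.0, "single"),
        ("pure_mb", 1.0, "single"),
        ("hybrid_1w", 0.56, "single"),
        ("hybrid_3block", (0.3, 0.56, 0.8), "by_block"),
        ("hybrid_3freq", (0.3, 0.56, 0.8), "by_frequency"),
    )
    for name, w, structure in cohort_specs:
        params = dataclasses.replace(REFERENCE_PARAMS, w_mb=w)
        cohort = simulate_cohort(params, cfg, n_subjects=2, seed=seed,
                                 weight_structure=structure)
        d = out / f"cohort_{name}"
        write_cohort(d, cohort)
        paths[f"cohort_{name}"] = d
    return paths


def stay_fixture() -> Dataset:
    """Nine hand-built trials exercising all four stay-probability cells.

    First-level choice trials alternate with second-level starts around two
    contingency changes (trials 4 and 8), so the eligible analysis trials
    and their 2x2 cell assignments can be enumerated by hand; the unit
    tests carry the enumeration."""
    rows = [
        # trial, start, choice, second, terminal, reward, cid, changed
        (1, 0, 0, 1, 3, 0.90, 0, False),
        (2, 1, None, 1, 3, 0.90, 0, False),
        (3, 0, 0, 1, 3, 0.80, 0, False),   # prev high/fixed, stay
        (4, 2, None, 2, 3, 0.70, 1, True),
        (5, 0, 1, 2, 3, 0.80, 1, False),   # prev high/changed, stay
        (6, 1, None, 1, 4, 0.30, 1, False),
        (7, 0, 0, 1, 4, 0.25, 1, False),   # prev low/fixed, stay
        (8, 2, None, 2, 4, 0.30, 0, True),
        (9, 0, 0, 1, 3, 0.80, 0, False),   # prev low/changed, switch
    ]
    trials = [TrialRecord(subject="fix", trial=t, block=1, start_state=s,
                          first_choice=c, second_state=s2, terminal_state=ter,
                          reward=r, contingency_id=cid, contingency_changed=ch,
                          reward_flip=False, high_state=3)
              for t, s, c, s2, ter, r, cid, ch in rows]
    cfg = TaskConfig(n_trials=9, block_length=9, block_change_ranges=((3, 6),))
    return Dataset(subject="fix", trials=trials, config=cfg)


def trace_fixture(seed: int = 7) -> Dataset:
    """A 10-trial simulated log for step-by-step likelihood tracing."""
    from .simulate import REFERENCE_PARAMS, simulate_subject
    cfg = TaskConfig(n_trials=10, block_length=10, block_change_ranges=((3, 6),))
    rng = np.random.default_rng(seed)
    return simulate_subject(REFERENCE_PARAMS, cfg, rng, subject="trace")
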