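"""Fitting tests: transforms, likelihood, EM machinery, model comparison."""

import dataclasses
import math
import zlib
from types import SimpleNamespace

import numpy as np
import pytest
from scipy import integrate, special

from contingencyrl import (AgentParams, REFERENCE_PARAMS, TaskConfig,
                           simulate_cohort, subject_nll)
from contingencyrl.data import Dataset
from contingencyrl.fitting import (CANDIDATE_MODELS, GroupPrior,
                                   HierarchicalModel, HierarchicalResults,
                                   compare_models, exceedance_probabilities,
                                   model, replay_nll, to_natural,
                                   to_unconstrained)
from contingencyrl.task import S0, TrialRecord


# ---------------------------------------------------------------------------
# transforms

def test_transform_midpoints():
    assert to_natural(0.0, "logit") == pytest.approx(0.5)
    assert to_natural(0.0, "exp") == pytest.approx(1.0)
    assert to_natural(1.3, "id") == pytest.approx(1.3)


def test_transform_round_trip_to_machine_precision():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 3, size=1000)
    for kind in ("logit", "exp", "id"):
        back = to_unconstrained(to_natural(x, kind), kind)
        assert np.max(np.abs(back - x)) < 1e-12


def test_untransform_rejects_boundary_values():
    for v in (0.0, 1.0):
        with pytest.raises(ValueError):
            to_unconstrained(v, "logit")
    with pytest.raises(ValueError):
        to_unconstrained(0.0, "exp")


# ---------------------------------------------------------------------------
# model specifications

def test_parameter_layout_per_model():
    assert model("pure_mf").param_names == ["alpha_mf", "beta", "lam",
                                            "stay_bias"]
    assert model("pure_mb").param_names == ["alpha_mb", "beta", "stay_bias"]
    assert model("hybrid_1w").param_names == ["w1", "alpha_mf", "alpha_mb",
                                              "beta", "lam", "stay_bias"]
    assert model("hybrid_3block").n_params == 8
    assert model("hybrid_3freq").n_params == 8
    assert model("hybrid_3block_no_stay").n_params == 7
    assert model("hybrid_3block_single_alpha").n_params == 7
    assert model("hybrid_3block_free_transition").n_params == 9
    assert model("mf_mf").param_names == ["w1", "beta", "lam", "stay_bias"]
    assert model("mb_mb").param_names == ["w1", "beta", "stay_bias"]


# ---------------------------------------------------------------------------
# likelihood

def make_trial(t, start, choice, second, terminal, reward, cid=0):
    return TrialRecord(subject="h", trial=t, block=1, start_state=start,
                       first_choice=choice, second_state=second,
                       terminal_state=terminal, reward=reward,
                       contingency_id=cid, contingency_changed=False,
                       reward_flip=False, high_state=3)


def two_trial_dataset():
    cfg = TaskConfig(n_trials=2, block_length=2, block_change_ranges=((3, 6),))
    trials = [make_trial(1, 0, 0, 1, 3, 1.0),
              make_trial(2, 0, 1, 2, 4, 0.0)]
    return Dataset("h", trials, cfg)


def test_flat_policy_nll_is_n_log_two(hybrid_cohort):
    ds = hybrid_cohort.datasets[0]
    params = dataclasses.replace(REFERENCE_PARAMS, beta=0.0, stay_bias=0.0)
    nll = subject_nll(ds, model("hybrid_1w"), params)
    assert nll == pytest.approx(ds.n_choice_trials * math.log(2), abs=1e-9)


def test_two_trial_likelihood_matches_hand_computation():
    """Hand derivation: trial 1 from symmetric initial values gives p = 1/2.

    After trial 1 (A1 -> S1 -> S3, r = 1; alpha = 0.5, lam = 1, fictive):
    MF second level 0.5 -> 0.75 (mirror 0.25), first level
    0.5 + 0.5*0 + 0.5*1*0.5 = 0.75; MB rewards (0.75, 0.25), transitions at
    mapping A.  Trial 2 hybrid values (w = 0.5): (0.75, 0.375); stay bias
    0.2 on A1 makes the logits 2*(0.95, 0.375), so choosing A2 costs
    log(1 + e^1.15)."""
    params = AgentParams(w_mb=0.5, alpha_mf=0.5, alpha_mb=0.5, beta=2.0,
                         lam=1.0, stay_bias=0.2)
    expected = math.log(2.0) + math.log(1.0 + math.exp(1.15))
    ds = two_trial_dataset()
    assert subject_nll(ds, model("hybrid_1w"), params) == pytest.approx(
        expected, abs=1e-12)
    assert replay_nll(ds, model("hybrid_1w"), params) == pytest.approx(
        expected, abs=1e-12)


@pytest.mark.parametrize("name", sorted(CANDIDATE_MODELS))
def test_compiled_likelihood_equals_agent_replay(name, hybrid_cohort):
    """The JIT likelihood and the reference agents must agree exactly for
    every candidate model, including ablations and control mixtures."""
    spec = CANDIDATE_MODELS[name]
    rng = np.random.default_rng(zlib.crc32(name.encode()))
    ds = hybrid_cohort.datasets[1]
    for _ in range(3):
        x = rng.normal(0, 1, size=spec.n_params)
        nat = spec.natural(x)
        assert subject_nll(ds, spec, nat) == pytest.approx(
            replay_nll(ds, spec, nat), abs=1e-9)


def test_likelihood_updates_continue_through_missed_trials(hybrid_cohort):
    ds = hybrid_cohort.datasets[2]
    # blanking a choice removes exactly that trial's likelihood term while
    # its observed outcome still drives learning
    trials = list(ds.trials)
    idx = next(i for i, t in enumerate(trials)
               if t.start_state == S0 and t.first_choice is not None)
    trials[idx] = dataclasses.replace(trials[idx], first_choice=None)
    missed = Dataset(ds.subject, trials, ds.config)
    spec = model("hybrid_1w")
    nat = spec.natural(np.zeros(spec.n_params))
    assert subject_nll(missed, spec, nat) == pytest.approx(
        replay_nll(missed, spec, nat), abs=1e-9)


# ---------------------------------------------------------------------------
# EM machinery on analytically tractable toys

class QuadraticToy(HierarchicalModel):
    """Gaussian observation per subject: the EM fixed point is available in
    closed form (conjugate Gaussian-Gaussian model)."""

    def __init__(self, ys, obs_var):
        self.ys = np.asarray(ys, dtype=float)
        self.obs_var = float(obs_var)
        self.spec = SimpleNamespace(n_params=1, param_names=["theta"],
                                    transforms=["id"])
        self.datasets = [SimpleNamespace(subject=f"s{i}")
                         for i in range(len(self.ys))]
        self.n_subjects = len(self.ys)
        self.n_choice_trials = len(self.ys)

    def _nll(self, i, x):
        return 0.5 * (x[0] - self.ys[i]) ** 2 / self.obs_var


def conjugate_fixed_point(ys, obs_var, init_s2=4.0):
    mu, s2 = 0.0, init_s2
    for _ in range(500):
        post_var = 1.0 / (1.0 / obs_var + 1.0 / s2)
        m = (ys / obs_var + mu / s2) * post_var
        mu = m.mean()
        s2 = max(np.mean((m - mu) ** 2 + post_var), 1e-6)
    return mu, s2


def test_em_fixed_point_matches_conjugate_gaussian_solution():
    ys = np.array([-1.2, 0.4, 0.9, 2.0, -0.3, 1.1])
    toy = QuadraticToy(ys, obs_var=0.5)
    fit = toy.fit(seed=0, n_restarts=3, max_iter=300, tol=1e-7)
    mu, s2 = conjugate_fixed_point(ys, 0.5)
    assert fit.prior.mu[0] == pytest.approx(mu, abs=1e-3)
    assert fit.prior.sigma2[0] == pytest.approx(s2, rel=0.02)
    # posterior means, not raw observations: MAPs are shrunk toward mu
    assert np.all(np.abs(fit.maps[:, 0] - mu) < np.abs(ys - mu) + 1e-9)


def test_identical_subjects_get_identical_maps(small_config):
    ds = simulate_cohort(REFERENCE_PARAMS, small_config, n_subjects=1,
                         seed=3).datasets[0]
    twin = Dataset("twin", ds.trials, ds.config)
    fit = HierarchicalModel([ds, twin], model("hybrid_1w")).fit(
        seed=0, n_restarts=2, max_iter=4)
    assert np.allclose(fit.maps[0], fit.maps[1], atol=1e-6)


def test_group_mean_recovers_generating_weight():
    cohort = simulate_cohort(REFERENCE_PARAMS, n_subjects=8, seed=13,
                             weight_structure="single")
    fit = HierarchicalModel(cohort.datasets, model("hybrid_1w")).fit(
        seed=0, n_restarts=3, max_iter=12)
    w = np.median(special.expit(fit.maps[:, 0]))
    assert abs(w - 0.56) < 0.15


def test_summary_reports_model_and_parameters(small_config):
    cohort = simulate_cohort(REFERENCE_PARAMS, small_config, n_subjects=2,
                             seed=4)
    fit = HierarchicalModel(cohort.datasets, model("hybrid_1w")).fit(
        seed=0, n_restarts=2, max_iter=2)
    text = fit.summary()
    assert "hybrid_1w" in text and "w1" in text and "beta" in text
    frame = fit.params_frame()
    assert set(frame.columns) == set(model("hybrid_1w").param_names)
    assert ((frame[["w1", "alpha_mf", "alpha_mb", "lam"]] >= 0).all().all()
            and (frame["beta"] >= 0).all())


# ---------------------------------------------------------------------------
# integrated evidence

class BernoulliToy(HierarchicalModel):
    """One logistic-transformed success probability per subject."""

    def __init__(self, ks, n):
        self.ks = list(ks)
        self.n = n
        self.spec = SimpleNamespace(n_params=1)
        self.datasets = [SimpleNamespace(subject=f"s{i}")
                         for i in range(len(self.ks))]
        self.n_subjects = len(self.ks)
        self.n_choice_trials = n * len(self.ks)

    def _nll(self, i, x):
        th = special.expit(x[0])
        return -(self.ks[i] * np.log(th) + (self.n - self.ks[i]) * np.log(1 - th))


def toy_results(toy, mu=0.0, s2=1.0):
    k = toy.spec.n_params
    return HierarchicalResults(
        model=toy, spec=toy.spec, prior=GroupPrior(np.full(k, mu), np.full(k, s2)),
        maps=np.zeros((toy.n_subjects, k)), laplace_var=np.ones((toy.n_subjects, k)),
        subject_nll_at_map=np.zeros(toy.n_subjects), n_iter=1, converged=True,
        trace=[], options={"mc_samples": 2000})


def test_monte_carlo_evidence_within_3_se_of_quadrature():
    toy = BernoulliToy(ks=[3, 1], n=5)
    res = toy_results(toy)
    log_ev, se = res.log_evidence(n_samples=4000, seed=1)
    for i in range(toy.n_subjects):
        quad, _ = integrate.quad(
            lambda x: np.exp(-toy._nll(i, np.array([x])))
            * np.exp(-0.5 * x ** 2) / np.sqrt(2 * np.pi), -10, 10)
        assert abs(log_ev[i] - np.log(quad)) < 3 * se[i]


def test_ibic_penalty_scales_with_hyperparameter_count():
    toy = BernoulliToy(ks=[3, 1], n=5)
    res = toy_results(toy)
    ib = res.ibic(n_samples=2000, seed=2)
    assert ib.n_hyperparams == 2
    assert ib.value == pytest.approx(
        -2 * ib.log_evidence.sum() + 2 * math.log(10))


# ---------------------------------------------------------------------------
# exceedance probabilities

def dirichlet_argmax_quadrature(alpha):
    """P(r_k is the largest) under Dirichlet(alpha), 3 components, by 2-D
    quadrature over the simplex."""
    a = np.asarray(alpha, dtype=float)
    lognorm = special.gammaln(a).sum() - special.gammaln(a.sum())

    def prob_first(a1, a2, a3):
        def pdf(r2, r1):
            r3 = 1.0 - r1 - r2
            if r3 <= 0:
                return 0.0
            return np.exp((a1 - 1) * np.log(r1) + (a2 - 1) * np.log(r2)
                          + (a3 - 1) * np.log(r3) - lognorm)

        val, _ = integrate.dblquad(
            pdf, 1 / 3, 1.0,
            lambda r1: max(0.0, 1.0 - 2 * r1),
            lambda r1: min(r1, 1.0 - r1), epsabs=1e-10)
        return val

    return np.array([prob_first(a[0], a[1], a[2]),
                     prob_first(a[1], a[0], a[2]),
                     prob_first(a[2], a[0], a[1])])


def test_exceedance_symmetry_and_dominance():
    rng = np.random.default_rng(3)
    same = np.tile(rng.normal(0, 1, size=(6, 1)), (1, 2))
    xp = exceedance_probabilities(same, seed=0)["exceedance"]
    assert xp == pytest.approx([0.5, 0.5], abs=0.01)
    dominant = np.zeros((20, 2))
    dominant[:, 0] = 10.0
    xp = exceedance_probabilities(dominant, seed=1)["exceedance"]
    assert xp[0] > 0.99
    with pytest.raises(ValueError):
        exceedance_probabilities(np.zeros((4, 1)))


def test_exceedance_matches_dirichlet_quadrature_oracle():
    rng = np.random.default_rng(4)
    L = rng.normal(0, 1.2, size=(6, 3))
    out = exceedance_probabilities(L, n_samples=400_000, seed=5)
    oracle = dirichlet_argmax_quadrature(out["alpha"])
    assert np.abs(out["exceedance"] - oracle).max() < 0.02
    assert out["exceedance"].sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# model identification at study scale

def test_generating_system_is_identified_under_ibic():
    """Data from a pure cached-value learner must not be won by the pure
    planner, and vice versa."""
    for gen_w, winner in ((0.0, "pure_mf"), (1.0, "pure_mb")):
        params = dataclasses.replace(REFERENCE_PARAMS, w_mb=gen_w)
        cohort = simulate_cohort(params, n_subjects=8, seed=21)
        tab = compare_models(cohort.datasets, ["pure_mf", "pure_mb"], seed=0,
                             fit_kwargs={"n_restarts": 3, "max_iter": 12},
                             n_mc_samples=500)
        best = tab.loc[tab["iBIC"].idxmin(), "model"]
        assert best == winner
        assert tab.set_index("model").loc[winner, "exceedance_prob"] > 0.5


def test_frequency_weight_indexing_respects_counterbalancing():
    """In the medium-first group, block 1 uses the medium-frequency weight
    component and block 2 the fast one."""
    spec = model("hybrid_3freq")
    blocks = np.array([1] * 2 + [2] * 2 + [3] * 2)
    fms = TaskConfig(block_order="fast-medium-slow")
    mfs = TaskConfig(block_order="medium-fast-slow")
    assert spec.weight_indices(blocks, fms).tolist() == [0, 0, 1, 1, 2, 2]
    assert spec.weight_indices(blocks, mfs).tolist() == [1, 1, 0, 0, 2, 2]
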