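"""Hierarchical model fitting and model comparison.

The candidate models are variants of a hybrid agent mixing model-based and
model-free action values.  Fitting is mixed-effects: each free parameter has
a Gaussian group-level distribution on an unconstrained scale, individual
subjects have MAP estimates under that prior, and the group distribution and
subject estimates are updated alternately by expectation-maximization.
Bounded parameters reach their natural scale through a logistic function
(weights, learning rates, eligibility trace) or an exponential (inverse
temperature); the stay bias is unconstrained.

Model comparison uses the integrated BIC (iBIC), which scores each model by
the group-prior-integrated data likelihood (estimated by Monte Carlo)
penalized by the number of group-level hyperparameters, and random-effects
Bayesian model selection, which estimates the posterior probability that
each model is the most common in the population (the exceedance
probability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, special

from ._likelihood import KIND_MB, KIND_MF, nll_core
from .agents import AgentParams, HybridAgent
from .data import Dataset
from .task import S0, TaskConfig

__all__ = [
    "ModelSpec", "model", "CANDIDATE_MODELS", "to_natural", "to_unconstrained",
    "subject_nll", "replay_nll", "HierarchicalModel", "HierarchicalResults",
    "GroupPrior", "ibic", "exceedance_probabilities", "compare_models",
]


# ---------------------------------------------------------------------------
# parameter transforms

def to_natural(x, kind: str):
    """Map unconstrained values to the natural parameter scale."""
    x = np.asarray(x, dtype=float)
    if kind == "logit":
        return special.expit(x)
    if kind == "exp":
        return np.exp(np.clip(x, -30.0, 30.0))
    if kind == "id":
        return x + 0.0
    raise ValueError(f"unknown transform {kind!r}")


def to_unconstrained(v, kind: str):
    """Inverse of :func:`to_natural`; rejects values at exact bounds."""
    v = np.asarray(v, dtype=float)
    if kind == "logit":
        if np.any((v <= 0.0) | (v >= 1.0)):
            raise ValueError("logistic-transformed values must lie strictly in (0, 1)")
        return special.logit(v)
    if kind == "exp":
        if np.any(v <= 0.0):
            raise ValueError("exp-transformed values must be positive")
        return np.log(v)
    if kind == "id":
        return v + 0.0
    raise ValueError(f"unknown transform {kind!r}")


# ---------------------------------------------------------------------------
# model specification

_STRUCTURES = ("pure_mf", "pure_mb", "single", "by_block", "by_frequency")
_CONTROLS = (None, "mf_mf", "mf_mf_traced", "mb_mb")


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: which parameters are free, shared or fixed.

    ``weight_structure`` selects how the model-based weight enters: fixed at
    0 (``pure_mf``) or 1 (``pure_mb``), one free constant (``single``), or a
    free 3-vector indexed by session block (``by_block``) or by
    contingency-change frequency class (``by_frequency``).  ``control``
    replaces the MB+MF pair with a two-MF or two-MB mixture with fixed
    learning rates (0.25 and 0.75) and a free mixing weight.
    """

    name: str
    weight_structure: str = "by_block"
    stay_bias_free: bool = True
    lam_fixed: Optional[float] = None
    single_learning_rate: bool = False
    fictive: bool = True
    free_transition_rate: bool = False
    control: Optional[str] = None

    def __post_init__(self):
        if self.weight_structure not in _STRUCTURES:
            raise ValueError(f"unknown weight_structure {self.weight_structure!r}")
        if self.control not in _CONTROLS:
            raise ValueError(f"unknown control variant {self.control!r}")
        if self.control is not None and self.weight_structure in ("pure_mf", "pure_mb"):
            raise ValueError("control hybrids need a free mixing weight")

    # -- which systems are in play -----------------------------------------
    @property
    def uses_mb(self) -> bool:
        return self.control is None and self.weight_structure != "pure_mf"

    @property
    def uses_mf(self) -> bool:
        return self.control is None and self.weight_structure != "pure_mb"

    @property
    def n_weights(self) -> int:
        if self.weight_structure in ("pure_mf", "pure_mb"):
            return 0
        if self.weight_structure == "single":
            return 1
        return 3

    # -- free parameter layout ---------------------------------------------
    @property
    def param_names(self) -> List[str]:
        names = [f"w{i + 1}" for i in range(self.n_weights)]
        if self.control is None:
            if self.single_learning_rate and self.uses_mf and self.uses_mb:
                names.append("alpha")
            else:
                if self.uses_mf:
                    names.append("alpha_mf")
                if self.uses_mb:
                    names.append("alpha_mb")
        names.append("beta")
        lam_free = (self.lam_fixed is None
                    and (self.uses_mf or self.control == "mf_mf"))
        if lam_free:
            names.append("lam")
        if self.stay_bias_free:
            names.append("stay_bias")
        if self.free_transition_rate and self.uses_mb:
            names.append("alpha_mb_transition")
        return names

    @property
    def transforms(self) -> List[str]:
        kinds = []
        for name in self.param_names:
            if name == "beta":
                kinds.append("exp")
            elif name == "stay_bias":
                kinds.append("id")
            else:
                kinds.append("logit")
        return kinds

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # -- natural-scale parameter dictionary --------------------------------
    def natural(self, x: np.ndarray) -> Dict[str, float]:
        """Expand an unconstrained parameter vector to natural-scale values,
        filling in fixed parameters."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters, got {x.shape}")
        vals = {n: float(to_natural(v, k))
                for n, k, v in zip(self.param_names, self.transforms, x)}
        nw = self.n_weights
        if self.weight_structure == "pure_mf":
            w = np.array([0.0])
        elif self.weight_structure == "pure_mb":
            w = np.array([1.0])
        else:
            w = np.array([vals.pop(f"w{i + 1}") for i in range(nw)])
        if "alpha" in vals:
            vals["alpha_mf"] = vals["alpha_mb"] = vals.pop("alpha")
        out = {
            "w": w,
            "alpha_mf": vals.get("alpha_mf", 0.5),
            "alpha_mb": vals.get("alpha_mb", 0.5),
            "beta": vals["beta"],
            "lam": vals.get("lam", self.lam_fixed if self.lam_fixed is not None else 0.5),
            "stay_bias": vals.get("stay_bias", 0.0),
            "alpha_mb_transition": vals.get("alpha_mb_transition", 1.0),
        }
        return out

    def unconstrained(self, params: Union[AgentParams, Dict]) -> np.ndarray:
        """Pack natural-scale parameters into an unconstrained vector."""
        if isinstance(params, AgentParams):
            d = {"alpha_mf": params.alpha_mf, "alpha_mb": params.alpha_mb,
                 "beta": params.beta, "lam": params.lam,
                 "stay_bias": params.stay_bias,
                 "alpha_mb_transition": params.alpha_mb_transition}
            w = params.w_vector()
        else:
            d = dict(params)
            w = np.atleast_1d(np.asarray(d.get("w", []), dtype=float))
        out = []
        for name, kind in zip(self.param_names, self.transforms):
            if name.startswith("w") and name[1:].isdigit():
                v = w[int(name[1:]) - 1] if len(w) > 1 else w[0]
            elif name == "alpha":
                v = d["alpha_mf"]
            else:
                v = d[name]
            out.append(float(to_unconstrained(v, kind)))
        return np.array(out)

    # -- likelihood-core plumbing ------------------------------------------
    def core_systems(self, nat: Dict) -> tuple:
        """(kind, alpha, lam, alpha_transition) for the high and low system."""
        if self.control is None:
            hi = (KIND_MB, nat["alpha_mb"], 0.0, nat["alpha_mb_transition"])
            lo = (KIND_MF, nat["alpha_mf"], nat["lam"], 1.0)
        elif self.control == "mf_mf":
            hi = (KIND_MF, 0.75, nat["lam"], 1.0)
            lo = (KIND_MF, 0.25, nat["lam"], 1.0)
        elif self.control == "mf_mf_traced":
            hi = (KIND_MF, 0.75, 1.0, 1.0)
            lo = (KIND_MF, 0.25, 0.0, 1.0)
        else:  # mb_mb
            hi = (KIND_MB, 0.75, 0.0, 1.0)
            lo = (KIND_MB, 0.25, 0.0, 1.0)
        return hi, lo

    def weight_indices(self, blocks: np.ndarray, config: TaskConfig) -> np.ndarray:
        """Per-trial index into the weight vector."""
        if self.weight_structure == "by_block":
            return (blocks - 1).astype(np.int64)
        if self.weight_structure == "by_frequency":
            freq = np.asarray(config.frequency_by_block, dtype=np.int64)
            return freq[blocks - 1]
        return np.zeros(len(blocks), dtype=np.int64)

    def agent(self, nat: Dict, config: TaskConfig) -> HybridAgent:
        """Reference-path agent with these natural parameters (for replay)."""
        w = nat["w"]
        params = AgentParams(
            w_mb=tuple(w) if len(w) > 1 else float(w[0]),
            alpha_mf=nat["alpha_mf"], alpha_mb=nat["alpha_mb"],
            beta=nat["beta"], lam=nat["lam"], stay_bias=nat["stay_bias"],
            alpha_mb_transition=nat["alpha_mb_transition"],
            fictive=self.fictive)
        structure = {"pure_mf": "single", "pure_mb": "single",
                     "single": "single", "by_block": "by_block",
                     "by_frequency": "by_frequency"}[self.weight_structure]
        if self.weight_structure == "pure_mf":
            params = replace(params, w_mb=0.0)
        elif self.weight_structure == "pure_mb":
            params = replace(params, w_mb=1.0)
        if self.control is None:
            return HybridAgent(params, structure, config)
        factory = {"mf_mf": HybridAgent.two_mf,
                   "mf_mf_traced": HybridAgent.two_mf_traced,
                   "mb_mb": HybridAgent.two_mb}[self.control]
        kwargs = {}
        if self.control == "mf_mf":
            kwargs["lam"] = nat["lam"]
        agent = factory(float(w[0]), nat["beta"], nat["stay_bias"],
                        fictive=self.fictive, **kwargs)
        agent._w = w
        from .agents import weight_index_by_block
        agent._widx = weight_index_by_block(structure, config)
        return agent


def _spec(name, **kw) -> ModelSpec:
    return ModelSpec(name=name, **kw)


CANDIDATE_MODELS: Dict[str, ModelSpec] = {
    "pure_mf": _spec("pure_mf", weight_structure="pure_mf"),
    "pure_mb": _spec("pure_mb", weight_structure="pure_mb"),
    "hybrid_1w": _spec("hybrid_1w", weight_structure="single"),
    "hybrid_3block": _spec("hybrid_3block", weight_structure="by_block"),
    "hybrid_3freq": _spec("hybrid_3freq", weight_structure="by_frequency"),
    # ablations of the block-indexed hybrid
    "hybrid_3block_no_stay": _spec("hybrid_3block_no_stay", stay_bias_free=False),
    "hybrid_3block_lam0": _spec("hybrid_3block_lam0", lam_fixed=0.0),
    "hybrid_3block_lam1": _spec("hybrid_3block_lam1", lam_fixed=1.0),
    "hybrid_3block_single_alpha": _spec("hybrid_3block_single_alpha",
                                        single_learning_rate=True),
    "hybrid_3block_no_fictive": _spec("hybrid_3block_no_fictive", fictive=False),
    "hybrid_3block_free_transition": _spec("hybrid_3block_free_transition",
                                           free_transition_rate=True),
    # control mixtures with fixed learning rates
    "mf_mf": _spec("mf_mf", weight_structure="single", control="mf_mf"),
    "mf_mf_traced": _spec("mf_mf_traced", weight_structure="single",
                          control="mf_mf_traced"),
    "mb_mb": _spec("mb_mb", weight_structure="single", control="mb_mb"),
}


def model(name: str) -> ModelSpec:
    """Look up a candidate model specification by name."""
    try:
        return CANDIDATE_MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; known: {sorted(CANDIDATE_MODELS)}")


# ---------------------------------------------------------------------------
# likelihood

def _expand_w(spec: ModelSpec, w: np.ndarray) -> np.ndarray:
    """Broadcast a scalar weight for multi-component specs; reject short
    vectors (the compiled core does no bounds checking)."""
    need = max(spec.n_weights, 1)
    w = np.atleast_1d(np.asarray(w, dtype=float))
    if len(w) == 1 and need > 1:
        return np.full(need, w[0])
    if len(w) < need:
        raise ValueError(f"model {spec.name!r} needs {need} weight components")
    return w


def _dataset_arrays(dataset: Dataset) -> dict:
    cached = getattr(dataset, "_arrays_cache", None)
    if cached is None:
        cached = dataset.arrays()
        dataset._arrays_cache = cached
    return cached


def subject_nll(dataset: Dataset, spec: ModelSpec,
                params: Union[AgentParams, Dict, np.ndarray],
                widx: Optional[np.ndarray] = None) -> float:
    """Negative log-likelihood of one subject's first-level choices.

    ``params`` may be an :class:`AgentParams`, a natural-scale dict (as
    produced by :meth:`ModelSpec.natural`), or an unconstrained vector.
    Every trial's observed transition and reward update the agent; only
    first-level trials with a recorded choice contribute likelihood terms.
    """
    if isinstance(params, np.ndarray):
        nat = spec.natural(params)
    elif isinstance(params, AgentParams):
        if spec.weight_structure == "pure_mf":
            w = np.array([0.0])
        elif spec.weight_structure == "pure_mb":
            w = np.array([1.0])
        else:
            w = params.w_vector()
        nat = {"w": w, "alpha_mf": params.alpha_mf,
               "alpha_mb": params.alpha_mb, "beta": params.beta,
               "lam": params.lam, "stay_bias": params.stay_bias,
               "alpha_mb_transition": params.alpha_mb_transition}
    else:
        nat = dict(params)
    nat["w"] = _expand_w(spec, nat["w"])
    arr = _dataset_arrays(dataset)
    if widx is None:
        widx = spec.weight_indices(arr["block"], dataset.config)
    (kh, ah, lh, th), (kl, al, ll, tl) = spec.core_systems(nat)
    val = nll_core(arr["start"], arr["choice"], arr["s2"], arr["ter"],
                   arr["reward"], widx, np.asarray(nat["w"], dtype=float),
                   kh, ah, lh, th, kl, al, ll, tl,
                   nat["beta"], nat["stay_bias"], int(spec.fictive))
    if not np.isfinite(val):
        raise FloatingPointError("non-finite likelihood")
    return float(val)


def replay_nll(dataset: Dataset, spec: ModelSpec,
               params: Union[AgentParams, Dict]) -> float:
    """Reference-path likelihood: replay the trials through the agents
    module, accumulating -log p of each observed choice.

    Slow; used to validate the compiled likelihood.
    """
    if isinstance(params, AgentParams):
        if spec.weight_structure == "pure_mf":
            w = np.array([0.0])
        elif spec.weight_structure == "pure_mb":
            w = np.array([1.0])
        else:
            w = params.w_vector()
        nat = {"w": w, "alpha_mf": params.alpha_mf,
               "alpha_mb": params.alpha_mb, "beta": params.beta,
               "lam": params.lam, "stay_bias": params.stay_bias,
               "alpha_mb_transition": params.alpha_mb_transition}
    else:
        nat = dict(params)
    nat["w"] = _expand_w(spec, nat["w"])
    agent = spec.agent(nat, dataset.config)
    nll = 0.0
    for t in dataset.trials:
        if t.start_state == S0 and t.first_choice is not None:
            p = agent.choice_probabilities(t.block)
            nll -= np.log(p[t.first_choice])
        agent.observe(t)
    return float(nll)


# ---------------------------------------------------------------------------
# hierarchical EM

@dataclass
class GroupPrior:
    """Independent Gaussians over the unconstrained parameters."""

    mu: np.ndarray
    sigma2: np.ndarray

    def logpdf(self, x: np.ndarray) -> float:
        return float(-0.5 * np.sum((x - self.mu) ** 2 / self.sigma2
                                   + np.log(2 * np.pi * self.sigma2)))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mu, np.sqrt(self.sigma2), size=(n, len(self.mu)))


class HierarchicalModel:
    """Mixed-effects model of a cohort's choices under one candidate model.

    Parameters
    ----------
    datasets : the cohort (one :class:`Dataset` per subject).
    spec : which candidate model to fit.
    widx_override : optional per-subject arrays overriding the per-trial
        weight-component index (used by the permutation tests, which shuffle
        block labels without touching the trial sequence).
    """

    def __init__(self, datasets: Sequence[Dataset], spec: ModelSpec,
                 widx_override: Optional[Sequence[np.ndarray]] = None):
        if len(datasets) < 2:
            raise ValueError("hierarchical fitting needs at least two subjects")
        self.datasets = list(datasets)
        self.spec = spec
        self._arrays = [_dataset_arrays(d) for d in self.datasets]
        if widx_override is not None:
            self._widx = [np.asarray(w, dtype=np.int64) for w in widx_override]
        else:
            self._widx = [spec.weight_indices(a["block"], d.config)
                          for a, d in zip(self._arrays, self.datasets)]
        self.n_subjects = len(self.datasets)
        self.n_choice_trials = int(sum(d.n_choice_trials for d in self.datasets))

    @classmethod
    def from_cohort(cls, cohort, spec: ModelSpec) -> "HierarchicalModel":
        return cls(cohort.datasets, spec)

    # -- likelihood ---------------------------------------------------------
    def loglike(self, i: int, x: np.ndarray) -> float:
        """Log-likelihood of subject ``i`` at unconstrained parameters."""
        return -self._nll(i, np.asarray(x, dtype=float))

    def _nll(self, i: int, x: np.ndarray) -> float:
        nat = self.spec.natural(x)
        arr = self._arrays[i]
        (kh, ah, lh, th), (kl, al, ll, tl) = self.spec.core_systems(nat)
        val = nll_core(arr["start"], arr["choice"], arr["s2"], arr["ter"],
                       arr["reward"], self._widx[i], nat["w"],
                       kh, ah, lh, th, kl, al, ll, tl,
                       nat["beta"], nat["stay_bias"], int(self.spec.fictive))
        return val if np.isfinite(val) else 1e12

    # -- EM -----------------------------------------------------------------
    def fit(self, seed: int = 0, n_restarts: int = 5, max_iter: int = 50,
            tol: float = 1e-3, init_sigma2: float = 4.0,
            laplace_in_mstep: bool = True,
            mc_samples: int = 2000) -> "HierarchicalResults":
        """Fit by expectation-maximization.

        E-step: per subject, maximize log-likelihood plus log group prior
        from multiple restarts (the current prior mean, the previous MAP
        once available, and prior draws); the local curvature gives a
        diagonal Laplace covariance.  M-step: update group means and
        variances from the MAP estimates (optionally adding the Laplace
        variances, the standard mixed-effects update).  Stops when all
        group means move less than ``tol`` on the unconstrained scale.
        """
        rng = np.random.default_rng(seed)
        k = self.spec.n_params
        prior = GroupPrior(np.zeros(k), np.full(k, float(init_sigma2)))
        maps = np.zeros((self.n_subjects, k))
        lapvar = np.tile(prior.sigma2, (self.n_subjects, 1))
        have_maps = False
        trace = []
        converged = False
        n_iter = 0
        for it in range(max_iter):
            n_iter = it + 1
            for i in range(self.n_subjects):
                starts = [prior.mu.copy()]
                if have_maps:
                    starts.append(maps[i].copy())
                # random restarts explore only during the first EM sweeps;
                # afterwards the previous MAP is a reliable warm start
                n_draws = max(0, n_restarts - len(starts)) if it < 2 else 0
                if n_draws:
                    starts.extend(prior.sample(rng, n_draws))
                best_x, best_f = None, np.inf
                for x0 in starts:
                    res = optimize.minimize(
                        lambda x: self._nll(i, x) - prior.logpdf(x),
                        x0, method="L-BFGS-B",
                        options={"ftol": 1e-8, "gtol": 1e-5, "maxiter": 500})
                    if res.fun < best_f:
                        best_x, best_f = res.x, res.fun
                maps[i] = best_x
                lapvar[i] = self._laplace_var(i, best_x, prior)
            have_maps = True
            new_mu = maps.mean(axis=0)
            if laplace_in_mstep:
                new_s2 = ((maps - new_mu) ** 2 + lapvar).mean(axis=0)
            else:
                new_s2 = ((maps - new_mu) ** 2).mean(axis=0)
            new_s2 = np.maximum(new_s2, 1e-6)
            delta = np.max(np.abs(new_mu - prior.mu))
            prior = GroupPrior(new_mu, new_s2)
            trace.append({"iter": n_iter, "mu": new_mu.copy(),
                          "sigma2": new_s2.copy(), "delta": delta})
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"EM did not converge in {max_iter} iterations "
                          f"(last mean change {trace[-1]['delta']:.2e})")
        subj_nll = np.array([self._nll(i, maps[i])
                             for i in range(self.n_subjects)])
        return HierarchicalResults(
            model=self, spec=self.spec, prior=prior, maps=maps.copy(),
            laplace_var=lapvar.copy(), subject_nll_at_map=subj_nll,
            n_iter=n_iter, converged=converged, trace=trace,
            options={"seed": seed, "n_restarts": n_restarts,
                     "max_iter": max_iter, "tol": tol,
                     "init_sigma2": init_sigma2,
                     "laplace_in_mstep": laplace_in_mstep,
                     "mc_samples": mc_samples})

    def _laplace_var(self, i: int, x: np.ndarray, prior: GroupPrior) -> np.ndarray:
        """Diagonal Laplace variances from finite-difference curvature."""
        f0 = self._nll(i, x) - prior.logpdf(x)
        k = len(x)
        var = np.empty(k)
        for j in range(k):
            h = 1e-3 * (1.0 + abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            d2 = (self._nll(i, xp) - prior.logpdf(xp)
                  - 2.0 * f0
                  + self._nll(i, xm) - prior.logpdf(xm)) / h ** 2
            # curvature can be tiny or negative at a flat/noisy optimum;
            # cap the implied variance at the prior variance
            var[j] = 1.0 / d2 if d2 > 1.0 / prior.sigma2[j] else prior.sigma2[j]
        return var


@dataclass
class HierarchicalResults:
    """Fit of a :class:`HierarchicalModel`: group prior, per-subject MAPs
    and Laplace variances, plus evidence-based model-comparison scores."""

    model: HierarchicalModel
    spec: ModelSpec
    prior: GroupPrior
    maps: np.ndarray            # (n_subjects, n_params), unconstrained
    laplace_var: np.ndarray     # (n_subjects, n_params)
    subject_nll_at_map: np.ndarray
    n_iter: int
    converged: bool
    trace: list
    options: dict

    # -- parameter access ---------------------------------------------------
    def params_frame(self) -> pd.DataFrame:
        """Per-subject MAP estimates on the natural scale."""
        rows = []
        for i, d in enumerate(self.model.datasets):
            row = {"subject": d.subject}
            for name, kind, v in zip(self.spec.param_names,
                                     self.spec.transforms, self.maps[i]):
                row[name] = float(to_natural(v, kind))
            rows.append(row)
        return pd.DataFrame(rows).set_index("subject")

    def group_means_natural(self) -> pd.Series:
        """Group-level means pushed through the transforms (the location of
        the group distribution on the natural scale, not the mean of the
        transformed distribution)."""
        vals = {n: float(to_natural(m, k)) for n, k, m in
                zip(self.spec.param_names, self.spec.transforms, self.prior.mu)}
        return pd.Series(vals)

    def subject_w(self) -> np.ndarray:
        """Per-subject natural-scale weight estimates, (n_subjects, n_w)."""
        nw = self.spec.n_weights
        if nw == 0:
            raise ValueError("model has no free weights")
        return special.expit(self.maps[:, :nw])

    @property
    def total_nll(self) -> float:
        return float(self.subject_nll_at_map.sum())

    # -- evidence and iBIC --------------------------------------------------
    def log_evidence(self, n_samples: Optional[int] = None, seed: int = 0):
        """Monte-Carlo per-subject log evidence under the fitted prior.

        Returns ``(log_ev, se)`` arrays; ``log_ev[i]`` estimates
        ``log p(data_i | group prior)`` by averaging the likelihood over
        prior draws, and ``se[i]`` is the standard error of the estimate on
        the log scale.
        """
        if n_samples is None:
            n_samples = self.options.get("mc_samples", 2000)
        rng = np.random.default_rng(seed)
        draws = self.prior.sample(rng, n_samples)
        n = self.model.n_subjects
        log_ev = np.empty(n)
        se = np.empty(n)
        for i in range(n):
            ll = np.array([-self.model._nll(i, x) for x in draws])
            m = ll.max()
            w = np.exp(ll - m)
            mean_w = w.mean()
            log_ev[i] = m + np.log(mean_w)
            se[i] = w.std(ddof=1) / (np.sqrt(n_samples) * mean_w)
        return log_ev, se

    def ibic(self, n_samples: Optional[int] = None, seed: int = 0) -> "IBICResult":
        return ibic(self, n_samples=n_samples, seed=seed)

    # -- simulation ---------------------------------------------------------
    def simulate(self, seed: int = 0, source: str = "map"):
        """Simulate a cohort from the fitted parameters.

        ``source="map"`` uses each subject's MAP estimates;
        ``source="group"`` draws fresh subjects from the group prior.
        """
        from .simulate import simulate_cohort
        n = self.model.n_subjects
        if source == "map":
            xs = list(self.maps)
        elif source == "group":
            rng = np.random.default_rng(seed)
            xs = list(self.prior.sample(rng, n))
        else:
            raise ValueError("source must be 'map' or 'group'")
        params = []
        for x in xs:
            nat = self.spec.natural(np.asarray(x))
            w = nat["w"]
            params.append(AgentParams(
                w_mb=tuple(w) if len(w) > 1 else float(w[0]),
                alpha_mf=nat["alpha_mf"], alpha_mb=nat["alpha_mb"],
                beta=nat["beta"], lam=nat["lam"], stay_bias=nat["stay_bias"],
                alpha_mb_transition=nat["alpha_mb_transition"],
                fictive=self.spec.fictive))
        structure = {"pure_mf": "single", "pure_mb": "single",
                     "single": "single", "by_block": "by_block",
                     "by_frequency": "by_frequency"}[self.spec.weight_structure]
        return simulate_cohort(params, self.model.datasets[0].config,
                               n_subjects=n, seed=seed,
                               weight_structure=structure)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        lines = []
        lines.append(f"Hierarchical fit: model {self.spec.name!r}")
        lines.append(f"  subjects: {self.model.n_subjects}, "
                     f"choice trials: {self.model.n_choice_trials}")
        lines.append(f"  free parameters: {self.spec.n_params} "
                     f"({', '.join(self.spec.param_names)})")
        lines.append(f"  EM iterations: {self.n_iter} "
                     f"({'converged' if self.converged else 'NOT converged'})")
        lines.append(f"  total -log L at MAP: {self.total_nll:.2f}")
        lines.append("")
        lines.append(f"  {'param':<22}{'group mean':>12}{'group sd':>10}"
                     f"{'natural':>10}{'MAP median':>12}")
        med = np.median(self.maps, axis=0)
        for j, (name, kind) in enumerate(zip(self.spec.param_names,
                                             self.spec.transforms)):
            lines.append(
                f"  {name:<22}{self.prior.mu[j]:>12.3f}"
                f"{np.sqrt(self.prior.sigma2[j]):>10.3f}"
                f"{float(to_natural(self.prior.mu[j], kind)):>10.3f}"
                f"{float(to_natural(med[j], kind)):>12.3f}")
        return "\n".join(lines)


@dataclass
class IBICResult:
    value: float
    log_evidence: np.ndarray
    se: np.ndarray
    n_observations: int
    n_hyperparams: int

    def __float__(self) -> float:
        return self.value


def ibic(fit: HierarchicalResults, n_samples: Optional[int] = None,
         seed: int = 0) -> IBICResult:
    """Integrated BIC of a fitted model.

    ``iBIC = -2 sum_i log p(data_i | group prior)
    + n_hyper * log(total choice trials)``, where each subject's integrated
    likelihood is a Monte-Carlo average over group-prior draws and
    ``n_hyper`` counts the group-level mean and variance of every free
    parameter.  Lower is better.
    """
    log_ev, se = fit.log_evidence(n_samples=n_samples, seed=seed)
    n_obs = fit.model.n_choice_trials
    n_hyper = 2 * fit.spec.n_params
    total_se = float(np.sqrt(np.sum(se ** 2)))
    if total_se > 0.5:
        warnings.warn(f"iBIC Monte-Carlo error is large "
                      f"(total SE {total_se:.2f} nats); raise n_samples")
    return IBICResult(value=float(-2.0 * log_ev.sum() + n_hyper * np.log(n_obs)),
                      log_evidence=log_ev, se=se,
                      n_observations=n_obs, n_hyperparams=n_hyper)


# ---------------------------------------------------------------------------
# random-effects Bayesian model selection

def exceedance_probabilities(log_evidence: np.ndarray, alpha0: float = 1.0,
                             n_samples: int = 200_000, seed: int = 0) -> dict:
    """Random-effects model selection over a (subjects x models) evidence
    matrix on the log scale.

    A Dirichlet prior over model frequencies is updated by variational
    Bayes; the exceedance probability of each model (the posterior
    probability that it is the most common in the population) is estimated
    by sampling from the Dirichlet posterior.
    """
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("need a (subjects x models) matrix with >= 2 models")
    n, m = L.shape
    alpha = np.full(m, float(alpha0))
    for _ in range(1000):
        logu = L + (special.digamma(alpha) - special.digamma(alpha.sum()))
        g = np.exp(logu - special.logsumexp(logu, axis=1, keepdims=True))
        new_alpha = alpha0 + g.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < 1e-8:
            alpha = new_alpha
            break
        alpha = new_alpha
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    xp = np.bincount(np.argmax(draws, axis=1), minlength=m) / n_samples
    return {"exceedance": xp, "alpha": alpha,
            "expected_frequency": alpha / alpha.sum(),
            "assignment": g}


def compare_models(datasets: Sequence[Dataset],
                   specs: Sequence[Union[str, ModelSpec]],
                   seed: int = 0, fit_kwargs: Optional[dict] = None,
                   n_mc_samples: int = 2000) -> pd.DataFrame:
    """Fit several candidate models and tabulate iBIC, -LL and exceedance
    probabilities (one row per model, best iBIC first in the table order
    given)."""
    fit_kwargs = dict(fit_kwargs or {})
    specs = [model(s) if isinstance(s, str) else s for s in specs]
    rows = []
    evid = np.zeros((len(datasets), len(specs)))
    for j, sp in enumerate(specs):
        fit = HierarchicalModel(datasets, sp).fit(seed=seed, **fit_kwargs)
        ib = fit.ibic(n_samples=n_mc_samples, seed=seed + 1)
        evid[:, j] = ib.log_evidence
        rows.append({"model": sp.name, "n_params": sp.n_params,
                     "neg_loglik": fit.total_nll, "iBIC": ib.value,
                     "converged": fit.converged})
    bms = exceedance_probabilities(evid, seed=seed + 2)
    out = pd.DataFrame(rows)
    out["exceedance_prob"] = bms["exceedance"]
    out["expected_frequency"] = bms["expected_frequency"]
    return out
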