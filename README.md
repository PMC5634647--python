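# contingencyrl

Model-based vs model-free reinforcement-learning analysis of behavior in a
two-level *contingency-change* task.

In this task each trial starts either at a first-level state `S0` (a free
choice between `A1` and `A2`, deterministically leading to second-level
states `S1`/`S2`) or directly at a second-level state. The mapping from
second-level states to the terminal states `S3`/`S4` flips unsignalled every
few trials, and one terminal state pays a high reward, the other its
complement (the two sum to 1; the high payoff drifts as a bounded Gaussian
walk and the high/low assignment swaps every 40 trials). Flexibility to
these *transition-contingency* changes separates the two classic control
systems: a model-based (MB) planner replans immediately from its updated
transition model, while a model-free (MF) learner, having cached first-level
action values, stays on stale actions after changes it never acted through.

The package provides the complete computational pipeline for this class of
experiment, for cognitive and computational-psychiatry researchers working
with trial-level choice data:

* **Task simulation** (`task`, `simulate`): the environment with its
  contingency-flip schedules, reward walk and reward-assignment swaps, and
  cohorts of simulated agents matching the study design (16 subjects, 600
  trials in fast/medium/slow blocks).
* **Agents** (`agents`): MF TD(λ) with fictive (mirror) updates
  (`Q_unvisited = 1 - Q_visited`, exploiting the complementary payoffs), an
  MB planner with transition and reward learning, and hybrids
  `Q = w·Q_MB + (1−w)·Q_MF` with softmax choice
  `p(a) ∝ exp(β·Q(a))` and a perseveration (stay) bias.
* **Behavioral analysis** (`behavior`): stay probabilities in the 2×2
  design previous reward (high/low) × previous transition (changed/fixed),
  condition ANOVA, per-block performance summaries.
* **Hierarchical fitting** (`fitting`): mixed-effects
  expectation-maximization with Gaussian group priors over transformed
  parameters, MAP subject estimates with Laplace variances, integrated-BIC
  and exceedance-probability model comparison across the candidate model
  suite (pure MF, pure MB, one/three-weight hybrids, ablations, control
  mixtures).
* **Validation** (`evaluation`): parameter-recovery grids and permutation
  tests for block-wise and frequency-wise differences in the MB weight,
  including a Hellinger-distance variant.

The fitting API follows the statsmodels convention: build a
`HierarchicalModel(datasets, spec)`, call `.fit()`, and work with the
returned `HierarchicalResults` (`summary()`, `params_frame()`, `ibic()`,
`simulate()`).

## Worked example

```python
import numpy as np
from contingencyrl import (REFERENCE_PARAMS, simulate_cohort,
                           stay_probabilities, condition_anova,
                           HierarchicalModel, model)

# 16 hybrid agents (w = 0.56) on the full 600-trial design
cohort = simulate_cohort(REFERENCE_PARAMS, n_subjects=16, seed=11)

tables = [stay_probabilities(d) for d in cohort.datasets]
print(np.round(np.nanmean([t.probs for t in tables], axis=0), 3))
print(condition_anova(tables).round(4))

fit = HierarchicalModel(cohort.datasets, model("hybrid_1w")).fit(
    seed=0, n_restarts=3, max_iter=12)
print(fit.summary())
```

Output:

```
[[0.589 0.736]
 [0.368 0.25 ]]
                    sum_sq    df         F  PR(>F)
reward              1.9967   1.0  166.5612  0.0000
contingency         0.0033   1.0    0.2720  0.6039
reward:contingency  0.2794   1.0   23.3033  0.0000
residual            0.7193  60.0       NaN     NaN

Hierarchical fit: model 'hybrid_1w'
  subjects: 16, choice trials: 4740
  free parameters: 6 (w1, alpha_mf, alpha_mb, beta, lam, stay_bias)
  EM iterations: 12 (NOT converged)
  total -log L at MAP: 2040.71

  param                   group mean  group sd   natural  MAP median
  w1                           0.063     0.094     0.516       0.516
  alpha_mf                     0.108     0.288     0.527       0.527
  alpha_mb                     0.126     0.322     0.532       0.523
  beta                         1.646     0.042     5.187       5.181
  lam                         -0.049     0.774     0.488       0.501
  stay_bias                    0.187     0.013     0.187       0.189
```

The stay-probability matrix (rows: previous reward high/low; columns:
previous transition changed/fixed) shows the hybrid signature: staying
tracks the previous reward (a large reward main effect, F(1,60) ≈ 167) but
flexibility is reduced after contingency changes experienced without a
first-level action (the reward × contingency interaction, F(1,60) ≈ 23).
The fit recovers the generating parameters (w = 0.56, β = 5, α = 0.5,
stay bias = 0.2) to within shrinkage; "NOT converged" marks the
12-sweep cap used in the example — the weight estimates stabilize within
about six sweeps, the slow residual drift is in the eligibility trace.

A command-line interface mirrors the library:

```bash
contingencyrl simulate --subjects 16 --seed 0 --out data/
contingencyrl analyze  --data data/ --out analysis/
contingencyrl compare  --data data/ --models pure_mf,pure_mb,hybrid_1w --out compare.csv
contingencyrl recover  --seed 0 --out recovery.csv
contingencyrl permute  --data data/ --test blocks --n-perm 100 --out perm.csv
```

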