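# Methods

## The task

The environment is a two-level sequential decision task over five states.
Each trial starts at the first level `S0` with probability 0.5 (two actions,
`A1`/`A2`) or directly at a second-level state `S1`/`S2` (probability 0.25
each; a single forced response). First-level transitions are deterministic
(`A1 -> S1`, `A2 -> S2`). The mapping from second-level states to the
terminal states `S3`/`S4` alternates, unsignalled, between two complementary
contingencies (mapping A: `S1 -> S3`, `S2 -> S4`; mapping B: the reverse).
One terminal state pays a high reward, the other pays one minus that amount.

Defaults reproduce the study design: 600 trials in three 200-trial blocks
whose contingency-flip gaps are drawn uniformly from 3–6, 7–10 and 11–14
trials (fast/medium/slow; the order of the fast and medium blocks is
counterbalanced via `TaskConfig.block_order`), and the high/low reward
assignment swaps every 40 trials, on a grid that contingency flips are
re-drawn to avoid. Flips apply at trial onset, so a flip trial already
exhibits the new mapping. Trials are 1-based; `block = ceil(trial / 200)`.

### Reward walk

The high payoff starts at a draw from Normal(0.5, 0.2) and takes Gaussian
steps of standard deviation 0.15 per trial, reflected at its bounds; the low
payoff is always one minus the high payoff. The reflection bounds for the
high payoff are [0.5, 1] (`TaskConfig.high_payoff_bounds`), not the full
payoff support [0, 1]: a walk reflected on the full support has a uniform
stationary distribution and would spend half its time below the midpoint,
at which point the nominally high-reward state would pay *less* than the low
state and every analysis conditioned on high/low reward (the stay-probability
reward factor, the planner's reward main effect) would lose its meaning.
Keeping the high payoff above the midpoint preserves the intended structure:
one unambiguously large and one unambiguously small reward on every trial.
The walk is a plain reflected walk, not mean-reverting.

The simulator never generates missed trials, but the trial-log format
accepts an empty first-level choice, which loads as missing: such trials
contribute no likelihood term and no first-level learning, while their
observed transition and reward still update the agents.

## The agents

Two value-learning systems run in parallel and are mixed by a weight
`w` (1 = fully model-based):

* **Model-free TD(λ).** The second-level value moves toward the terminal
  reward by `alpha_MF * delta2`. If the trial started at `S0`, the chosen
  first-level action receives `alpha_MF * delta1 + alpha_MF * lam * delta2`,
  where `delta1` is its own one-step error (no reward at the first level)
  computed against pre-update second-level values. With `lam = 0` the first
  level learns only through second-level values; with `lam = 1` the terminal
  reward credits the first-level action directly within the trial.
* **Model-based planner.** A transition belief over the second-level-to-
  terminal mapping (one scalar suffices: the two rows are tied by the
  complement equations, and observing either transition updates knowledge of
  both) is updated toward the observed contingency at rate
  `alpha_MB_transition` (fixed at 1 by default, so knowledge jumps to the
  last observed mapping; optionally free). Subjective terminal rewards move
  toward the observed reward by the delta rule at rate `alpha_MB`.
  First-level values are the expectation of the subjective rewards under
  the transition belief.

Because the two payoffs are complementary, both systems apply a *fictive*
(mirror) update: when a visited second-level value or terminal reward is
updated, the paired unvisited entry is set to one minus the new value.
First-level action values are not mirrored; the unchosen action's preference
reverses through the second-level mirror. All values initialize at 0.5, the
indifference point of the mirrored scale; the transition belief initializes
at mapping A.

Choices are softmax in the mixed values with inverse temperature `beta`,
after transiently adding a perseveration (stay) bias to the value of the
most recently chosen first-level action (intervening forced trials do not
reset it; the bias is never written into stored values).

A note on the model-based reward update: the delta rule moves the estimate
*toward* the observed reward (`R += alpha_MB * (r - R)`); the
away-from-reward variant diverges and is not implemented.

### Reference parameter values

Simulations that need a single documented parameter set use
`alpha_MF = alpha_MB = 0.5`, `beta = 5`, `lam = 0.5`, `stay_bias = 0.2`, and
a reference weight `w = 0.56` (the median fitted hybrid weight). These are
round mid-range values of the natural parameter scales; `beta = 5` gives a
~92% choice probability at a value difference of 0.5, a realistic level of
choice determinism for this task class.

## Behavioral analyses

**Stay probability** is the probability of choosing the first-level action
leading to the same second-level state as visited on the previous trial,
tabulated 2x2 by the previous trial's reward (high = its terminal state was
the one currently carrying the high payoff) and the previous trial's
transition relative to the trial before it (changed/fixed). A trial is
eligible only if it starts at `S0` with a recorded choice and its
predecessor is at least the session's second trial; the main variant further
requires the predecessor to have started at the second level (only those
trials separate model-based from model-free control, because the model-free
system never experienced a first-level action under the new contingency),
the control variant requires a first-level predecessor. Trials following a
missed first-level trial are ineligible. Trials immediately after a reward-
assignment swap are classified under the assignment in force on the previous
trial (the log records the per-trial high state). Empty cells are reported
as NaN with a zero count, never as zero probability.

**Condition ANOVA**: a two-way reward x contingency ANOVA on the per-subject
cell means. The default treats the four cells per subject as independent
observations (error df `4N - 4`, i.e. F(1, 60) at N = 16); a
repeated-measures variant is available behind a flag. Subjects with
undefined cells are excluded with a warning.

**Performance summaries**: per block, the fraction of free-choice trials
whose chosen action leads under the current contingency to the current
high-reward state, and the mean reward per trial.

## Hierarchical fitting

Each candidate model's free parameters are Gaussian at the group level on an
unconstrained scale; a unit-slope logistic maps to [0, 1] (weights, learning
rates, eligibility trace), an exponential maps to `beta >= 0`, and the stay
bias is untransformed. Off-diagonal covariances are fixed at zero.

Fitting is expectation-maximization. The E-step maximizes each subject's
log-likelihood plus log group prior (L-BFGS-B on the unconstrained scale)
and takes a diagonal Laplace variance from finite-difference curvature at
the optimum, capped at the prior variance where curvature is flat. Random
restarts drawn from the current prior run during the first two sweeps; later
sweeps start from the previous MAP and the prior mean, which is faster and
keeps the iteration from being perturbed by fresh draws once the mode is
tracked continuously. The M-step sets each group mean to the MAP mean and
each group variance to the mean squared deviation plus the Laplace variances
(the covariance-free mixed-effects update; a MAP-only variant is a flag).
EM stops when every group mean moves less than 1e-3 on the unconstrained
scale, or at 50 iterations (the result is flagged unconverged and the last
iterate returned). The group prior initializes at mean 0, variance 4.
Likelihood terms come only from first-level trials with a recorded choice;
every trial's observed outcome updates the learners.

The compiled trial-loop likelihood and the reference agent implementation
are two independent code paths; tests assert their exact agreement on every
candidate model.

**Candidate models**: pure model-free, pure model-based, hybrids with one
constant weight, three block-indexed weights, or three frequency-indexed
weights (components selected by each block's contingency-change frequency
class, so counterbalanced block orders map correctly); ablations of the
block-indexed hybrid (no stay bias, `lam` fixed at 0 or 1, a single shared
learning rate, no fictive updates, a free transition learning rate); and
control mixtures of two model-free or two model-based systems with fixed
learning rates 0.25/0.75 and a free mixing weight.

**Model comparison.** iBIC = `-2 * sum_i log p(data_i | group prior) +
n_hyper * log(total choice trials)`, with the per-subject integrated
likelihood estimated by Monte Carlo over group-prior draws (default 2000
per subject, seeded; the standard error of the estimate is reported and a
warning raised when it is large). Exceedance probabilities come from
random-effects Bayesian model selection: a variational Dirichlet posterior
over model frequencies, with the probability that each model is the most
common estimated by sampling that posterior. The same per-subject integrated
likelihoods feed both criteria.

## Parameter recovery

The recovery grid varies one block's weight at a time over 0, 0.1, ..., 1
(33 settings; 11 per block), holding the other two blocks at the reference
weight 0.56 and all other parameters at the reference values, with 16
simulated subjects per setting. Each cohort is refit with the block-indexed
hybrid; the recovered value is the median across subjects of the MAP weight
for the varied block, and Pearson correlations against the truth are
reported per block and overall. Settings that fail to fit are excluded with
a warning; a single-setting grid reports an undefined correlation.

## Permutation tests

Whether fitted weights genuinely differ across blocks is tested by
refitting under label permutations. Each permutation shuffles every
subject's per-trial block labels (the trial sequence, and hence all
learning dynamics, is untouched; labels only select which weight component
governs each choice), producing three equal pseudo-blocks that mix the true
blocks. The statistic is `p(w_later > w_earlier)` under the fitted
group-level Gaussians — the normal CDF of the standardized mean difference
on the unconstrained scale, which is continuous and tie-free where a
subject-counting statistic saturates at 0/1 under group-prior shrinkage.
The one-tailed p-value is the add-one-corrected fraction of permutations
reaching at least the true-label statistic.

The frequency version permutes each subject's counterbalancing-group
assignment (which fixes the block-to-frequency mapping), refits the
frequency-indexed hybrid, and adds a two-tailed Hellinger-distance
statistic between the group-level distributions of the compared weight
components: Gaussian-parametric (closed form on the fitted group
Gaussians) by default, or an empirical shared-bin histogram estimate over
per-subject MAPs. The default permutation count is 100 (every permutation
requires a full refit); calibration tests run at reduced counts.

## Problem sizes used by the shipped checks

The test suite exercises reduced designs chosen to keep each check sharp at
desk scale: the recovery check uses 5 weight values per block with 16
subjects per setting and a 12-sweep EM cap (weights stabilize within ~6
sweeps; the remaining drift is in the eligibility trace and does not move
the weight correlations); null-calibration checks use 300-trial cohorts of
6 subjects with 9 permutations and 20 (blocks) or 10 (frequencies)
replicates; the stay-probability signatures use 1000 simulated agents where
a distributional claim is made and 16 (the study's cohort size) where the
claim is about the study scale. `scripts/acceptance.py` runs the full
33-setting recovery grid. All randomness is seeded; identical seeds
reproduce identical results bit for bit.

## What the generator does and does not emulate

Simulated cohorts reproduce the study's design parameters (trial counts,
block structure, flip schedules, reward walk, counterbalancing) and produce
choices from the generating agents themselves, so fitted models are
well-specified for simulated data. Real data differ in ways the generator
does not emulate: missed trials, reaction times, within-session drift of
parameters (the generating parameters are constant within a subject), and
any behavior outside the hybrid model class. Passing recovery and
calibration checks therefore validates the estimation machinery, not the
adequacy of the model class for any particular empirical dataset.

## Known limitations

* Group priors are diagonal by construction; parameter correlations at the
  group level are not modelled (the free-transition-rate variant is known
  to induce strong correlations and is included only as a comparison model).
* The integrated likelihood is a plain Monte-Carlo average over prior
  draws; for very peaked likelihoods more samples may be needed (the
  reported standard error flags this).
* Exceedance probabilities inherit the variational approximation of the
  standard random-effects scheme; on adversarial evidence matrices the
  variational Dirichlet can deviate a few percentage points from the exact
  assignment-mixture posterior.
* The permutation tests refit the model for every permutation and are
  compute-bound; the default count of 100 is a cost compromise.
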