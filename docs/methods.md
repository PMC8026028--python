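# Methods

## The model

`fixopt` implements a model of simple value-based choice (e.g., picking
one snack from two or three) in which fixations *are* information
sampling.  The decision maker (DM) holds an independent Gaussian belief
about each item's subjective value and, at each 100 ms time step, either

* samples the currently attended item, receiving a noisy signal
  `x ~ Normal(u_i, sigma_x^2)` of its true value and updating the
  belief by conjugate-normal (Kalman) rules, or
* terminates and chooses the item with the highest posterior mean.

Sampling costs `gamma_sample` per step plus `gamma_switch` whenever
attention moves to a different item (the first fixation is exempt).  A
fixation is a maximal run of consecutive samples of one item.  The trial
payoff is the chosen item's true value minus the accumulated costs.

This is a metalevel Markov decision process: states are beliefs
`(mu, lambda, last)` (posterior means, precisions, last-attended item),
actions are computations ("sample item i" or "terminate").  The optimal
policy maximizes the expected termination reward `max_i mu_i` minus
costs.  Exact dynamic programming is infeasible beyond two items (six
continuous belief dimensions for trinary choice), so the policy is
approximated.

### Units

Everything runs in *standardized value units*: the prior over true values
is the standard normal, so one unit is one prior SD of value.  Item
ratings `r` on their native integer −10..10 scale are mapped in by

    u_i = (r_i − alpha · mean(ratings)) / std(ratings),

where the moments are empirical moments of the rating distribution and
`alpha ∈ [0, 1]` is the prior-bias parameter: `alpha = 1` is an unbiased
prior centered on the empirical mean; `alpha = 0` centers the prior at
zero, a strong underestimate when most items are rated positively.  A
consequence of fitting both dataset arms jointly in standardized space is
that parameters mapped back to the raw rating scale differ between arms
by fixed factors: the SD ratio (2.631/2.524 = 1.042 for the
binary-vs-trinary moments shipped with the package) for everything except
`alpha`, and the mean ratio (3.492/4.295 = 0.813) for the prior mean.
These two factors are recomputed by `scripts/acceptance.py`.

## Policy approximation

The value of computation (VOC) of a sampling action is approximated by a
linear combination of three value-of-information (VOI) features:

    VOC^(b, c; w) = w1·VOI_myopic(b, c) + w2·VOI_item(b, c)
                    + w3·VOI_full(b) − (cost(b, c) + w4),

with `VOC^(b, ⊥) = 0` for termination.  `VOI_myopic` is the expected
choice improvement from one more sample (a preposterior analysis:
the post-sample mean is Normal with variance `1/lam − 1/(lam + sigma_x^-2)`),
`VOI_item` from learning one item's value exactly, and `VOI_full` from
learning every item's value; `w1..w3` form a convex combination and `w4`
approximates future sampling costs.  Computations are chosen by a softmax
with inverse temperature `beta`.

### Expected-maximum numerics

All three features reduce to expected maxima of independent Gaussians.

* One uncertain value against a known constant: the standard closed form
  `m·Phi((m−mu)/s) + mu·Phi((mu−m)/s) + s·phi((m−mu)/s)`.
* Two Gaussians: the classical pairwise closed form.
* Three Gaussians (`VOI_full`, trinary): an exact expression obtained by
  splitting `E[max] = Σ_i E[U_i·1(U_i = max)]` and applying Stein's
  identity: each term is `mu_i` times a bivariate-normal orthant
  probability (computed with Owen's T function) plus `sigma_i^2` times
  two Gaussian-product integrals with closed forms.  We chose this exact
  route over quadrature because the product of the competitors' CDFs
  becomes step-like when precisions diverge by orders of magnitude,
  which defeats fixed-node rules; the closed form was validated against
  50-million-draw Monte Carlo (agreement within one MC standard error)
  and against `scipy.stats.multivariate_normal` to machine precision.
* Four or more items (not used by the shipped model, but supported):
  panelled Gauss–Legendre quadrature with panel boundaries at the other
  items' means, where the boundary layers sit.

Negative VOI values from round-off are clipped at zero (the quantities
are provably nonnegative).

### Weight search

Because wide regions of weight space perform nearly identically while
producing behaviorally distinct policies, the search returns an
*ensemble* of near-optimal weight vectors rather than a single optimum,
and behavioral predictions aggregate over the ensemble.  Candidates tile
the unit cube with one uniform draw per box of an `n × n × n` grid
(full scale: `n = 20`, 8000 candidates); the two first coordinates,
sorted, give a uniform draw from the 3-simplex; the third scales `w4`
between 0 and the break-even sampling cost at the prior belief (the
weighted VOI feature value there — costs enter linearly, so the
break-even point is available analytically; a bisection cross-check is
retained).  Each candidate receives baseline evaluation episodes (true
values drawn iid standard normal), then an upper-confidence-bound loop
repeatedly awards extra episodes to the currently top-scoring candidates.
The exploration bonus defaults to three *standard errors* of the mean
return, which tightens as episodes accumulate; the literal
three-standard-deviations variant (which never tightens) is available via
`UCBConfig(exploration="sd")`.  Full-scale budgets are 100 baseline
episodes, top-80 refinement with 10 episodes each for 5000 iterations;
desk-scale runs in the test suite use 64–512 candidates, 10–20 baseline
episodes and 15–250 iterations, chosen to keep the suite within minutes
on one core while preserving the qualitative behavior of the ensembles.
Policy returns are computed as the termination reward (maximum posterior
mean) minus costs; this equals the realized payoff in expectation and
has lower variance.

Two independently seeded ensembles per parameter vector are available
(`policy_set_pair`) so that likelihood estimation and prediction use
different optimization noise.

## Simulation engine

Episodes run on a vectorized engine that advances a whole batch in
lock-step with per-episode true values, weights and temperatures.
Softmax sampling uses the Gumbel-max trick (overflow-free at any finite
`beta`).  Posterior precisions are recomputed from integer sample counts
(`lam = 1 + n·sigma_x^-2`) at every update, so the precision ledger is
bit-exact.  A scalar reference implementation (`run_episode`) follows the
textbook update rule literally and is cross-checked against the engine
distributionally in the tests.  Episodes are capped at `max_samples`
(default 5000; 250–1500 in desk-scale runs) as a guard against
degenerate parameterizations; capped episodes are flagged truncated and
choose by current argmax.

## Likelihood and fitting

The model has no analytic likelihood, so each trial is collapsed to four
summary statistics — chosen item's rating rank, number of fixations,
total fixation time, and fixation-time proportions per rating rank — and
the likelihood of a trial is read from a normalized histogram of the
binned statistics in model simulations with the same unordered rating
set (full scale: 625 simulations × 80 policies = 50,000 per set).
Binning: N cells for the chosen rank; fixation counts capped into
{1, 2, 3, 4, 5+} with zero-fixation trials joining the 1 bin; total time
and N−1 proportion statistics (ranks 0..N−2; the last proportion is
redundant) in quintiles whose edges are 20/40/60/80th percentiles
(linear interpolation) of the reference data, with out-of-range values
in the tail bins.  This gives `C = N·5^(N+1)` cells — 250 (binary) and
1875 (trinary) — which is the unique allocation over rank × count ×
time × proportions consistent with that cell count.  Zero-fixation
trials have undefined proportions and deterministically inherit the
lowest proportion bin.

The dataset likelihood mixes the histogram with a uniform distribution
over cells: `eps/C + (1−eps)·hist[cell]`, with `eps ∈ [0, 0.5]` chosen
per parameter vector to maximize the likelihood (bounded 1-D
optimization, tolerance 1e-4, endpoints checked).  Histograms are cached
per rating multiset and are permutation-invariant by construction
(simulation places items in rating-rank order).

The outer search draws scrambled-Sobol points over the box
`sigma_x ∈ (1, 5)`, `gamma_sample ∈ (0.001, 0.01)`,
`gamma_switch ∈ (0.003, 0.03)`, `beta ∈ (100, 500)`.  The prior bias
`alpha` does not affect the optimal policy (the DM believes her prior),
so it is profiled per point on a seven-value grid containing 0, 1 and
five evenly spaced values with a random offset drawn once per search.
Fitting uses even-indexed trials only (an `index_base` flag sets the
parity convention); odd trials are reserved for out-of-sample behavioral
comparison.  Both arms share one parameter vector and one `eps`.

## Validation against an exactly solvable variant

With Bernoulli samples and Beta(1, 1) priors the belief space is a finite
trellis, so the optimal policy is computable exactly by backward
induction once the episode length is capped (horizon 50 by default; the
memory guard refuses horizons above 60).  The package solves this
variant exactly, builds Beta-belief analogues of the three VOI features
(Beta-CDF closed forms; the two-Beta expected maximum by a 64-node
Gauss–Legendre rule on the product of CDFs), optimizes feature weights
by the same UCB scheme, and measures the ratio of the feature policy's
expected return to the exact optimum over a 3×3 grid of sampling costs
{0.001, 0.002, 0.005} × switching costs {0, 0.005, 0.01}.  Monte-Carlo
evaluation simulates the belief MDP directly — successes arrive with
probability equal to the current posterior mean, which marginalizes the
latent values exactly — and scores the terminal maximum posterior mean
minus costs.  At these settings the feature policy retains ≈98% of the
optimal expected reward in the worst case (the acceptance script
recomputes this number).

## Synthetic study data

The generator emulates the food-choice experiments the model is meant
for: integer liking ratings on a −10..10 scale whose post-discretization
moments match the published per-arm values (3.492 ± 2.631 binary,
4.295 ± 2.524 trinary) within 0.15 — the latent normal's parameters are
solved for by least squares on the discretized moments — 70-item pools,
and trials of 2 or 3 distinct positively rated items (100 per arm at
full scale).  "Human-like" datasets simulate one episode per trial with
a policy drawn uniformly from a near-optimal ensemble at a known
parameter vector, recorded in a ground-truth sidecar for parameter
recovery.  The generator does not emulate: rating noise or retest
unreliability (ratings are treated as unbiased value measures), initial
fixation latencies, saccade gaps, lapses, or any spatial/salience biases.
Passing tests therefore show that the pipeline recovers the model's own
behavior under the published study dimensions, not that the model fits
any particular human dataset.

## Behavioral metrics

`behavior_metrics` computes the standard fixation/choice analyses on any
dataset in the three-table layout, observed or simulated, through one
code path: psychometric choice curves, total-fixation-time distributions,
fixation counts and durations by fixation number (final fixations
segregated, since they are cut off by the choice), fixation-advantage
distributions at fixation onset (an item's cumulative fixation time
minus the mean of the others'), value-directed refixation metrics, and
choice biases (last-fixated, gaze-time, first-fixation).  Estimates are
bin means with percentile-bootstrap 95% CIs from trial-level resampling
(10,000 resamples at full scale, 1000 by default here).  Rating-scale
x-axes bin at integer resolution; time axes use fixed-width bins
(configurable, 200–500 ms defaults).

Two conditioning choices in the qualitative test suite deserve note,
because naive pooled comparisons measure index composition rather than
the mechanisms:

* *Final fixations are shorter.*  Trials that resolve after one or two
  fixations end with a long, decisive run, so the cut-off signature is
  visible at fixation depth: the suite compares final vs non-final
  fixations among fixations at index ≥ 5, mirroring the
  duration-by-fixation-number analysis in which final fixations occupy
  the last bin.
* *Two-item fixations are longer than three-item fixations.*  Trinary
  trials contain more late (hence long) fixations, which can flip the
  pooled mean; the suite compares durations at matched fixation numbers,
  where the binary arm exceeds the trinary arm uniformly.

## Reduced problem sizes

Desk-scale defaults used by the test suite and examples (full-scale
equivalents in parentheses): policy pools of 64–512 candidates (8000),
10–20 baseline episodes (100), 15–250 UCB iterations (5000), histogram
budgets of 25–150 simulations per policy (625), ensembles of 5–20
policies (80), 200 Sobol points (10,000), 40 trials per arm (100), and
episode caps of 250–1500 samples (5000).  These sizes were fixed when
the experiments were designed; the parameter-recovery exercise
(40 trials/arm, 200 points) recovers `sigma_x` and `alpha` within 25%
and ranks the generating parameters above 90% of probed configurations.

## Known limitations

* The approximate likelihood is a summary-statistic likelihood; it is a
  principled device for parameter selection, not a model-comparison
  metric.
* Policy optimization is stochastic; at desk budgets the selected
  ensembles vary noticeably with the seed, which is why behavioral
  checks aggregate over ensembles and why two independently optimized
  ensembles are used for fitting vs prediction.
* The Bernoulli validation bounds approximation quality in a discrete
  analogue only; no exact solution of the Gaussian-belief MDP is
  attempted (that intractability is the reason for the approximation).
* No leaky/decaying accumulation, no parallel sampling of unattended
  items, no per-participant fitting.
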