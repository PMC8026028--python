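# fixopt

Optimal information sampling as a model of eye fixations in simple
value-based choice.

When people choose between a few familiar items (two or three snacks,
say), they look back and forth between the options before deciding, and
what they fixate predicts what they choose.  `fixopt` implements a model
in which those fixations are *rationally allocated information
sampling*: the decision maker holds a Gaussian belief
`u_i ~ Normal(mu_i, 1/lambda_i)` about each item's value, pays a cost
`gamma_sample` to draw a noisy sample `x ~ Normal(u_i, sigma_x^2)` from
the currently fixated item (plus `gamma_switch` to move the eyes), and
stops to take the item with the highest posterior mean when sampling is
no longer worth its cost.  Formally this is a metalevel Markov decision
process whose states are beliefs and whose actions are computations.

Because the optimal policy is intractable beyond two items, it is
approximated by a softmax over a linear value-of-computation proxy

    VOC^(b, c) = w1·VOI_myopic + w2·VOI_item + w3·VOI_full − (cost + w4),

whose features are nested values of information (one more sample /
perfect knowledge of one item / perfect knowledge of all items), with
the weight vectors found by an upper-confidence-bound bandit search and
kept as an *ensemble* of near-optimal policies.  The package also
provides:

* a simulator producing fixation sequences and choices at 100 ms
  resolution, with a standard three-table CSV layout (trials /
  fixations / choices);
* a summary-statistic approximate-likelihood fitting pipeline
  (quintile-binned histograms, epsilon-mixture smoothing, Sobol search
  over `theta = (sigma_x, gamma_sample, gamma_switch, beta, alpha)`,
  with the prior-bias `alpha` profiled on a small grid);
* an exactly solvable Bernoulli-belief variant (backward induction on
  the Beta-count trellis) used to validate the feature-policy
  approximation;
* a synthetic-data generator emulating the binary/trinary food-choice
  study conditions (integer −10..10 liking ratings with published
  moments, positively rated items only), so everything is testable with
  no external data;
* behavioral metric tables (choice curves, fixation durations,
  uncertainty- and value-directed attention, choice biases) with
  bootstrap CIs, computed identically for simulated and observed data.

See `docs/methods.md` for the model, numerics and fitting details.

## A worked example

```python
import numpy as np
from fixopt import (ModelParams, PriorSpec, UCBConfig,
                    ucb_policy_search, simulate_dataset)
from fixopt.synthetic_data import (BINARY_MOMENTS, generate_rating_pool,
                                   generate_trials)
from fixopt import behavior_metrics as bm

rng = np.random.default_rng(0)

# 1. optimize a small ensemble of near-optimal attention policies
params = ModelParams(n_items=2)          # fitted group-level defaults
config = UCBConfig(n_boxes_per_dim=6, n_baseline=16, top_k=8,
                   n_refine=8, n_iterations=40)
ensemble = ucb_policy_search(params, beta=364.0, config=config, rng=rng)

# 2. synthetic binary-choice trials matching the published rating moments
pool = generate_rating_pool(70, BINARY_MOMENTS.mean, BINARY_MOMENTS.sd, rng)
trials = generate_trials(pool, "binary", n_trials=100, rng=rng)
ratings = np.concatenate([np.asarray(t.ratings, float) for t in trials])
prior = PriorSpec(alpha=0.581, rating_mean=ratings.mean(),
                  rating_sd=ratings.std(ddof=1))

# 3. simulate and summarize
sims = simulate_dataset(ensemble, trials, prior, n_sims_per_policy=4, rng=rng)
adv = bm.fixation_advantage_values(sims)
curve = bm.psychometrics(sims, n_boot=200, rng=rng)[
    "choice_rate_vs_relative_rating"]
```

Output (trimmed):

```
best weights w1..w4 = [0.215 0.05  0.736 0.121], mean return = 0.450
3200 simulated trials: mean total fixation time = 1590 ms, mean fixations/trial = 3.60
median fixation advantage at fixation onset = -200 ms
   x  estimate   ci_low  ci_high   n
-2.0  0.216346 0.175481 0.247656 416
 0.0  0.500000 0.467606 0.530190 896
 2.0  0.783654 0.745192 0.824579 416
```

Reading it: the search settles on weights that mix the myopic and
full-revelation features; simulated trials last about 1.6 s of fixation
time spread over 3–4 fixations, in the range of the food-choice tasks.
The negative median fixation advantage says new fixations go to the item
that has so far received *less* fixation time (uncertainty-directed
attention), and the choice curve rises steeply with the fixated item's
relative liking rating — at equal ratings the choice is at chance.

## Command line

```bash
fixopt make-synthetic --arm trinary --n-trials 100 --out data/ --seed 1
fixopt simulate --trials data/ --out sim/ --seed 1
fixopt analyze --data sim/ --out metrics/ --plots
fixopt fit --binary data2/ --trinary data3/ --budget small --out fit.json
fixopt validate-approx --out approx.csv --seed 1
```

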