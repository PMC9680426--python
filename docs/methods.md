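# Methods

## The selection model

A foraging trial presents `2n` selectable targets (default `n = 20` per
class) at normalized positions in the unit square (screen convention:
origin top-left, y increasing downward). Selection is modelled as sampling
without replacement: at each step every remaining item `i` receives a
weight

```
w_i = g(b_class * t_i + b_stick * m_i) * exp(-sigma_d * d_i)
                                       * exp(-sigma_theta * theta_i)
```

and is chosen with probability `w_i / sum_j w_j`. Here

* `t_i = 1` if item `i` is of class A, else 0;
* `m_i = 1` if item `i` has the same class as the previously selected item;
* `d_i` is the Euclidean distance from the last selection (unit-square
  lengths);
* `theta_i` in `[0, 1]` is the angular deviation of the move to `i` from the
  previous direction of travel, divided by pi (0 = straight on, 1 = full
  reversal);
* `g` is the logistic function `1 / (1 + exp(-z))`.

The four biases are unconstrained reals. `b_class` (reported as `pA`) and
`b_stick` (`pS`) act on the logit scale; `sigma_d` (`bP`) and `sigma_theta`
(`bM`) are exponential decay rates in inverse normalized distance and
inverse normalized angle. Negative decay rates encode the opposite bias
(preferring far or direction-reversing targets) and are permitted.

Boundary conventions, chosen so the likelihood is well defined everywhere:

* **First selection.** No history exists, so the weight is the class
  salience alone, `g(b_class * t_i)`. By default the first selection is not
  scored at all (`include_first=False`); the initial-selection models below
  handle it instead.
* **Second selection.** A last item exists but no direction of travel, so
  the direction factor is fixed to 1.
* **Coincident items** are rejected at display construction (minimum
  spacing 1e-6) so the direction of travel is always defined.

### Properties of the logistic link

The logistic class/stick factor lies in (0, 1) and saturates: as
`b_stick -> +inf`, a same-class candidate is favoured over a different-class
one by at most `g(inf)/g(0) = 2`, and with two remaining items (one per
class, spatial biases off) `p(A) -> g(b_class)/(g(b_class)+1/2) -> 2/3`.
Strong stick or class biases therefore tilt, but never force, class runs —
unlike the proximity term, whose unbounded exponent does drive the model to
the greedy nearest-neighbour chain as `sigma_d -> inf`. A consequence worth
knowing: relabelling the classes while negating `b_class` preserves the
preference ordering of first selections but not the exact probabilities
(that identity would require an exponential link). An exponential/softmax
link would change absolute weights while preserving many ratios; the
logistic form is retained because it keeps the class/stick factor a bounded
probability-like quantity and matches the parameterisation the biases were
defined on.

## Initial target selection

First-selection locations are bimodal across people: a top-left-corner mode
and a diffuse central mode. Two models are provided.

**Per-participant betas.** Independent `Beta(a, b)` distributions for the x
and y coordinates of each participant's first selections, fitted by maximum
likelihood (4 parameters per participant; 232 for a 58-participant study).

**Shared two-component mixture.** Two beta components common to all
participants — component 1 the corner mode (smaller mean x by convention),
component 2 the centre — with one per-participant mixing weight `lambda` on
the corner component: 8 + P parameters (66 for P = 58). Defaults used by
the simulator: corner `Beta(1.5, 10)` on both axes, centre `Beta(5, 5)`.

The mixture is fitted by EM. Responsibilities are computed per trial with a
single component indicator shared by x and y: the mixture equations are
written marginally per axis, but a joint indicator is what makes `lambda`
identifiable from bivariate data. The M-step updates `lambda` as each
participant's mean responsibility and the shapes by weighted beta MLE
(log-shape coordinates, analytic gradient, warm-started at the current
shapes), a generalized EM whose observed-data log-likelihood never
decreases. `n_starts` seeded restarts guard against local optima; the
per-participant corner fraction (share of first picks with `x + y < 1`)
plus uniform jitter initializes `lambda`. Coordinates are clamped to
`[1e-6, 1 - 1e-6]` because the beta support is open.

Degeneracy: a component whose total responsibility falls below 1e-8 raises
an error; after convergence, if a single shared component explains the data
as well by BIC, the minority component is flagged degenerate (on
single-cluster data EM tends to split the cluster into two overlapping
components rather than emptying one, so a mass threshold alone is not
informative).

First-item prediction assigns every display item a weight proportional to
the fitted density at its position (product of x and y densities,
lambda-mixed for the mixture), normalized over the display. Simulated first
picks select among actual items by these weights, never a free (x, y) draw,
so simulated data stays inside the model's support.

## Fitting the foraging biases

Per participant, the four biases maximize the summed sequence
log-likelihood via BFGS with the analytic gradient, from 5 starts (the
origin plus Normal(0,1) jitter), gradient tolerance 1e-8. Standard errors
are observed-information (finite-difference Hessian of the negative
log-likelihood at the optimum, central differences, step `1e-5 * (1+|x|)`).
The likelihood is evaluated on flattened per-step candidate arrays
(class/stick indicators, distances, heading changes precomputed once per
sequence), so a 20-trial fit takes well under a second.

The original analysis fits these models in a hierarchical Bayesian sampler
and then works with posterior means; here the same likelihood is maximized
per participant, with optional two-stage empirical-Bayes shrinkage: the
between-participant variance `tau^2` of each bias is estimated by the
method of moments (sample variance of estimates minus mean squared SE,
floored at 0) and each estimate is pulled toward the population mean with
reliability weight `tau^2 / (tau^2 + SE^2)`. Posterior means from a full
hierarchical fit would differ by small prior-driven offsets; the evaluation
layer consumes point estimates either way.

`train_test_split` assigns whole trials at a given fraction, stratified by
(participant, condition) so each group keeps its intended trial counts;
disjoint, exhaustive, and reproducible under the seed.

## Synthetic studies

The default scenario mirrors the paradigm's scale: 58 participants, 20
trials per condition, 40 targets (20 per class) with minimum spacing 0.04,
rejection-sampled uniformly in the unit square (the original displays'
exact layout generator is not documented; the model is position-generic).
Two conditions are emulated: "feature", with population biases
Normal around (b_class 0.5, b_stick 1.0, sigma_d 5.0, sigma_theta 0.5), and
"conjunction", identical except a stronger stick bias (mean 3.0) to produce
the long same-class runs characteristic of hard discriminations. Population
SDs (0.2, 0.3–0.5, 1.0, 0.2) give clear but realistic individual
differences. Per-participant `lambda` is drawn from `Beta(2, 1)` (mean 2/3:
corner starters are the majority group). All randomness flows through one
seeded generator per command; identical seeds give byte-identical outputs.

What the generator does *not* emulate: response times and foraging tempo
(time is outside the model), distractor items, value-weighted targets,
screen-edge effects, attentional lapses, and any path-planning beyond the
one-step-ahead biases. Passing tests on this synthetic data therefore show
that the pipeline is self-consistent and that the estimators recover known
generating processes — not that human foragers obey the model; on real
data the model is a (good but imperfect) approximation, and behaviours like
local path-length optimisation are exactly what its errors expose.

## Evaluation

`step_through` replays each observed trial, recomputing the selection
probabilities over the remaining items at every step, and records the
probability on the actually-selected item, the maximum probability, and the
selected item's rank (ties broken by lowest item id — a measure-zero event
in continuous layouts, fixed for reproducibility). From these records:

* **accuracy** — the proportion of selections where the model's top item
  was chosen, per participant. Its uniform-guessing **chance baseline**
  over a fully foraged n-item trial is `H(n-1)/(n-1)` when the first
  selection is excluded (10.9% for n = 40). The metric averages steps with
  unequal baselines (2.5%–100% as the trial empties), so the baseline is
  always reported alongside.
* **calibration** — records binned by top weight (10 equal-width bins over
  (0, 1] by default); in each bin the mean predicted probability is
  compared with the empirical top-choice frequency. On data generated from
  the scoring parameters every bin agrees within binomial error.
* **rank selection rates** — mean assigned weight vs. empirical selection
  frequency of the rank-r candidate (r = 1, 2, 3), which is where real
  foragers' under-use of runner-up items shows up.
* **path lengths** — total polyline length of a selection order; per
  participant the observed median is compared against sequences simulated
  from their fitted biases on the same displays, along with the proportion
  of trials the observed forager was shorter than the simulated median
  (0.5 under exchangeability).
* **accuracy–parameter association** — Pearson correlation of
  per-participant accuracy with each fitted bias (reported under the field
  labels pA, pS, bP, bM); the proximity bias `bP` is the dominant driver of
  predictability. Zero-variance inputs are flagged undefined.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline at study scale —
58 participants x 20 trials x 40 targets (~45,000 scored selections) for
the step-through and calibration checks, 20 replicate refits for parameter
recovery, and a 40-participant x 20-trial mixture recovery — chosen as the
smallest sizes at which the population-level claims are sharp. The
brute-force likelihood oracle (total probability over all complete orders
equals 1) uses 4–5-item displays, where exhaustive enumeration is exact.
Normalization is always computed in log space (max-subtracted logsumexp),
which keeps the `sigma_d = 500` greedy limit exact where naive weights
would underflow. Optimizer and EM tolerances: 1e-8; EM restarts: 3;
fit restarts: 5.

## Known limitations

* Point estimates, not posteriors: uncertainty is normal-approximation
  only, and shrinkage is two-stage rather than joint.
* The accuracy metric inherits the unequal-baseline caveat above.
* The logistic link bounds class/stick preferences (see above); data
  generated by a forager with truly deterministic runs is outside the
  model family.
* Continuous-uniform displays; gridded or structured layouts may interact
  differently with the proximity bias.
* One split protocol (per-participant random halves); no k-fold machinery.
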