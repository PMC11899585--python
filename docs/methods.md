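# Methods

## The estimation problem

`medcnn` estimates natural direct and indirect effects when the mediator
is not a single measured variable but a high-dimensional, group-structured
feature set — microbiome OTU abundances grouped by phylum, gene expression
grouped by pathway, and similar designs.  The causal quantities follow the
counterfactual definitions for a binary exposure A, continuous outcome Y
and scalar mediator M:

* NIE = E[Y_{a M_a} − Y_{a M_{a*}}] — the effect transmitted through the
  mediator;
* NDE = E[Y_{a M_{a*}} − Y_{a* M_{a*}}] — the remainder;
* TE = NIE + NDE.

With linear mediator and outcome regressions and no exposure–mediator
interaction,

    E[M | A] = beta0 + beta1 A
    E[Y | A, M] = alpha0 + alpha1 A + alpha2 M

the effects at the natural contrast (a, a*) = (1, 0) are NIE =
alpha2 · beta1 and NDE = alpha1.  The package also carries the general
formulas with a confounder and an exposure–mediator interaction
(`effects.nie_full` / `nde_full`) so the simplified forms can be checked
as special cases, but it never fits that extended model: confounder
adjustment is deliberately out of scope.

## The integrative mediation metric (IMM)

The scalar mediator in the regressions is not observed; it is summarized
from the grouped features by a composite convolutional network.  Each of
the K feature networks gets its own 1D-CNN branch: two convolutions (32
then 64 filters, kernel 5, stride 1, ReLU activations, "same" padding),
each followed by width-2 pooling, then a linear unit that condenses the
flattened maps to one scalar branch score P_k.  The K branch scores feed
one linear output unit producing h(Z), the IMM.  Branches are independent
by construction: zeroing the head weight of branch k makes h invariant to
network k (tested).

Before entering a branch, features within a network are reordered by a
composite correlation score — the geometric mean of the absolute Pearson
correlations of each feature with all features in its network (diagonal
included) — in descending order, ties broken by original position.  This
places strongly inter-correlated features adjacently so the width-5
kernels can exploit local structure.  The permutation is estimated on the
training split only and applied unchanged to the test split.  Features are
column-standardized (training-split statistics) before the CNN.

The network is implemented directly on NumPy (float32, im2col
convolutions, hand-derived reverse-mode gradients, Adam optimizer);
gradient correctness is verified against central finite differences in the
test suite.

## Alternating estimation

The joint loss over the IMM and the five regression coefficients is

    L = Σ_i (y_i − alpha0 − alpha1 A_i − alpha2 h(Z_i))²
            + (h(Z_i) − beta0 − beta1 A_i)² .

Estimation alternates, in the spirit of EM:

1. **IMM step.**  With the coefficients frozen, the per-sample minimizer
   of L in h(Z_i) is the closed form
   r_i = [(y_i − alpha0 − alpha1 A_i) alpha2 + beta0 + beta1 A_i] /
   (alpha2² + 1) (an identity checked against a grid-search oracle); the
   CNN is trained toward these targets by mini-batch Adam, warm-starting
   from the previous iteration's weights.
2. **Regression step.**  The predicted IMM is standardized (sample SD,
   n−1) and the two OLS regressions are refit, giving updated
   coefficients and their covariance blocks.

Iterations stop when the relative change of every coefficient is below a
percentage threshold (default 0.01%; denominator |previous value| floored
at 1e−8) or after `max_iter` iterations.  A 70/30 train/test split
(stratified on A) is made first; reported effects use the training-split
regressions, with test-split effects stored for diagnostics.  The NIE
estimate alpha2·beta1 is invariant to affine rescaling of the IMM (alpha2
scales by 1/c, beta1 by c), which is why per-iteration standardization
does not bias it.

Initialization is deterministic: the initial IMM is the standardized
first principal component of the pooled (reordered, scaled) training
features, and the initial coefficients come from the two OLS fits on it.
For near-linear feature maps this starts the loop close to the truth; for
non-linear maps the CNN iterations do the real work.

**Early stopping.**  Within each outer iteration the CNN can be trained
with validation-based early stopping: a fraction (default 15%) of the
training split is held out, and training halts once validation MSE has
not improved for `patience` epochs, restoring the best-validation
weights.  This matters for calibration.  The targets r_i contain outcome
noise; without a generalization guard the network memorizes it, the
training-split regression then attributes that memorized noise to
alpha2, and under a complete null (alpha2 = beta1 = 0) the product
alpha2·beta1 drifts away from zero (we measured null NIE estimates around
0.6–0.7 without early stopping versus ~0.02 with it).  Because the rule is
validation-driven it is adaptive: under a null it stops within a few
epochs; when real signal is present it trains for as long as the signal
generalizes.  Early stopping is the package's default operating mode for
simulation work; setting `patience=None` recovers the plain
fixed-epoch loop.

## Synthetic data generator

The generator emulates the grouped-mediator study design used throughout:

* A_i ~ Bernoulli(0.5); M_i = beta0 + beta1 A_i + N(0, sigma_M);
  Y_i = alpha0 + alpha1 A_i + alpha2 M_i + N(0, sigma_Y).
* Default coefficients beta0 = 2, alpha0 = 1.5, alpha1 = 2, alpha2 = 5,
  sigma_M = sigma_Y = 2, n = 1000, five networks of 100/150/120/130/140
  features.  Scenarios: complete null (alpha2 = beta1 = 0), no
  mediator→outcome path (alpha2 = 0), no exposure→mediator path
  (beta1 = 0), and the alternative (both non-zero; beta1 on the grid
  ±5, ±3, ±1).  True NIE = alpha2·beta1 (25 at beta1 = 5), true NDE = 2.
* Each feature is a_kj + b_kj · f(M_i) + N(0, 1) with loadings
  b_kj ~ U(0.5, 1.5) with random sign and intercepts a_kj ~ U(−1, 1) —
  chosen so every feature is informative about M with heterogeneous
  strength.  f is the identity in linear mode; in non-linear mode f
  cycles through {x², sin x, |x|, exp(x/5)}, a fixed dictionary that
  includes non-monotone maps while keeping runs reproducible.
* Optional pairwise interactions: features at 1-based positions
  5, 10, 15, … form consecutive pairs (5,10), (15,20), …; for each pair
  the next column (11, 21, …) is incremented by 2 × the elementwise
  product of the pair.
* One master seed expands into per-replicate `SeedSequence([seed, rep])`
  substreams, so any replicate is reproducible in isolation and replicate
  streams are disjoint.

What the generator does *not* emulate: compositionality and zero
inflation of real abundance data, within-network correlation beyond the
shared latent factor, confounding, and missing data.  Passing tests
therefore demonstrate correct behavior of the estimator under its own
generative assumptions, not robustness to real microbiome artifacts.

## Comparator estimators

Two simplified surrogates of established high-dimensional mediation
approaches serve as benchmarks, both operating on the pooled feature
matrix (hence exactly invariant to within-network feature order):

* **sd_based** — principal components retaining 90% of pooled variance
  become uncorrelated candidate mediators; NIE = Σ_c (outcome
  coefficient of component c) × (component-on-exposure slope).
* **reg_based** — sure-independence screening keeps the n/log n features
  most associated with the outcome; a lasso (or an MCP approximation via
  local linear reweighting) on exposure-residualized features selects
  mediators; an unpenalized refit gives outcome coefficients and NIE is
  the coefficient-times-slope sum.

These are faithful simplifications, not reimplementations of the
published methods, and comparisons against them are treated as
qualitative.

## Numerical and design choices

* Pearson correlation for the reordering scores; the diagonal (=1) enters
  the geometric mean, as the composite-score definition writes it.
* Pooling: width 2, stride 2.  Both average (default) and max pooling are
  implemented; the estimator's effect estimates are insensitive to the
  choice in our measurements, and average pooling keeps the branch maps
  linear between activations.
* Optimizer: Adam, default lr 1e−3 / batch 32 / 100 epochs per outer
  iteration for full-fidelity runs.  The **fast profile** used by the
  simulation harness and the acceptance script (single CPU): lr 5e−3,
  batch 128, 60 epochs in the first outer iteration, 10 thereafter,
  patience 5 with one learning-rate drop (×0.2) at the first validation
  plateau, at most 3 outer iterations, replicate counts 3–6 per
  condition.  These were chosen by monitoring the IMM's recovery of the
  latent mediator on the generator (correlation ≥ 0.995 is reached within
  the first-iteration budget in the linear setting); a full-fidelity run
  uses 100 replicates and the default schedule.
* Standardized features are clipped at ±5 SD before entering the CNN.
  Gaussian readouts are essentially unaffected; the clip matters for the
  heavy-tailed interaction columns (products of squared readouts reach
  x⁴-scale tails), whose outliers otherwise dominate mini-batch gradients
  and noticeably worsen the IMM fit in the interaction scenarios.
* Exposure contrast fixed at (a, a*) = (1, 0).
* Delta-method SEs use the independent-regressions (Sobel) first-order
  form: se(NIE) = sqrt(beta1² Var(alpha2) + alpha2² Var(beta1)); the
  alpha2–beta1 cross-covariance is zero because the two coefficients come
  from separate OLS fits.
* Degenerate inputs fail loudly: constant exposure, zero-variance feature
  columns, a CNN collapsed to a constant IMM, and missing values all
  raise specific errors rather than producing silent numbers.

## Known limitations

* No confounder adjustment, hypothesis tests, bootstrap intervals, or
  feature-importance scores — all deliberately out of scope.
* Reported effects come from training-split regressions on a CNN-derived
  mediator, so they inherit a small optimism/attenuation trade-off: with
  heavy training the network memorizes outcome noise and inflates
  |alpha2|; with conservative early stopping the IMM's residual error
  attenuates the NIE slightly (order −1 on a true NIE of 25 at the fast
  profile).  Monte-Carlo spreads at the fast profile are correspondingly
  tighter than a full-fidelity run's.
* The delta-method SE understates uncertainty because it treats the IMM
  as known.
* Feature tables are TSV/CSV only.
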