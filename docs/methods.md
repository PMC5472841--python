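# Methods

## Model

`mnrm` fits the multidimensional nominal response model (MNRM) to an
N × J matrix of unordered categorical responses coded 1..K.  Category k of
item j carries a linear utility in the D latent traits,

    z_jk(θ) = c_jk + Σ_d a_jkd θ_d,

and the response probabilities are the softmax over an item's categories,

    P_jk(θ) = exp(z_jk) / Σ_k' exp(z_jk').

Unlike an ordinal factor model, every *category* has its own slope vector,
so the model performs a nominal factor analysis: the relation between each
response option and each trait is estimated, with no order assumed among
the options.

Adding a constant to all of an item's utilities leaves the probabilities
unchanged, so per item one intercept and D slopes must be constrained.
Three equivalent parameterizations are implemented and interconvertible:

* **simple** — one reference category (default K) has c = 0, a = 0;
* **deviation** — intercepts and slopes sum to zero across categories
  (obtained by centering, which is a pure utility shift);
* **scoring** — category slopes factor into an item slope a_jd times
  category scores s_jkd anchored at s_j1d = 0 and s_jKd = K − 1
  (a_jkd = s_jkd a_jd).  The scoring transform divides by the slope of
  category K after re-referencing category 1 to zero, and raises a
  descriptive error when that anchor slope is numerically zero.

Transforms never change the likelihood; tests verify probability
equivalence to 1e-10 at random traits.

## Identification

Rotational and scale indeterminacy of the trait space is removed during
estimation by the echelon pattern on the stacked J(K−1) × D slope matrix A
(reference-category rows are structural zeros): row t (t = 1..D) has its
t-th entry fixed to 1 and entries to the right fixed to 0.  The fixed unit
slopes anchor the orientation and scale of each trait; the trait standard
deviations σ_d are estimated in compensation.  Free-parameter counts are

    free slopes = J(K−1)D − D(D−1)/2 − D,   free intercepts = J(K−1),

plus D trait SDs.

## Priors and posterior

Two presets: informative — c_jk, a_jkd ~ N(0, 3), σ_d ~ lognormal(0, 0.5)
(median 1, mean e^{1/8} ≈ 1.13, SD ≈ 0.60); uniform — c, a ~ U(−10, 10)
with the same lognormal on σ.  All scale parameters are standard
deviations.  Traits are random effects, θ_id ~ N(0, σ_d), independent
across dimensions.

Sampling uses an own-implementation multinomial no-U-turn sampler (NUTS)
with analytic gradients, dual-averaging step-size adaptation (target
acceptance 0.8) and a diagonal mass matrix estimated from a mid-warmup
window.  Default run: 4 chains × 2000 iterations, first 1000 discarded.
Design choices that matter:

* **Non-centered traits.**  θ_id = σ_d η_id with η ~ N(0, 1).  Each person
  contributes only J observations, so θ_i is weakly informed and the
  centered geometry (Neal's funnel) mixes poorly.
* **Bounded priors via logistic transform.**  Uniform(−10, 10) parameters
  are sampled through x = −10 + 20·expit(u) with the Jacobian in the
  target, keeping the sampler unconstrained.
* **Orientation-aware initialization.**  The posterior is multimodal in the
  trait orientations: reflecting a dimension's slopes (the fixed unit slope
  cannot flip, which is what usually makes one basin dominant) and even
  partial flips of a single item's or category's slopes create local modes.
  Joint-space mode finding is unreliable here — the joint density both
  degenerates along the scale ridge and ignores the θ-integration volume
  that determines which basin actually carries mass — so modes are found on
  the **θ-marginalized posterior** (Gauss–Hermite quadrature for D ≤ 2 with
  analytic gradients; a per-person Laplace approximation for D ≥ 3), with a
  hill-climb over whole-dimension and per-item sign-flip moves.  Chains
  start at the dominant basin's mode, with η at each person's conditional
  posterior mode, jittered per chain; a chain that drifts out of its
  assigned basin during warmup is resampled from a fresh jitter (bounded
  retries).
* **Near-tied orientations.**  Occasionally (small N) two orientation
  basins hold nearly equal marginal mass; when the top two basin maxima are
  within 0.5 log-units (posterior odds within about 1.6:1), half the chains
  are started in each basin so the retained draws approximate the mixture
  posterior rather than conditioning arbitrarily on one basin.  Split-chain
  R̂ then correctly reports the disagreement.  Such datasets are genuinely
  orientation-ambiguous: no estimator can recover the generating signs from
  them.
* **Summaries.**  EAP = posterior mean over retained draws; posterior SDs
  use the sample (n−1) convention, so fixed entries report SD exactly 0.
  Convergence is monitored by split-chain R̂ per free parameter (each chain
  halved); 1.05 is the warning threshold, values ≤ 1.01 indicate good
  convergence.

### The scale ridge

Only the products a_jkd σ_d (and the intercepts) are strongly identified;
the split between σ_d and the slope scale is pinned down solely by the
single fixed unit slope per dimension.  The marginal posterior of σ_d is
therefore wide and, because smaller σ concentrates more prior volume for
the compensating slopes, it typically sits below the generating value even
for data simulated with σ = 1 (verified against an independent ensemble
sampler on the θ-marginalized posterior).  Consequently the simulation
study evaluates slope recovery on the **standardized metric** — the EAP of
a_jkd σ_d, the slope in a unit-variance trait coordinate system, which is
what IRT software conventionally reports — while σ_d recovery is reported
raw, where its error (~0.4–0.5, nearly independent of N) simply reflects
this weak identification.  Raw EAPs are unchanged everywhere else.

## Model evaluation

**Nominal SGDDM.**  Each (item, category < K) pair is a binary pseudo-item
X_ijk.  For two pseudo-items from different items the pairwise statistic is
the absolute residual cross-moment standardized by the residual root mean
squares (population 1/N moments), with P_ijk evaluated at a posterior
draw's (c, a, θ); it is bounded by [0, 1].  Pairs with zero residual
variance are undefined: they raise at the pair level and are excluded (with
a warning and count) from the aggregate.  The aggregate sums pairs over
j < j′ and all category pairs and multiplies by 2/[J(K−1)(J(K−1)−1)]; note
this constant counts all pseudo-item pairs while the sum omits within-item
pairs (54 of 66 at J = K = 4) — the printed form is the default and
`pair_mean=True` divides by the number of summed pairs instead.

**Posterior predictive check.**  For each (thinned, default 500 evenly
spaced) retained draw, predicted data are simulated conditional on the
draw — same persons' θ by default (`redraw_theta` optionally redraws from
N(0, σ)).  p_post is the proportion of draws whose predicted SGDDM is ≥
the realized one (ties count as exceedance).  A well-specified model gives
p_post scattered around 0.5; an under-dimensioned fit leaves cross-item
residual structure, so realized exceeds predicted and p_post collapses
toward 0.  Rejection uses p_post ≤ 0.05.

**Information criteria.**  The pointwise unit is the person (θ_i couples a
person's responses): ll_li = Σ_j log P at draw l.  WAIC uses
lppd_i − var_l(ll_li) with the sample-variance penalty (the R `loo`
package's convention; arviz differs by ddof only).  LOO is PSIS-based
(Pareto-smoothed importance weights via arviz, reff = 1), with per-unit
k̂ diagnostics reported, not fatal.  DIC uses the conditional
(θ-inclusive) deviance with the plug-in at posterior means of (c, a, θ);
all three are reported on the −2·elpd scale.

## Simulation study harness

A `StudyCondition` fixes generator dimensionality (built-in 4-item,
4-category parameters; for D < 3 the leading slope columns are used),
sample size, prior preset, replication count and sampler settings; seeds
split hierarchically (master → replication → simulate/fit/PPC), so any
replication is reproducible in isolation.  Metrics: EPR (share of
replications with p_post ≤ 0.05), EPS (argmin of DIC/WAIC/LOO per
replication, ties to the lowest dimensionality), and per-group RMSE
(intercepts; standardized slopes; σ) averaged over replications, free
parameters only.  Replication failures are logged, excluded and counted,
never silently averaged.

Default desk-scale settings (10 replications, 2 chains × 500 iterations,
250-draw warmup, 150 PPC draws) run one condition in a few minutes; the
full design (50 replications, 4 × 2000 chains, 3 sample sizes × 3
dimensionalities × 2 prior sets) is supported through the same config but
takes hours.

## What the generator does and does not emulate

The synthetic data match the study design exactly: uncorrelated standard
normal traits, constant K across items, complete responses, and strong
slopes on every item.  Real questionnaire data bring missing responses,
correlated or weak dimensions, testlet structure and person heterogeneity
that the generator does not produce, so passing desk-scale checks
demonstrates correctness of the machinery and the behavior of the
statistics under the stated design, not robustness to those features.

## Numerical choices

Softmax is computed with max-subtraction (an exact utility shift), stable
to |z| ≈ 700.  Deviation/scoring constraint checks use 1e-10; SGDDM
residual variances below 1e-12 mark a pair undefined.  Varimax uses the
Kaiser-normalized SVD iteration to a 1e-8 criterion change.  Draw CSVs are
written with 17 significant digits and parsed with round-trip float
precision, so write→read is lossless.  Empty datasets (N = 0) are valid:
the sampler then targets the prior, which is how the prior-moment checks
are exercised.
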