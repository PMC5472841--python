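# mnrm — Bayesian multidimensional nominal response modelling

`mnrm` estimates and evaluates the **multidimensional nominal response
model (MNRM)**: a factor-analysis model for items whose response options
are *unordered* categories (multiple-choice distractors, survey options,
learning-style choices).  Where an ordinal factor model gives each item one
slope per dimension, the MNRM gives each *category* its own slope vector,
so the analysis recovers how every response option relates to every latent
dimension.  The package is aimed at psychometricians and applied
methodologists who need to answer two questions for nominal data: *how many
latent dimensions are there*, and *what do the category parameters look
like* under a stabilizing Bayesian treatment.

## Model

For an item j with categories k = 1..K and a trait vector θ ∈ R^D,

    P_jk(θ) = exp(z_jk) / Σ_k' exp(z_jk'),        z_jk = c_jk + Σ_d a_jkd θ_d,

with identification by a reference category (simple constraints),
sum-to-zero (deviation) constraints, or an item-slope × category-score
factorization — all interconvertible without changing the likelihood.
Estimation fixes the echelon pattern on the stacked slope matrix (unit
slope on each dimension's first row, zeros above) and samples the joint
posterior of intercepts, free slopes, trait SDs σ_d and person traits by a
gradient-based no-U-turn sampler, under either informative priors
(c, a ~ N(0, 3), σ ~ lognormal(0, 0.5)) or uniform(−10, 10) priors.

Dimensionality is assessed two ways:

* **SGDDM posterior predictive check** — the standardized generalized
  dimensionality discrepancy measure: the average absolute standardized
  residual cross-moment between category pairs of different items, compared
  between observed data and data simulated from each posterior draw.  Too
  few dimensions leave cross-item residual structure, so the realized value
  exceeds the predicted one and the posterior predictive p-value (p_post)
  collapses toward 0; the model is rejected when p_post ≤ 0.05.
* **Discrepancy statistics** — DIC, WAIC and PSIS-LOO on the person-wise
  conditional likelihood, for relative comparison of candidate
  dimensionalities.

See `docs/methods.md` for assumptions, priors, sampler design and known
limitations (notably the weakly identified trait-scale split).

## Worked example

Simulate responses from the built-in two-dimensional generating design
(4 items × 4 categories, N = 500, standard-normal uncorrelated traits),
then ask whether one dimension is enough:

```python
from mnrm import (NominalResponseModel, generate_theta,
                  simulate_responses, table2_parameters)

truth = table2_parameters(2)                       # built-in 2-D design
latent = generate_theta(500, 2, 1.0, seed=7)
X = simulate_responses(truth, latent, seed=8)

for D in (1, 2):
    model = NominalResponseModel(X, D)             # informative priors
    res = model.fit(chains=2, iterations=500, warmup=250, seed=9)
    ppc = res.sgddm_ppc(thin=150, seed=10)
    print(f"D={D}: p_post={ppc['p_post']:.3f}  "
          f"realized={ppc['realized'].mean():.4f}  "
          f"predicted={ppc['predicted'].mean():.4f}")
print(res.summary().head(4).round(3))
```

Output:

```
D=1: p_post=0.000  realized=0.0554  predicted=0.0311
D=2: p_post=0.720  realized=0.0279  predicted=0.0306
         mean     sd   rhat
c[1,1] -0.550  0.180  1.000
c[1,2]  0.005  0.209  1.092
c[1,3]  1.105  0.155  1.010
c[2,1] -0.787  0.464  1.049
```

The one-dimensional fit is rejected: its realized SGDDM (0.055) clearly
exceeds what the model predicts for itself (0.031), so no posterior draw
shows the predicted value at or above the realized one (p_post = 0).  The
two-dimensional fit reproduces its own discrepancy level (0.028 vs 0.031)
and p_post lands comfortably in the retention region — the check recovers
the generating dimensionality.  The summary table reports EAP estimates,
posterior SDs and split-chain R̂ per free parameter.

A command-line interface wraps the same steps (`mnrm simulate`, `mnrm fit`,
`mnrm evaluate`, `mnrm rotate`, `mnrm study`); run `mnrm --help`.

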