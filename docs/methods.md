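# Methods

## The estimation problem

Two-stage cluster surveys (clusters sampled within districts with
probability proportional to size, individuals within clusters) yield too
few observations per district for stable direct prevalence estimates.
`distprev` borrows strength across the administrative hierarchy with a
four-level random-intercept logistic model and turns its posterior into
per-district prevalence figures that are comparable across survey waves.

## Outcome definitions

Binary outcomes come from WHO cutoffs applied to biomarker readings:

* **Hypertension** — combined systolic ≥ 140 mmHg and/or combined
  diastolic ≥ 90 mmHg, both cutoffs inclusive, invariant to age and sex.
* **Diabetes** — random blood glucose ≥ 200 mg/dL, inclusive.

Blood pressure is measured three times per participant. How three readings
become one is a genuine design choice; the default here averages the 2nd
and 3rd readings (the documented convention for the portable monitors used
in DHS-style surveys, whose first reading runs systematically high), with
`mean_all` and `last` as configurable alternatives. The choice is recorded
in classification logs because the cutoff is applied to the combined value.

Eligibility is ages 15–49 inclusive. Persons missing the required
biomarkers are excluded and tallied by reason; missingness is assumed
ignorable (it is generated MCAR in the synthetic data).

## The model

For person *i* in cluster *j*, district *k*, state *l*:

```
y_ijkl ~ Bernoulli(p_ijkl)
logit(p_ijkl) = beta0 + u_jkl + v_kl + f_l
u ~ N(0, sigma2_u),  v ~ N(0, sigma2_v),  f ~ N(0, sigma2_f)
```

The individual level contributes the logistic distribution's fixed
variance of pi^2/3 ≈ 3.29. One model is fitted per outcome × sex × wave
cell; there are no covariates, by design — the model exists to pool, not
to adjust.

### Sampling scheme

The sampler is exact Gibbs via Pólya-Gamma data augmentation: one
auxiliary omega_i ~ PG(1, eta_i) per person makes the Bernoulli-logit
likelihood Gaussian in the linear predictor, so the intercept and each
residual block have closed-form normal full conditionals and each variance
component an inverse-gamma full conditional. No tuning parameters, no
rejection at the model level. The PG(1, z) primitive is implemented
in-package with the alternating-series rejection sampler for the Jacobi
J*(1, z) density (truncated inverse-Gaussian proposal below the crossover
point 2/pi, truncated exponential above); it is exact and numba-compiled,
at roughly 0.3 µs per draw.

Update order is fixed — omega, beta0, u, v, f, then the three variances —
and persons are canonically sorted by ID when the design matrix is built,
so a seeded run is bit-reproducible and invariant to input row order.

### Priors, initialisation, chain lengths

* Flat (improper) prior on beta0; Inv-Gamma(0.001, 0.001) on each
  variance, both configurable. These mirror the diffuse defaults of the
  multilevel-MCMC software tradition this workflow comes from. The
  posterior is proper whenever the response is not constant.
* Starting values: intercept at the empirical log-odds (clamped to
  ±logit(1/(n+1)) for degenerate all-0/all-1 responses), residuals at
  zero, variances at 0.1 — an approximate-mode start. Iterative
  quasi-likelihood point estimation is deliberately not implemented:
  starting values only affect burn-in, never the stationary distribution,
  and the burn-in default (500) absorbs the difference.
* Defaults: burn-in 500, monitoring 5000, thin 1, single chain.
  Diagnostics (bulk ESS, split-chain R-hat, MCSE = sd/sqrt(ESS)) are
  computed via ArviZ and flag constant or non-converged chains.

With the diffuse Inv-Gamma(0.001, 0.001) prior and a single group per
level the posterior mean of a variance component does not exist (posterior
shape < 1); the oracle-comparison tests therefore use a proper
Inv-Gamma(2, 0.5) prior on tiny instances, under which the variances can
be marginalised analytically to Student-t priors and the exact 4-dim
posterior integrated by adaptive tensor-grid quadrature.

## From posterior to district prevalence

"Precision-weighted" cluster estimates are the posterior-mean residuals:
shrinkage toward zero in proportion to each cluster's sampling
imprecision is exactly what the posterior mean of a random intercept does.
The default cluster prediction is the plug-in

```
p_hat_jkl = ilogit(mean(beta0) + mean(u_jkl) + mean(v_kl) + mean(f_l))
```

matching the tradition of the software this workflow follows; a fully
Bayesian alternative (`mode="draws"`, the average of per-draw inverse
logits) is implemented and agrees within 0.5 pp whenever the posterior is
concentrated. The choice is logged. District prevalence is the simple
unweighted mean of member-cluster probabilities, in percent — clusters
count equally regardless of size.

Distribution summaries (median, quartiles, IQR, 1.5×IQR fences) use
linear interpolation between order statistics; the quartile convention is
stated because IQR comparisons depend on it.

## Change analytics

Change is wave-2 minus wave-1 prevalence in percentage points, per
district, over the shared (post-crosswalk) district frame. Banding uses
the ±2.49 pp thresholds with an inclusive middle band ("stable" iff
−2.49 ≤ change ≤ 2.49). The quadrant analysis crosses baseline position —
above or below the *unweighted mean* of wave-1 district prevalences — with
the sign of change. Exact-zero changes and exactly-average baselines are
tallied separately instead of being silently assigned to a side: published
analyses of this kind are not always internally consistent about ties, so
this package reports complete tallies and lets the reader do the
bookkeeping.

Cross-outcome association is the Pearson correlation (Spearman optional)
of district prevalences over shared districts.

## The synthetic survey generator

The generator is first-class, tested code: it is the package's test bed
for every downstream stage, with known ground truth.

* **Frame** — configurable states × districts/state × clusters/district;
  cluster target sizes from a log-normal size measure truncated to
  [10, 60] persons (mean 30 by default), mimicking the unbalanced cluster
  sizes a PPS design produces. Defaults (15 × 8 × 10 × ~30 ≈ 36,000
  persons) are the reference design used for recovery experiments — large
  enough that every variance component is identified, small enough to fit
  in about a minute per chain on one core.
* **Truth** — beta0 = (−2.2, −2.0) per wave (≈ 10% and 12% baseline
  prevalence), sigma2_u = 0.30, sigma2_v = 0.20, sigma2_f = 0.10, on the
  log-odds scale: cluster variation largest, state variation smallest, as
  is typical for health outcomes in large federal surveys.
* **Individuals** — ages uniform on [15, 49]; sampling weights log-normal
  with mean 1 (weights only enter descriptive prevalences); sex is a
  config-level stratum since fits are sex-stratified.
* **Biomarker mode** — latent SBP ~ N(118, 12²) and DBP correlated 0.7,
  three readings each with independent 4 mmHg device noise and a +3 mmHg
  first-reading elevation; glucose log-normal (median 110 mg/dL,
  log-sd 0.3). Each person's latent means are shifted so that the WHO
  classification probability equals the model probability: the glucose
  shift is closed-form, the joint SBP/DBP threshold-crossing equation is
  inverted once on a dense grid of the bivariate-normal exceedance
  probability. Calibration is checked to Monte-Carlo accuracy over 10^5
  persons. Binary mode (direct Bernoulli draws) is the fast default.
  Calibration targets the default reading-combination rule.
* **Two waves** — fresh clusters, effects and persons per wave; a
  configurable fraction of districts is split in two for wave 2, and the
  emitted crosswalk maps every cluster of both waves to the wave-2
  (target) district frame, mirroring real inter-round boundary changes.

What the generator does *not* emulate: informative missingness, household
rosters, realistic weight construction, spatial autocorrelation between
neighbouring districts, and any realistic joint distribution of SBP, DBP
and glucose (the marginals are stipulated). Passing tests therefore show
the estimator recovers the generating process of this model family; they
do not validate the model against real survey behaviour such as
informative nonresponse.

## Numerical choices

* PG draws use one fresh sub-seed per iteration drawn from the chain's
  generator; everything descends from a single configured seed.
* Degenerate PG draws (non-finite or non-positive) are retried once, then
  raise.
* The weighted-prevalence CI uses first-stage PSU linearisation of the
  ratio estimator with the n/(n−1) small-sample factor, normal quantiles,
  clamped to [0, 100]; degenerate all-0/all-1 inputs return a zero-width
  interval at the boundary.
* The pipeline derives per-cell seeds from the global seed by
  `SeedSequence` spawning in fixed cell order, so cells are independent
  but the manifest (global seed + config hash) reproduces any cell alone.

## Known limitations

* With only 15 states, the state-level variance posterior is governed by
  the realized spread of 15 effects (a chi-square with 14 df on the truth
  scale): its posterior mean legitimately fluctuates by a factor of ~2
  between replicate surveys, and summaries of sigma2_f recovery at a
  handful of replicates inherit that volatility. Cluster- and
  district-level variances, with hundreds of groups, are far tighter.

* Single-chain defaults mean split-chain R-hat is computed on chain
  halves; multi-chain diagnostics require explicitly running extra chains.
* No district-level uncertainty intervals are reported by default (point
  prevalences only, matching the downstream use); the draws are exposed
  for callers who want them.
* Self-reported medication or diagnosis is deliberately not part of the
  outcome definitions; prevalence is purely biomarker-based and will
  undercount treated, controlled cases.
* The crosswalk is consumed as given; no population-weighted apportionment
  of clusters in split districts is attempted.
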