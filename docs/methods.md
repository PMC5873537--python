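# Methods

## The model

Each prognostic group *g* gets its own multivariate generalised linear
mixed model over the R markers. Marker *r*'s observations follow an
exponential-family distribution with canonical link — identity for
Gaussian (with residual SD φ_r), log for Poisson, logit for Bernoulli —
and linear predictor x'α_r + z'b. The random-effects vector **b**
(dimension q, one intercept and optionally one slope per marker) is shared
across markers and follows a mixture of multivariate normals; density
evaluation supports any number of components, while fitting and
random-effects estimation are restricted to the single-component case used
throughout the simulation studies.

Identifiability note: a marker's "intercept" and "slope" population
effects are carried by the random-effect means μ rather than by separate
fixed coefficients (a fixed intercept next to a random-intercept mean
would be redundant); α_r holds only terms with no random counterpart, here
the Bernoulli marker's fixed time slope. Recovery tables therefore label
both kinds uniformly as `E[marker:term]`.

Model time is in **months**. Simulated visit days are converted with
months = days × 12/365.25 (`loda.MONTHS_PER_DAY`); the conversion factor
is a scenario field, so 1/30 or 1/30.44 conventions can be configured.

## Predictive densities

* **Marginal**: for all-Gaussian single-component models the integral over
  **b** is exact — y ~ N(Xα + Zμ, Z D Z' + Σ_resid), evaluated per patient
  by Cholesky factorisation. Otherwise it is a Monte Carlo average of the
  conditional density over draws from the random-effects distribution
  (default 500 draws; 300 in the study's fast profile), computed in log
  space with log-sum-exp, reusing the same standard-normal variates for
  every group within one MCMC draw (common random numbers reduce the
  variance of the probability contrasts). A delta-method standard error of
  the log density is available.
* **Conditional** and **random-effects**: both need a patient- and
  group-specific estimate b̂ of the random effects, re-estimated under each
  retained draw of each group's parameters. For all-Gaussian models b̂ is
  the exact posterior mean μ + D Z' V⁻¹ (y − Xα − Zμ). With non-Gaussian
  markers the posterior mean has no closed form; we use the posterior
  mode found by damped Newton iteration (Laplace estimate) as the mean
  surrogate. The target is strictly log-concave for these families, so the
  iteration is reliable; for all-Gaussian models mode and mean coincide,
  where we verify the two paths agree to solver tolerance.

Per-draw group probabilities combine a predictive density with the prior
group proportions by Bayes' rule in log space; the reported probability is
the average of the per-draw probabilities (an average of ratios, matching
the estimator the probability constructions define), over all retained
draws or an evenly spaced subset (default 100 in study runs — the
per-draw probabilities vary little across draws, so a subset adds
negligible Monte Carlo error at a tenth of the cost).

## MCMC sampler

One iteration updates, in order:

1. **b, Gaussian coordinates** — exact multivariate-normal conditional
   draw per patient (vectorised over patients), conditioning on the
   non-Gaussian coordinates through the prior precision.
2. **b, non-Gaussian coordinates** — one block per marker: an
   *independence* Metropolis–Hastings step proposing from a normal
   approximation at the Newton mode of the block's conditional posterior
   (4 Newton steps from the conditional prior mean; proposal covariance
   inflated ×1.3 for tail coverage). Acceptance rates are ~0.9. A local
   random walk was tried first and mixes far too slowly at desk-scale
   chain lengths for weakly informed binary random effects: its draws hug
   the conditional mean given the other coordinates, inflating the
   estimated cross-correlations and collapsing the block's variance.
3. **Fixed coefficients** — conjugate normal draws for Gaussian markers;
   adaptive random-walk Metropolis (target acceptance 0.35, adaptation
   during burn-in only) for non-Gaussian markers.
4. **Residual precisions** — conjugate gamma draws.
5. **μ** — conjugate normal draw given the b's.
6. **D** — conjugate inverse-Wishart draw, followed by the scale-mixture
   update of the Huang–Wand prior (below).
7. **Scale moves** — for each coordinate *k*, a Metropolis move that
   rescales the deviations b_k − μ_k of all patients and D's k-th
   row/column by a common factor. The normal-prior terms and the
   b-Jacobian cancel analytically, leaving the marker likelihood, the
   inverse-Wishart prior ratio and a residual Jacobian. This traverses the
   variance direction of the hierarchy, which an update-b-then-update-D
   scan moves along only slowly.

**Priors.** N(0, 10⁴) on every mean-type coefficient (μ and α);
Gamma(1, 0.005) on residual precisions; the Huang–Wand hierarchical prior
on D: D | a ~ inverse-Wishart(ν+q−1, 2ν·diag(1/a_k)), a_k ~
inverse-gamma(½, 1/A²) with ν = 2 and A = 10, giving each random-effect SD
a marginal half-t(2) prior with scale 10 and the correlations a uniform
marginal. The hierarchical form matters here: the random-effect scales in
these models span five orders of magnitude (slope SDs ~10⁻³, a binary
random-intercept SD ~2), so any fixed scalar inverse-Wishart scale either
dominates the small variances or — if made small — loses its degeneracy
barrier, at which point the det(D)^{-(ν+q+1)/2} factor concentrates
posterior mass on |corr| → 1 and collapses weakly informed variances. We
confirmed this failure mode (and the Huang–Wand fix) against a brute-force
posterior for a small Gaussian+Bernoulli model computed by exact Gaussian
integration, 1-D quadrature and long-run random-walk MH.

**Initialisation.** Per-patient crude link-scale estimates (patient means,
log-means, smoothed logits; per-patient least-squares slopes), with μ and
D started at their empirical mean and covariance. Starting the hierarchy
at the data's own spread avoids a sticky near-degenerate state for the
binary marker's variance.

**Chain profiles.** `full`: burn-in 500, 1:10 thinning, 10,000 retained
(100,500 iterations; cluster-scale). `fast`: burn-in 200, 1:2 thinning, 1,000 retained; one Scenario-1
group fit takes ~10 s. The desk-scale studies below use `fast`.

## Synthetic scenarios

Two presets ship as YAML (`loda/presets/`), with 200 good-prognosis and 50
poor-prognosis patients and four visits per patient: day 0 plus uniform
draws in (170, 200), (350, 390) and (710, 770) days.

* **scenario1** — albumin and log-bilirubin (Gaussian, random intercept +
  slope), platelet count (Poisson, random intercept + slope), blood-vessel
  malformation (Bernoulli, random intercept + fixed slope); q = 7. The
  groups differ in mean profiles and share one covariance D (all 21
  pairwise correlations specified; the assembled matrix is verified
  positive definite).
* **scenario2** — the two Gaussian markers only (q = 4); the groups share
  means and D and differ solely in residual SDs (0.314/0.395 vs
  0.159/0.169). Correlations not listed for this reduced model are zero.
  Correlations involving the Bernoulli marker attach to its random
  intercept (its slope is fixed).

The generator draws visit days as continuous uniforms, one b per patient,
then family-distributed observations; identical seeds give byte-identical
datasets. It emulates the study design only: no dropout or missed visits,
identical visit times across markers within a patient, no covariates
beyond time. Passing tests therefore demonstrate correctness of the
method under a correctly specified model, not robustness to the
missingness and irregular sampling of real cohorts.

## Cross-validation and the study runner

`loocv_predict` offers *exact* leave-one-out (refit the held-out patient's
group without them, for every patient) and *fit_once* (each group fitted
once on all its patients). The study runner's default is fit_once: the
leave-one-out perturbation of a 200-patient fit is O(1/n), and exact LOOCV
multiplies the fitting cost by the cohort size. Priors π are the training
group proportions (0.8, 0.2). Per replicate, each approach's cutoff is
chosen on that replicate's own ROC (closest point to the top-left corner,
Euclidean distance, ties to the smaller cutoff) and the accuracy measures
are averaged across replicates; per-replicate tables are retained, and a
pooled fixed-cutoff averaging can be derived from them. Replicate seeds
are spawned from the master seed; per-replicate results are cached as CSV
and reloaded on re-runs; failed replicates are logged and skipped, with
more than 20% failures aborting the study.

**Desk-scale study sizes** (the package's default profile): 12 replicates
for the Gaussian-only scenario, 5 for the four-marker scenario, fast MCMC
profile, 300 Monte Carlo draws for marginal integration, probabilities
averaged over 100 retained draws. At these sizes the full acceptance
recomputation runs in a few minutes on one CPU; the `full` profile scales
the study up (100 replicates, 10,000 retained draws, exact LOOCV) for
cluster use.

## Numerical conventions

* All density work in log space; mixture and normalisation sums via
  log-sum-exp.
* Covariance factorisations add a 10⁻¹⁰ diagonal ridge, so degenerate
  (zero-variance) limits are handled as tolerances rather than errors.
* ROC semantics: positive iff score **strictly** exceeds the cutoff;
  thresholds at every distinct score plus ±∞ sentinels. Trapezoidal AUC
  on this grid equals the Mann–Whitney concordance with ties counted
  half (asserted exactly in tests, and cross-checked against
  scikit-learn).
* Argmax classification breaks ties toward the lower group index.
  Undefined PPV/NPV denominators yield NaN, not 0.
* HPD intervals are the shortest window containing the requested mass of
  the sorted draws.

## Known limitations

* Random-effects estimation (hence conditional and random-effects
  prediction) requires a single-component random-effects distribution;
  mixture fitting with K > 1 is out of scope, as is dynamic re-prediction
  as new visits arrive.
* The across-replicate "SD" of a parameter can be read two ways (average
  posterior SD vs SD of posterior means); recovery tables report the SD
  of posterior means across replicates, and posterior summaries carry the
  within-fit posterior SD separately.
* Random-slope SDs are systematically under-estimated with poor coverage
  at these study sizes — the true slope variability is small relative to
  the residual error and four visits per patient carry little information
  about it. This is a property of the study design; the recovery tables
  make it visible rather than hiding it.
* In the four-marker scenario the random-effects AUC sits close to the
  marginal AUC at these study sizes; the AUC ordering across approaches
  is preserved, but the marginal-vs-random gap is small relative to
  replicate-to-replicate variation, so orderings from a handful of
  replicates should be read with care.
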