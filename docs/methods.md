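# Methods

## Model

Samples are partitioned into q groups (subpopulations, clusters, breeds).
For sample i in group k, with standardized dosages x_kij over p markers,

    y_ki = mu_k + sum_j x_kij (b0_j + bk_j) + e_ki,   e_ki ~ N(0, sigma2_k).

The marker effect experienced by group k is beta_kj = b0_j + bk_j: a main
component b0_j common to all groups plus a group-specific deviation bk_j.
Three analysis modes share this machinery:

* **across** — all bk_j = 0: one effect set for the pooled sample;
* **stratified** — b0_j = 0: independent effect sets per group, no borrowing
  of information between groups;
* **interaction** — both components; the main-effect variance controls how
  much information is shared.

Group intercepts mu_k have flat priors.  Residual variances sigma2_k have
scaled-inverse-chi-square priors chi^-2(S_k, df_k), one per group, so model
fit can differ between groups.  Effect blocks (the main block and each
deviation block) are assigned independent priors per term:

* **BRR** — b_j ~ N(0, sigma2_term) iid within the block, with
  sigma2_term ~ chi^-2(S_term, df_term);
* **BayesB** — beta_j = delta_j b_j with delta_j ~ Bernoulli(pi),
  b_j | sigma2_j ~ N(0, sigma2_j), sigma2_j ~ chi^-2(S_term, df_m); the
  marker df_m is fixed at 5, the common scale S_term gets a Gamma(shape,
  rate) hyperprior and pi a Beta(pi_a, pi_b) prior.  Marginally the slab is
  a scaled-t, so the prior is a spike-slab with heavy-tailed slab.

Because the deviations are independent across groups, the implied covariance
of total effects between any two groups equals Var(b0); consequently

    Cor(beta_j, beta_j') = Var(b0) / sqrt((Var(b0)+Var(b_j)) (Var(b0)+Var(b_j')))

is non-negative and, for q > 2, shares one numerator across all pairs.  This
is a structural assumption of the model, appropriate when between-group
covariances are believed positive and similar across pairs.

## Gibbs sampler

One scan updates, in this fixed order: intercepts; each effect block in
layout order (main first), markers in index order, by single-site updates;
block-level prior parameters; residual variances.  Full conditionals:

* mu_k ~ N(mean of group-k residual + mu_k, sigma2_k / n_k);
* BRR coefficient: Gaussian with precision c = sum_k x_kj' x_kj / sigma2_k
  + 1 / sigma2_term.  For the main block the sum runs over all groups
  (a precision-weighted least-squares coordinate step); for a deviation block
  only that group's rows contribute;
* BayesB marker: the inclusion indicator is drawn from its Bernoulli
  conditional with the effect integrated out given sigma2_j — the log Bayes
  factor is -log(1+v c0)/2 + v rhs0^2 / (2 (1+v c0)) with the effect removed
  from the residual — then, if included, the effect is drawn from its
  Gaussian conditional, else set to zero; sigma2_j is refreshed from
  chi^-2(df_m + delta_j, (S_term df_m + beta_j^2)/(df_m + delta_j));
* sigma2_term (BRR): chi^-2(df + p, (S df + sum_j b_j^2)/(df + p));
* S_term (BayesB): Gamma(shape + p df_m / 2, rate + (df_m/2) sum_j 1/sigma2_j);
  pi: Beta(pi_a + #included, pi_b + p - #included);
* sigma2_k: chi^-2(df_k + n_k, (S_k df_k + SSE_k)/(df_k + n_k)) from group-k
  residuals only.

The residual vector is maintained incrementally and recomputed from scratch
every 1000 iterations; drift beyond 1e-8 is logged.  Non-finite residuals
abort the run with the iteration index.  All randomness is pre-generated per
sweep from one `numpy.random.Generator` seeded by the configuration, so a
fixed seed yields a bit-identical chain; the inner loops are numba-compiled
but consume only those pre-generated draws.

Defaults: 15,000 iterations, 5,000 burn-in, thinning 5.  These are
conventional run lengths for single-site samplers at these model sizes;
cross-validation loops typically use shorter chains (the `examples/` scripts
use 1,500–6,000 iterations).

## Default hyperparameters (variance budgeting)

Half of the average within-group phenotypic variance is assigned a priori to
the residual and half to the genomic terms, the genomic share split equally
across blocks (main + q deviations in interaction mode).  Scales are set so
the prior *mode* matches the budgeted value: S = mode (df+2)/df with df = 5
throughout.  For BayesB the slab scale is budgeted through
E[beta^2] = S df/(df-2) at prior inclusion 0.5, with a Gamma(1.1, rate)
hyperprior whose mode sits at the budgeted scale, and pi ~ Beta(5, 5)
(prior mean 0.5, weight of ten observations).  All of this is overridable;
`fit` echoes the fully resolved configuration in its summary, and the CLI
writes it next to the outputs.

## Standardization and the genomic-variance scale

Markers are centered and scaled to unit sample variance (n-1 divisor) across
the *whole* sample — never within group — so between-group allele-frequency
differences remain visible to the model.  Consequently trace(G) = n-1 for
G = W W' / p.  Variance parameters are per-marker; summaries report
genvar = p * sigma2_term, the block's genomic variance on the scale of the
phenotypes, and the generator draws effects so that its var_main / var_int
arguments are exactly such genomic variances.  Ratios (shares, correlations)
are invariant to this factor.

Monomorphic markers cannot be standardized and are dropped with a warning.
Missing dosages are never imputed silently; marker-mean imputation is an
explicit reader option.

## Variance decomposition estimators

`decompose` reports each summary twice: as a plug-in ratio of posterior-mean
variance components and as the posterior mean of the per-draw ratio (with a
posterior SD).  The two agree on well-identified fits; the per-draw version
propagates posterior uncertainty and is preferable for intervals.  For BayesB
fits the genomic variance of a block is computed per draw as the sum of
squared sampled effects, which is the natural analogue on standardized,
(near-)independent markers.

## Preprocessing choices

* PCA is the eigendecomposition of the GRM; scores are eigenvectors scaled by
  the square root of their eigenvalues, and explained proportions are
  eigenvalue ratios.  Tiny negative eigenvalues from round-off are clipped.
* Marker pruning is greedy in input order: a marker is kept iff its absolute
  Pearson correlation with every already-kept marker is below the threshold.
  The greedy order is a convention; it makes the result deterministic.
* Clustering is k-means on the leading PC scores (default two, matching how
  structure is usually visualized), ten restarts with a fixed seed, groups
  relabeled so group 1 is largest (ties broken by the lowest original
  label).  This is a pragmatic stand-in for dedicated admixture-model
  clustering: any externally derived labels can be supplied as a
  `GroupAssignment`, which is the recommended route when reproducing an
  analysis whose clustering came from a specific published method.

## Evaluation choices

* Training-testing partitions hold out a fixed count per group, sampled
  without replacement, reproducibly from a seed.  Accuracy is the
  within-group Pearson correlation between held-out phenotypes and
  predictions from posterior-mean effects (point predictions, not the full
  posterior predictive, matching standard practice).  Undefined correlations
  (zero-variance cells) are recorded as missing and excluded from means.
* The ridge permutation diagnostic estimates marker effects per group by
  penalized least squares (own intercept per group) and correlates the two
  effect vectors.  The default penalty is p (1-h2)/h2 with h2 = 0.5 on
  standardized markers, i.e. lambda = p.  Permutations re-shuffle only the
  group labels; phenotypes and genotypes stay attached to their samples.
  The reported p-value is add-one corrected.

## Synthetic-data generator

The generator emulates the salient features of a structured breeding
population: ancestral allele frequencies Uniform(0.1, 0.9); group
frequencies drawn from a Beta distribution centered on the ancestral value
with spread set by a differentiation coefficient F (a Balding–Nichols-style
drift model; F = 0.2–0.3 produces many markers whose frequencies differ by
more than 0.2 between groups, as seen in strongly structured panels);
binomial dosages (Bernoulli in inbred mode, frequencies clamped to
[0.01, 0.99]); effects drawn on a shared support so that each term's total
genomic variance equals its budget, with an optional disjoint-support mode to
probe misspecification; Gaussian noise with group-specific variances.

What it does **not** emulate: linkage disequilibrium (markers are
independent), admixed/continuous ancestry (groups are discrete), pedigree
structure, non-Gaussian phenotypes, and shared environments.  Tests passing
on this generator therefore validate the statistical machinery under the
model's own assumptions; they do not certify behavior under LD-driven
phenomena such as between-group differences in marker-QTL phase.

## Validation problem sizes

The test suite validates the sampler against independent oracles at sizes
chosen to make each check informative while keeping the suite quick:
conjugate closed form at n = 40 with no markers; spike-slab inclusion odds
against quadrature at n = 5, one marker; BLUP equivalence (all variances
pinned) at n = 200, p = 100; parameter recovery at n = 1000 per group,
p = 300, 15,000 iterations (residual variances within 15%, effect
correlation within 0.15); directional accuracy patterns at 10 partitions
with true effect correlations 0.9 and 0.1; permutation pipeline with 200
permutations.  The zero-interaction collapse check uses n = 1500 per group
with p = 60 because the posterior of an interaction variance has an
estimation-noise floor of roughly p sigma2 / n_k, which must sit well below
the main-effect variance for the collapse to be visible.

## Known limitations

* Between-group covariances of effects are non-negative by construction and
  constant across pairs for q > 2; strongly negative or heterogeneous
  covariance patterns call for a multivariate model instead.
* No additional fixed covariates or experimental-design effects in v1.
* Priors beyond BRR and BayesB (Bayesian lasso, BayesA, BayesC) are not
  implemented.
* The number of effects grows as p (q+1); very large panels with many groups
  will be slow under single-site sampling.
* File I/O is dosage-matrix text only (no PLINK/VCF parsing in v1).
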