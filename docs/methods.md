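# Methods

## The common-factor model

Observed variables are modeled as linear combinations of k unobserved
factors plus variable-specific noise:

    x_iv ≈ Σ_f l_vf F_fi + ε_iv,   ε_iv ~ N(0, ψ_v),

so the population covariance of standardized variables is
Σ = LL′ + U², with L the variables × factors loading matrix and
U² = diag(ψ) the uniquenesses. On z-scored data, communality plus
uniqueness is 1 per variable. Factors are taken orthogonal; scores are
i.i.d. standard normal in the generator (the noise is Gaussian by
model assumption; the factor distribution is a modeling choice — the
simplest one consistent with ML estimation).

### Estimation

`fit_ml_factors` minimizes the ML discrepancy

    E = ½ · tr(((S − Σ) Σ⁻¹)²)

in two stages. Stage one is the classical Lawley–Maxwell profile
device: optimize the canonical ML fit function over uniquenesses only,
with conditionally optimal loadings from the top-k eigenpairs of
U⁻¹SU⁻¹ (L-BFGS-B with the standard analytic gradient
diag(LL′ + U² − S)/ψ²). Stage two polishes all parameters
(loadings and log-uniquenesses) by L-BFGS on E itself with its analytic
gradient, so the returned solution is a stationary point of the
discrepancy above; tests verify a general-purpose simplex optimizer
cannot improve it. The contract is the discrepancy value, not the
optimizer path.

Numerical choices:

- **Heywood guard**: uniquenesses are bounded below at 0.005; hitting
  the floor raises a warning.
- **Degenerate no-shared-variance inputs** (S effectively diagonal):
  the split of a variable's variance between a single-indicator
  loading and its uniqueness is unidentified (both give E = 0), so the
  null solution (L = 0, U² = diag S) is returned.
- **Sign and order**: factors are sorted by decreasing EV_f = Σ_v l²_vf
  and each factor's sign is set so its largest-magnitude loading is
  positive; the sign of a factor is otherwise arbitrary.
- **Varimax** uses the SVD iteration without Kaiser row-normalization
  by default (flag available). Row communalities are preserved to
  1e-10; rotation never changes the reconstructed Σ.
- **Bartlett scores**: W = U⁻²L(L′U⁻²L)⁻¹, the unbiased
  weighted-least-squares estimator; requires strictly positive
  uniquenesses and a nonsingular L′U⁻²L.

## Model selection

Three criteria are computed per k and combined into a tidy report;
the final choice of k is deliberately left to the analyst.

- **Parallel analysis** (default 20 repetitions) compares
  correlation-matrix eigenvalues of the data with their means over
  i.i.d. N(0,1) matrices of identical shape; the crossover is the
  number of leading factors whose value exceeds the noise mean. A
  variant (`method="ml"`) refits the ML model per candidate k on real
  and null data and compares per-factor squared-loading sums; it is
  systematically more liberal, because surplus factors that split a
  correlated block retain sizable shared variance, so its crossover
  bounds the dimensionality from above rather than pinpointing it.
  The eigenvalue comparison is the default for that reason. Note that
  for pure-noise data the real and null spectra are exchangeable, so
  the crossover of a single noise dataset is a coin-flip run length;
  only its distribution across datasets concentrates near zero.
- **Robustness** (defaults: 1000 iterations, 80% of subjects drawn
  without replacement): factors re-extracted per subsample are aligned
  to the full-data solution at the same k by the Hungarian assignment
  with cost 1 − |corr| (the full-data solution is the alignment
  reference; the choice of reference only relabels columns). The
  statistic per (k, factor) is the mean absolute Pearson correlation
  of the loading vector over all subsample pairs.
- **Interpretability**: a factor passes with ≥ 3 variables at
  |loading| > 0.4. Absolute loadings are used since factor signs are
  arbitrary.

## Factor hierarchy

Solutions at k = 1..k_max are levels; Bartlett scores are correlated
between consecutive levels and |r| is the flow of variance from parent
to child. Edges are not thresholded; weights live in [0, 1] and are
invariant to factor sign flips. Non-converged levels are flagged and
their edges omitted.

## Consensus clustering

Variables are clustered as points in subject space (columns of the
standardized matrix; a correlation-profile feature space is available
by flag). Defaults follow the reference procedure: 80% of variables
per subsample, 1000 iterations, K-means with 10 centroid restarts.
The consensus index of a pair is its co-clustering count divided by
its co-sampling count; the diagonal is 1.

Diagnostics per K (upper triangle only; the diagonal would only add a
constant mass at 1):

- **CDF and AUC**: the AUC is the exact area under the right-continuous
  empirical CDF over [0, 1] (a left step sum), e.g. 0.5 when indices
  split evenly between 0 and 1. It stabilizes from the true cluster
  count onwards.
- **ΔAUC**: relative change to the next K by default; absolute by flag.
- **Cluster consensus**: mean index over within-cluster pairs;
  singletons are defined as 1 with a warning.
- **Consensus score**: CS = mean(indices > 1/K) − mean(indices ≤ 1/K).
  Ties at exactly chance fall in the lower bin (configurable); an
  empty bin contributes 0. CS ≈ 0 when co-clustering is random and 1
  for perfect consensus; it peaks at the planted cluster count on
  block-structured data.

Final labels come from K-means on the rows of the consensus matrix
(each variable's consensus profile). Partition agreement uses the
adjusted Rand index and adjusted mutual information (permutation-model
expectation, max-entropy normalization), delegated to scikit-learn and
cross-checked in the test suite against exhaustive-enumeration oracles
over all partitions of up to six items.

## Confirmatory factor analysis

The pattern fixes which loadings are free — by default those with
|loading| > 0.45 in the rotated exploratory solution; variables with
no free loading are dropped from the model. Factor variances are fixed
to 1; factor covariances are free by default (standard practice when
identifying the scale through the variances; an orthogonality flag
exists). Residual variances are free and log-parameterized.

Estimation minimizes F_ML = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p by L-BFGS-B
with the analytic gradient Σ⁻¹(Σ − S)Σ⁻¹ mapped to each parameter
block; χ² = (n − 1)·F_ML (an n multiplier is available). The
independence baseline has χ²_B = (n − 1)(ln|diag S| − ln|S|),
df_B = p(p−1)/2. Indices:

- CFI = 1 − max(χ²_M − df_M, 0) / max(χ²_B − df_B, χ²_M − df_M, 0)
- TLI = ((χ²_B/df_B) − (χ²_M/df_M)) / ((χ²_B/df_B) − 1), truncated at 1
- RMSEA = √(max(χ²_M − df_M, 0) / (df_M (n − 1))) — the parsimony
  correction; its 90% CI inverts the noncentral χ² CDF at 0.95/0.05 by
  root-finding on λ ∈ [0, 10χ²]
- SRMR = RMS of the standardized residuals (S − Σ̂)_ij / √(S_ii S_jj)
  over the p(p+1)/2 unique elements.

Standard errors (optional) come from a finite-difference Hessian of
F_ML, acov = (2/(n−1))H⁻¹, with the delta method for the
log-parameterized residuals. Non-convergence is reported on the fit
object, never raised.

## Synthetic data: what it emulates, and what it does not

The generator emulates the structural features the pipeline depends
on: block-structured loadings with configurable strength and jitter,
unit-variance variables, linear age (integer-uniform 22–37) and gender
(Bernoulli 0.5) confound effects, MCAR missingness capped strictly
below the 10% inclusion threshold, and family groupings (a seeded mix
of singletons, pairs and triples) for the splitter. It does **not**
emulate ordinal or bounded response scales, floor/ceiling effects,
non-Gaussian heavy tails, informative missingness, or correlated
factors — so passing tests demonstrate correctness of the machinery
and recoverability under the stated model, not performance on any
particular real battery.

## Preprocessing details

- Inversion of error measures is a sign flip (−x), which preserves the
  correlation magnitudes the factor model consumes and is an
  involution; a reciprocal variant is available by flag.
- The |r| > 0.1 selection screen uses pairwise-complete correlations
  and runs before imputation (a post-imputation screen is a config
  switch).
- Chained imputation produces a single completed dataset with
  posterior-draw noise (default 10 iterations, seeded); analyses
  proceed on one completed set per subset rather than pooling.
- The family split assigns whole families greedily by descending size
  to the currently smaller subset, with seeded tie-breaking; a family
  holding over half the subjects triggers a warning and a best-effort
  balance.
- z-scoring uses the n−1 denominator.

## Problem sizes in the test and acceptance runs

Simulated studies use 300–800 subjects and 24–40 variables, with
robustness at 100 subsample iterations and consensus at 200 — large
enough that recovery targets (congruence > 0.95, consensus indices at
0/1, ARI = 1) are stable across seeds, while a full suite run stays in
the minutes range. The procedure defaults (1000/1000/20/10) remain the
package defaults.

## Known limitations

- Only orthogonal (varimax) rotation is provided; oblique structures
  are approximated by correlated-factor CFA, not by oblique EFA.
- The ML-EFA objective is nonconvex; multi-start behavior beyond the
  profile-likelihood initialization is not implemented. On symmetric
  two-block structures a one-factor solution may legitimately tilt
  toward one block (a property of ML factor analysis, not a bug).
- CFA assumes complete, continuous, roughly multivariate-normal input;
  there are no robust or weighted-least-squares estimators.
- Parallel-analysis crossover on noise is a run-length statistic with
  a heavy right tail for single datasets (see above).
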