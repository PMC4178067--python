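# Methods

## The problem

Complex diseases are usually measured as a cluster of correlated traits, and
the genetic factors behind them often act through gene–gene (epistatic) or
gene–environment interactions whose single-locus marginal effects are too
small for one-SNP-at-a-time scans.  Multifactor dimensionality reduction
(MDR) attacks the interaction problem combinatorially: a subset of m loci
spans a 3^m-cell genotype table, each cell is labelled high- or low-risk, and
the pooled two-group attribute is scored by its classification accuracy under
cross-validation.  Generalized MDR (GMDR) replaces case/control status with a
model-based score residual, which admits quantitative traits and covariate
adjustment; the multivariate extension implemented here drives the same
kernel with a *joint* score over several correlated traits, estimated by
generalized estimating equations (GEE), so that pleiotropic interactions can
borrow strength across traits.

## Null model and score residuals

Let y_i = (y_i1, …, y_iJ) be the J trait values of individual i.  The null
model omits all target (interaction) effects: each trait gets its own
intercept and covariate coefficients through a link g(mu) = X beta, with a
variance function V(mu) and dispersion phi.  Three estimation routes share
this structure:

* **GLM** (`family=gaussian|binomial`): maximum likelihood per trait.  The
  gaussian-identity route is solved by ordinary least squares; others by
  IRLS (via statsmodels).
* **QLM** (`family=quasi`): only the link and the mean–variance relation are
  specified; the fit maximizes the corresponding quasi-likelihood.
* **GEE** (`working_correlation=exchangeable|unstructured`): each individual
  is one cluster of J trait components; Liang–Zeger estimating equations are
  iterated with moment estimation of the working-correlation parameter(s)
  and phi (statsmodels `GEE`).  With `independence` (or J = 1) the solution
  coincides with the GLM, which is fitted directly.

Dispersion is always the moment estimator phi = sum(r^2)/(N − q) from Pearson
residuals r with q estimated mean parameters — never ML.

The score residual of component j is t_ij = (y_ij − mu_ij) / sqrt(phi ·
V(mu_ij)).  For GEE fits the per-cluster residual vector is whitened by the
symmetric inverse square root of the fitted working correlation, R^(−1/2), a
fixed convention adopted where the choice of standardizing matrix is
otherwise open.  The per-individual score is the sum of the J components
(`aggregation=sum`, default) or their mean.  At the default threshold T = 0
the two differ by the positive factor 1/J, so cell labels, individual
high/low values and every accuracy metric are identical under either choice.

## The dimensionality-reduction kernel

Given a factor subset of size m, every individual with complete genotypes on
the subset occupies one cell of the 3^m table (base-3 coding of the additive
genotype codes); individuals missing any subset locus are excluded from that
subset's table rather than imputed.  A non-empty cell is *high-valued* iff
the mean score of its members is ≥ T ("not less than" — a mean exactly at T
is high); empty cells never join either pooled group.  An individual's own
value is high iff its score ≥ T, the same boundary convention.

Classification quality is measured by one of four criteria
(`accuracy_metric`):

* `weighted` (default): each individual contributes its score mass
  |score − T|; the criterion is the correctly classified fraction of total
  mass.  For unit-magnitude scores (case/control ±1) this reduces exactly to
  the plain proportion.  This is the criterion under which the package
  reproduces the benchmark table; count-based accuracy provably
  cannot — its infinite-sample ceiling at the true digenic model under the
  benchmark generative model is 0.612 (multivariate) and 0.580 (univariate),
  below the benchmark means of 0.665 and 0.617, whereas the weighted
  criterion's ceilings (0.671 / 0.624) bracket them from above.
* `plain`: the proportion (TP+TN)/(TP+TN+FP+FN) of correct classifications.
* `balanced`: mean of sensitivity and specificity; an arm with an empty
  denominator contributes 0.5 so degenerate folds never yield NaN.
* `score_difference`: mean score of the pooled high group minus the low
  group (selection criterion only; reported accuracies stay count-based).

Test individuals landing in cells that were empty during training follow
`unseen_cell_policy`: `low` (default — conservative toward the null) or
`exclude` (dropped from the denominators).  Measured on the benchmark
scenarios the two policies give indistinguishable CVC/TA means.

## Search and cross-validation

The data are split into k = 10 folds, stratified on the sign of the score so
each fold carries a proportional share of high- and low-valued individuals
(`stratify_folds`, optional; the benchmark means are insensitive to it).
For each model size m, every one of the C(L, m) subsets is evaluated on each
fold: cells labelled on the k−1 training parts, accuracy computed on both
partitions.  The within-fold winner maximizes the training criterion (ties:
lexicographically first subset).  The final model at a size is the modal
per-fold winner, ties broken by higher mean testing accuracy and then
lexicographic order.  Cross-validation consistency (CVC) is the number of
folds selecting the final model.

Two testing-accuracy statistics are reported: the mean held-out accuracy of
the per-fold winners, and the mean held-out accuracy of the final (modal)
subset across all folds.  The per-fold-winner mean is the headline TA: the
two coincide when CVC = 10, and exactly where CVC drops below 10 the
benchmark table's values track the winner mean (e.g. univariate 4-locus
0.528 at CVC 5.7) while the modal-subset mean overshoots them.  Across
sizes, the best size maximizes CVC, ties broken by TA.

The search kernel is vectorized: all subsets of one size are scored per fold
with a handful of `bincount` calls over offset base-3 cell indices, so a
full 4-locus search over 10 loci (210 subsets × 81 cells × 10 folds) takes
tens of milliseconds, and permutation tests with B = 1000 replicates remain
desk-scale.

## Significance

Under no association the testing accuracy of a cross-validated model
fluctuates around 0.5.  Three tests are provided: (i) an exact one-sided
sign test on the k fold-level TAs against success probability 0.5, folds at
exactly 0.5 dropped; (ii) an empirical p-value p = (r+1)/(B+1) against a
permutation null built by shuffling the aggregated score vector over
genotype rows B times and re-running the full cross-validated search — the
null-model fit stays fixed, genotype structure is preserved, and the add-one
estimator avoids zero p-values; (iii) a normal (Z) approximation using the
permutation null's mean and SD.  Bonferroni adjustment multiplies by the
number of candidate models examined, capped at 1.

## Synthetic scenarios

The generator emulates the benchmark conditions: n = 1000 individuals,
L = 10 unlinked biallelic loci under Hardy–Weinberg and linkage equilibrium
with coded-allele frequency p = 0.3 (all causal loci equi-frequent), and two
continuous traits.  The interaction models partition the multilocus
genotypes at the m causal loci by the total coded-allele count: the digenic
*antidiagonal* model (AAbb, AaBb, aaBB high) and the k-uppercase models
(exactly k coded alleles over k loci high), all of which have count = m as
the high class, so under HWE/LE the high-class frequency has the closed form
f = P(Binomial(2m, p) = m): 0.2646 / 0.18522 / 0.13614 for m = 2/3/4 at
p = 0.3.  Their single-locus marginals are small relative to the joint
effect (exactly zero at p = 0.5), which is what makes them pure-interaction
benchmarks.

Each trait is y_ij = mu_j + g_i + e_ij with the *same* two-point genetic
value g_i for every trait (equal pleiotropic control): g_i = sigma_g ·
sqrt((1−f)/f) in the high class and −sigma_g · sqrt(f/(1−f)) otherwise,
which satisfies mean zero and variance sigma_g^2 identically.  Total
phenotypic variance is normalized to 1: sigma_g^2 = h2 (default 0.05 per
trait) and the residual vector is multivariate normal with variances 1 − h2
and correlation rho (default 0; the sweep covers ±0.5).  The non-causal
loci carry no effect and act purely as search noise.

What the generator does *not* emulate: linkage disequilibrium, allele-
frequency spectra, missing genotypes, non-Gaussian trait distributions,
population structure or family relatedness.  Passing benchmarks therefore
demonstrate the machinery's correctness and calibration under idealized
sampling, not robustness to real-data artefacts; covariate adjustment and
the GEE working-correlation options are the intended handles for such data.

## Monte Carlo experiments

Per-scenario significance cutoffs are built once, from the permutation
distribution (B = 1000) of a single simulated dataset of that scenario,
matching the benchmark protocol; a pooled multi-dataset null is available as
an option.  Type I error is the fraction of R null-scenario replicates whose
selected-model TA has empirical p ≤ alpha; the Q–Q table pairs nominal
levels with these rates.  Power counts a replicate as a success when the
final model at the true size is exactly the causal subset *and* clears the
cutoff (strict, default) or regardless of identity (lenient).  Both the
across-replicate SD and the SEM (SD/sqrt(R)) of CVC and TA are emitted,
labelled, since summary tables are often ambiguous about which they print.

Problem sizes used by the shipped harnesses: the acceptance script runs
R = 500 Type I replicates per scenario (B = 1000) and R = 200 table
replicates; the test suite runs R = 500/100 and B = 1000/499 respectively.
Replicate-level seeds are spawned deterministically from the run seed, so
results are bit-identical across re-runs and independent of execution order.

## Numerical choices

* GEE convergence: statsmodels' Fisher-scoring iteration at tolerance 1e-8,
  max 100 iterations; non-convergence raises, carrying the last iterate.
* Exchangeable alpha is clipped to (−1/(J−1), 1); whitening refuses a
  non-positive-definite working correlation.
* Binomial fits with fitted probabilities at 0/1 (separation) raise rather
  than emit infinite residuals; a perfect gaussian fit (phi = 0) warns and
  returns all-zero scores.
* Fold assignment, permutations and simulations all draw from named child
  seeds (`SeedSequence([seed, tag, index])`), keeping every run replayable.
* Ties at the T boundary are always "high", one convention everywhere.

## Known limitations

* Exhaustive search scales as C(L, m); genome-wide locus counts need
  pre-filtering (the kernel chunks its workspace but does not prune).
* Binary-trait simulation and family-based designs are out of scope;
  environmental factors must be pre-discretized to at most 3 codes.
* The GEE route assumes balanced, complete trait vectors per individual.
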