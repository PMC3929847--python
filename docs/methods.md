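# Methods

## Model

The package implements the weighted Lancaster combination of n p-values,
T = Σᵢ γ⁻¹_{wᵢ/2,2}(1 − pᵢ), where the transform sends pᵢ ~ U(0,1) to a
χ²_{wᵢ} variable. Under independence T ~ χ²_{Σwᵢ} exactly; this exact
reference is always reported alongside the adjusted methods. Under
dependence only the first two moments of T are tractable:
E(T) = Σ wᵢ and Var(T) = 2Σ wᵢ + 2Σ_{i<j} ρᵢⱼ with ρᵢⱼ the covariance of
the transformed values (not of the raw p-values — the two differ by the
nonlinear transform, and all interfaces use the transformed scale).

All five tail approximations first match cT to χ²_v by Satterthwaite
(v = 2E(T)²/Var(T), c = v/E(T)). `TA` uses the matched gamma survival
function directly (v need not be an integer). `TB`–`TE` approximate the
matched chi-square tail further:

* `TB` (Fisher): √(2·cT) ≈ N(√(2v−1), 1); requires v > 1/2.
* `TC` (Wilson–Hilferty): (T/E(T))^{1/3} ≈ N(1 − 2/(9v), 2/(9v)).
* `TD` (Cornish–Fisher): the five-term chi-square quantile expansion in
  x = Φ⁻¹(α), inverted for the observed cT by monotone bisection on
  x ∈ [−8, 8] (tolerance 1e−10, ~200 iterations); out-of-bracket values
  clamp the p-value to 0 or 1, and T = 0 returns exactly 1.
* `TE` (Lugannani–Rice saddlepoint): Y = T/E(T) is treated as the mean of v
  χ²₁-type components with component CGF K(t) = −½log(1−2t) and saddlepoint
  t_y = (y−1)/(2y). The pieces simplify to a = sign(y−1)√(v(y−1−log y)),
  b = (y−1)√(v/2), lower CDF Φ(a) + φ(a)(1/a − 1/b). The formula is
  singular at the mean y = 1, where the exact expansion gives lower CDF
  0.5 + 1/(3√(πv)); within |y−1| < 1e−4 the general formula is blended
  linearly into that value to avoid catastrophic cancellation. Published
  renderings of this formula disagree on the sign/argument arrangement of
  the correction term; the orientation used here is fixed by agreement with
  the exact χ²_v tail (verified to ≤2e−3 absolute over v ∈ [3, 100], tails
  down to 0.001 — the `TD`/`TE` forms are accurate to ~1e−5 for v ≥ 8).

Accuracy against the exact χ²_v survival function, asserted in tests:
|error| ≤ 0.01 (`TB`), 0.005 (`TC`), 0.002 (`TD`, `TE`) over
v ∈ {3, 8, 20, 50, 100} and tail levels 0.2–0.001.

Numerical choices: p-values are clipped to [1e−15, 1] before the transform
(p = 1 maps to 0 exactly); a user-supplied covariance that makes
Var(T) ≤ 0 is rejected rather than floored, since no valid covariance
matrix can produce it; probabilities are clamped to [0, 1].

## Weights

`weights_from_gene_sizes` supports three schemes: `inv` (wᵢ = 2/nᵢ,
default), `inv_sqrt` (2/√nᵢ) and `flat` (2, plain Fisher). A singleton
gene gives w = 2 under every scheme. `inv` is the default because it
equalizes gene contributions exactly (each gene's tests sum to df 2) and
because it reproduces the published benchmark operating characteristics
best: in calibration sweeps of the naive null rejection rate under the
benchmark pathway it matches the reference value 0.101 at n = 200,
D = 0.15, while 2/√n gives 0.111–0.115 under otherwise identical
conditions.

## Permutation covariance

`estimate_transformed_covariance` shuffles the phenotype m times (default
1000), keeping genotype rows intact so the LD structure is preserved, runs
the per-variant test on each shuffle, transforms each p-value with its
weight, and returns the sample covariance (ddof = 1) across permutations.
Permutations are drawn uniformly without enforcing distinctness. The score
(trend) test is the default tester because it is closed-form and vectorizes
across all permutations as a single matrix product — the full benchmark
requires ~10⁷ per-variant tests. A per-variant logistic Wald test is
available (`tester="logistic"`); it falls back to the score p-value for a
column where IRLS diverges (quasi-complete separation, where the Wald
statistic is meaningless). Constant genotype columns get p = 1 by
convention.

## The simulator

Genotypes: within each gene, loci form a first-order Markov chain. Locus 1
is Bernoulli(q); each subsequent locus is drawn from the classical
two-locus conditional law P(A|B) = (q_A q_B + D)/q_B etc., which preserves
the marginal frequency algebraically (also Monte-Carlo tested). The
two-locus construction pins down only adjacent pairs; the chain is its
minimal n-locus extension, so correlation decays geometrically with
distance (tested at k = 1…4). D is bounded by
D_max = min(q_A(1−q_B), (1−q_A)q_B) = 0.21 at q = 0.3, where the induced
allelic correlation is R = D/0.21 (0.714 at D = 0.15, 0.952 at D = 0.20).
`D="uniform"` draws an independent D ~ U(0, D_max) per adjacent pair per
matrix. Default coding is haploid 0/1 (the benchmark simulates a haploid
GWAS pathway); diploid 0/1/2 sums two independent haplotypes.

Phenotypes: logit P(Y=1) = Σ_k β·(product of the term's genotypes), no
intercept, so the null prevalence is exactly 0.5. Six canonical term sets
(cases I–VI) place main effects and product interactions on fixed loci of
the benchmark pathway (genes of 12, 8, 5, 3, 2 SNPs; e.g. case I is five
main effects inside the 12-SNP gene, case III spans the three smallest
genes).

The simulator emulates LD-induced dependence among per-SNP tests in a
case-control pathway; it does not emulate realistic haplotype mosaics
(coalescent structure), allele-frequency spectra, missing data, covariates
or continuous phenotypes. Passing benchmarks therefore demonstrate correct
behaviour of the combination method under first-order LD dependence, not
performance on any particular real cohort.

## Benchmark harness and problem sizes

`rejection_rate_experiment` runs full replicates (simulate → test →
permute → combine) with per-replicate seeds spawned from the master seed
by counter, so results are independent of execution order; replicate-level
failures are counted and reported, never dropped. The package's standard
desk-scale profile — used by the test suite and `scripts/acceptance.py` —
is 500 replicates with 300 permutations for the permutation-adjusted
cells and 1000 replicates for naive-only cells (which skip the
permutation step entirely). A comparison run at m = 1000 permutations
moved the adjusted null rejection rates by ≤ 0.004, so the profile is not
a material approximation.

For distributional accuracy checks, `qq_comparison` draws dependent
p-values through a one-sided Gaussian copula (p = 1 − Φ(Z),
Z ~ MVN(0, Σ)), whose marginals are exactly uniform, and compares
empirical quantiles of T against each approximation's implied quantiles
computed from the *true* transformed-scale covariance. That covariance is
obtained by 64-node tensor Gauss–Hermite quadrature
(`copula_transformed_cov`), which doubles as the independent oracle for
the permutation estimator in tests. Correlation structures: fixed or
random compound-symmetric blocks (ρ per block from Beta(0.3, 1.5) or
U(−0.2, 0.2)) and full random positive-definite correlation matrices
(random orthogonal eigenvectors with Dirichlet-scaled eigenvalues summing
to the dimension, rescaled to unit diagonal — a simple recipe chosen for
reproducibility, not a uniform distribution over correlation matrices).

## Pathway mode

`run_pathway_analysis` gathers the member p-values of each gene set, sets
nᵢ = number of tests mapping to gene i within the supplied table, combines
with the chosen scheme, and BH-adjusts one chosen method's p-value across
sets (default `TA`). A set holding a single single-test gene returns that
test's p-value unchanged. Covariance may be supplied for the whole table
(the member submatrix is used per set); the default assumes independence
across tests, which is appropriate when the upstream tests were computed
on uncorrelated units and conservative-neutral otherwise — estimating ρ
requires the raw data, not just the p-value table.

## Known limitations

* The moment adjustment matches two moments only; with very strong
  dependence and small v the adjusted tests can sit slightly above the
  nominal level (observed ~0.05–0.07 at R = 0.71–0.95 in the benchmark)
  rather than below it.
* The permutation estimate of ρ is computed per dataset; its Monte-Carlo
  noise propagates into the p-value. m ≥ 300 makes this negligible at the
  benchmark sizes.
* Binary phenotypes only; genotype matrices must be complete.
* The Cornish–Fisher expansion is not monotone over all of x ∈ [−8, 8]
  for very small v; the bisection inverts it on the monotone region and
  clamps outside, and T = 0 is special-cased.
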