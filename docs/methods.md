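# Methods

## Problem and model

Single-trait GWAS release, per SNP `j` and phenotype `k`, an effect estimate
and its standard error (equivalently a Z score `Z_kj = beta_kj / se_kj`) and
a p-value.  When K related phenotypes have been scanned on overlapping
samples, the vector `Z_j = (Z_1j, ..., Z_Kj)'` is approximately multivariate
normal, `Z_j ~ N(mu_j, R)`, where `R` is the K x K phenotype correlation
matrix (inclusive of shared-sample and confounding correlation) and `mu_j`
is zero under the global null that SNP `j` is associated with none of the
phenotypes.  Everything in this package operates on that working model; no
individual-level data are required beyond optional small fixtures.

## Estimating R by LD score regression intercepts

Under a polygenic model the expected product of two traits' Z scores at a
SNP decomposes into a genetic part proportional to the SNP's LD score `l_j`
and an intercept:

    E(Z_sj * Z_kj) = G_g * l_j + rho_sk .

The intercept `rho_sk` is the phenotypic correlation between traits `s` and
`k` (for `s = k`, the univariate intercept estimates 1 plus confounding
inflation).  `estimate_R` therefore runs, over all aligned SNPs, an ordinary
least-squares regression of each pairwise Z product (and each squared Z) on
the LD scores and assembles the intercepts into a raw matrix.

Choices within this step:

* **Unweighted OLS** is the default.  The intercept, not the slope, is the
  target, and unweighted OLS is an unbiased, transparent baseline;
  inverse-variance weights can be supplied through the `weights` argument of
  `ldsc_regression`.
* **Heritability-bounds filter.**  A phenotype is excluded before assembly
  when its slope-implied heritability `slope * M / N` (raw slope when the
  sample size is unknown) falls outside [0, 1] — estimators outside the
  parameter space indicate a phenotype for which the regression model is
  unusable.
* **Normalize-and-repair.**  The raw intercept matrix is rescaled to unit
  diagonal (`D^{-1/2} A D^{-1/2}`); if any eigenvalue falls below the PSD
  floor (default 1e-8) the spectrum is clipped at the floor and the matrix
  re-normalized, iterating to convergence.  Eigenvalue clipping is preferred
  to nearest-correlation iteration because it is deterministic, cheap, and
  adequate for the small violations produced by sampling noise.  Inputs
  already satisfying the invariants pass through unchanged, making the
  repair idempotent.
* **No jackknife standard errors**: only the point estimate of R enters the
  tests, so intercept standard errors are not computed.

## The sCLC test

For one SNP with Z vector `Z`:

1. **Phenotype tree.**  Agglomerative hierarchical clustering of the K
   phenotypes on the dissimilarity `D = 1 - R` (entrywise; negative
   correlations simply give distances in (1, 2], used as-is).  Cutting the
   tree at every height yields nested partitions for every cluster count
   `L = 1..K`.  Average linkage (UPGMA) is the default — the conventional
   choice for correlation-derived distances — with single and complete
   linkage selectable.  Ties in the merge distance are broken toward the
   pair with the lexicographically smallest (minimum member index, other
   minimum member index), so fully tied inputs (e.g. `R = I`) produce one
   documented, platform-independent tree.  The agglomeration is implemented
   in-package (Lance–Williams updates, O(K^3)) to own that tie-break; the
   test suite cross-checks it against scipy's UPGMA on untied inputs.
2. **CLC statistics.**  For the L-cluster membership matrix `B` (K x L,
   one 1 per row), with `W = B' R^{-1}`,

       T_L = (W Z)' (W R W')^{-1} (W Z)  ~  chi2_L  under the null.

   Algebraically `W R W' = B' R^{-1} B`, so only solves against `R`'s
   Cholesky factor are needed.  Two identities anchor the implementation:
   `L = K` (B the identity) collapses to the Wald statistic `Z' R^{-1} Z`,
   and `L = 1` (B all-ones) to the homogeneous-combination statistic
   `(e' R^{-1} Z)^2 / (e' R^{-1} e)`; both are asserted exactly in tests.
3. **Cauchy combination.**  The K p-values `p_L` are aggregated as

       T_sCLC = (1/K) * sum_L tan((0.5 - p_L) * pi),

   whose null tail is approximately standard Cauchy even under the strong
   dependence among the `p_L` (heavy-tail robustness of the Cauchy mean),
   giving `p = 0.5 - arctan(T_sCLC)/pi`.

### Numerical policy

* Chi-square survival probabilities are computed in log space
  (`chi2.logsf`) so far-tail `p_L` never underflow before combination.
* `tan((0.5 - p) pi)` switches to its asymptote `1/(p pi)` below
  `p = 1e-15`, and `p_L = 1` (statistic 0) is clamped to `1 - 1e-16`;
  this is the standard ACAT stabilization and preserves the Cauchy tail.
* The combined p is evaluated as `arctan(1/T)/pi` for `T > 0` (stable at
  both tails), clipped into `[5e-324, 1]`, and also reported as `-log10 p`
  computed in log space for scan output.
* `R` is inverted via Cholesky after repair; if factorization still fails
  (duplicated phenotypes), shrinkage `(1-eps) R + eps I` with `eps = 1e-6`
  is applied with a warning rather than aborting a genome scan.
* Scans factor the partitions, the per-L loadings `B' R^{-1}` and the
  cluster covariances once per R and reuse them for every SNP; results are
  identical to the per-SNP path to 1e-12.

The Cauchy approximation is a **tail** approximation: its p-values are
accurate at small alpha (the regime of genome-wide testing) but deviate
from uniformity by a few percent in the body of the null distribution
(measured Kolmogorov–Smirnov statistic ~0.037 against U(0,1) at 1e4 null
replicates, K in {5, 40}).  Calibration claims and tests are therefore
stated at tail levels (alpha <= 1e-2), where empirical rejection rates sit
within Monte-Carlo error of nominal.

## Competitor tests

* **SSU**: `T = Z'Z`, approximated by `a chi2_d + b` with `a, b, d` matched
  to the first three moments of the exact null `sum c_i chi2_1` (`c_i` the
  eigenvalues of R).  The exact mixture tail is available in
  `weighted_chisq_pvalue` (Imhof inversion; the oscillatory tail integral
  is evaluated with an oscillation-aware quadrature in extended precision,
  absolute error well below 1e-8) and serves as the oracle in tests.  The
  moment-matched approximation is accurate in the bulk but its relative
  error grows below p ~ 1e-3 (up to ~25% around p = 1e-4 for generic R) —
  the same deterioration that shows up as SSU's inflated far-tail type-I
  rates in null simulations.
* **Hom**: `(e' R^{-1} Z)^2 / (e' R^{-1} e) ~ chi2_1`; optimal for
  homogeneous same-direction effects, blind to effect patterns orthogonal
  to `R^{-1} e` (opposed-direction scenarios drive its power to zero).
  Implemented with optional per-trait weights `sqrt(n)` (diagonal V); with
  a single cohort the weights cancel.
* **Wald**: `Z' R^{-1} Z ~ chi2_K`.
* **PCFisher**: Fisher combination `-2 sum log p_m ~ chi2_{2K}` of the K
  independent principal-component p-values, `PC_m ~ N(0, lambda_m)`;
  per-PC p-values are two-sided (the sign-free choice consistent with the
  `N(0, lambda)` null).
* **MAT(gamma)**: `Z' R+_gamma Z` with `R+_gamma` the pseudoinverse keeping
  the top `m` singular values with `sigma_1/sigma_m <= gamma` (the
  non-strict inequality makes `gamma = 1` keep the top multiplicity rather
  than nothing); exactly `chi2_m` under the null.
* **aMAT**: the minimum MAT p over `gamma in (1, 10, 30, 50)`, calibrated
  through a Gaussian copula.  Because the MAT statistics share R's
  eigenbasis, under the null they are deterministic functions of iid
  `chi2_1` spectrum components; the probit-scale correlation of the
  distinct per-gamma p-values is estimated once per R from 1e5 seeded
  draws of those components.  The union probability
  `P(min_g p_g <= t)` is evaluated by inclusion–exclusion over Gaussian
  tail orthants (Genz algorithm, seeded, good relative accuracy in the
  tail) and clipped into the Fréchet bounds `[t, G t]`.  Batch evaluation
  interpolates a monotone log-log grid of that map (measured error
  < 0.1%).

## Simulation study

Z vectors are drawn from `N(mu, R)` (Cholesky transform, seeded
`numpy.random.Generator`).  The fully specified correlation structure is a
40-phenotype block-diagonal AR(1): four equal blocks, blocks 1 and 3 with
entries `rho^|s-k|` and blocks 2 and 4 with `(-rho)^|s-k|`, `rho = 0.1`.
(The source literature writes the negative blocks as `-rho^|s-k|`, which
would put -1 on the diagonal; the negative-parameter AR(1) reading keeps a
unit diagonal and is the interpretation used here.)  Four effect scenarios:

1. graded same-direction effects `beta * (1/K, ..., 1)`;
2. half nulls, half constant `beta`;
3. with `k = K/5`: 2k nulls, 2k at `beta`, k opposed ramp
   `-(2 beta/(k+1)) * (1..k)`;
4. sparse, with `k = K/14`: 13k nulls, ramp `(2 beta/(k+1)) * (1..k)`.

Scenario 3 requires `5 | K` and scenario 4 `14 | K`; the 40-phenotype
structure cannot run scenario 4 and the module raises rather than guessing.
Scenario-4 results are reported at `K = 28`, the smallest size compatible
with both the four-block structure and the 14-part layout.

**Replicate sizes** are desk-scale by design: 1e5 null replicates for
type-I at alpha >= 1e-3 (binomial SE 1e-4 at alpha = 1e-3) and 1e4
replicates for power at alpha = 5e-8, both configurable.  **Effect sizes**
`DEFAULT_BETAS = {1: 1.75, 2: 1.75, 3: 1.6, 4: 5.0}` were fixed once so
sCLC's power lies in the informative mid-range (0.4–0.9) rather than
saturating; power orderings among methods are asserted as rank properties,
not numeric targets.  All studies are driven by seeded generators and
reproduce bit-identically.

### A caution about the symmetric stand-in structure

The block AR(1) matrix has repeated blocks, hence eigenvalues of
multiplicity >= 2 and exactly tied dissimilarities.  Quantities that depend
on an eigenbasis (PCFisher) or on the merge order of the phenotype tree
(sCLC partitions) are discontinuous there: an infinitesimal perturbation of
R rotates degenerate eigenvectors and reshuffles tied merges by a finite
amount.  This is an artifact of the synthetic symmetry — empirical phenotype
correlation matrices are generic.  Perturbation-robustness experiments are
therefore run on a generic (seeded Wishart-type) correlation matrix.

Perturbation itself (`perturb_R`) adds independent `N(0, delta)` noise
(variance `delta`) to the off-diagonals and repairs; `delta` in
{1e-5, 1e-4} corresponds to entry noise of sd 3e-3 to 1e-2, the scale of
LDSC intercept estimation error.  Note that noise of sd 0.01 on a 40 x 40
matrix displaces effective noncentralities by ~2%, which 1e4 replicates
resolve as a statistically significant (though practically small,
<= ~0.06) power shift at mid-range power; robustness holds strictly at
`delta = 1e-5` and approximately (small absolute shifts) at `delta = 1e-4`.

## Synthetic summary statistics (fixture generator)

`ldsc_fixture` draws per-SNP LD scores `l_j = 1 + Gamma(shape 2, scale
2.5)` (right-skewed, mean ~6) and `Z_j ~ N(0, R0 + l_j G)` independently
across SNPs, so the product-on-LD-score regression has intercept matrix
`R0` and slope matrix `G` by construction.  Default `G = (N h2 / M) R0`
with `h2 = 0.05` and `N = 1e5`: every phenotype has (liability-agnostic)
heritability 5% — the low-heritability regime typical of EHR-derived binary
phenotypes — and genetic correlations mirror the phenotypic ones.  What the
fixture deliberately does **not** emulate: LD-induced dependence between
neighboring SNPs (draws are independent across SNPs), case-control
ascertainment and saddlepoint-adjusted score statistics, allele-frequency
structure, or population stratification.  Recovery tests on these fixtures
therefore validate the estimator's algebra and sampling behavior, not its
behavior under real LD or confounding.

## Degenerate inputs and edge cases

* `K = 1`: the pipeline degenerates to the single-trait chi-square test.
* `Z = 0`: all statistics are 0 and p-values 1 (the Cauchy combination
  clamps `p_L = 1` as above, returning a combined p >= 0.5).
* Duplicate SNP ids, non-positive standard errors, p-values outside (0, 1],
  allele pairs that cannot be harmonized, and empty SNP intersections are
  rejected with specific errors; strand-ambiguous (A/T, C/G) pairs are
  flagged but kept, since the summary data cannot resolve them.
* p-values that underflow double precision enter through the log10-p path
  of `adjusted_z`.

## Known limitations

* The phenotype tree is built from the phenotypic correlation matrix; a
  genetic-correlation-based tree (LDSC slopes) is a plausible alternative
  and is deliberately out of scope.
* The Cauchy combination's body-of-distribution deviation (above) makes
  sCLC p-values unsuitable for, e.g., genomic-control inflation estimates
  computed from median p; tail inference is unaffected.
* aMAT's copula correlation is simulation-estimated; the original
  publication does not specify its parameterization, so exact parity with
  the original software is not claimed.
* Rejection of multi-allelic sites and liftover are out of scope; inputs
  are assumed to be on one build with unique SNP ids.
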