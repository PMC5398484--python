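# Methods

## Model and tests

`gxcset` models an N x C trait matrix Y (N individuals, C categorical
contexts; all defaults target C = 2) as fixed effects plus a regional genetic
random effect and structured noise:

    vec(Y) ~ N( vec(F B),  Cs ⊗ Rs  +  Cn ⊗ I_N ).

Rs = G Gᵀ / S is the realized relatedness of the S region variants after
per-variant standardization (mean 0, variance 1; monomorphic variants are
dropped before S is counted, so the diagonal of Rs has mean exactly 1).
Cs and Cn are C x C trait-context covariances. Marginalizing a variants x
contexts effect matrix W with independent unit-normal rows maps architectures
onto structures of Cs: identical columns of W (persistent effects) give a
block Cs = a₀·**1**; proportional columns (rescaling) give rank-one Cs = aaᵀ;
independent columns (heterogeneity) give a full-rank Cs = AAᵀ. The three
tests are REML likelihood-ratio statistics, LLR = 2·(ll_full − ll_null),
clipped at zero, against the null / block / rank-one constrained models. Any
monotone transform of the likelihood difference would do since significance
is empirical; the factor 2 is fixed for determinism.

Fixed effects B are profiled out by generalized least squares at every
covariance evaluation, and the REML correction log|Xᵀ V⁻¹ X| is included, so
the search space contains only covariance parameters. Population structure is
handled by including the top principal components of genome-wide relatedness
(default 10) as fixed-effect covariates; an additional genome-wide random
effect is out of scope.

### Parametrization and optimization

All covariance structures are PSD by construction for any real parameter
vector: block a₀ = c², rank-one via a free vector, full via a free
lower-triangular factor. Cn uses a lower-triangular factor whose diagonal is
exponentiated (clipped to ±15 in log space to avoid overflow); in stratified
designs Cn is restricted to its diagonal because off-diagonal entries never
enter the likelihood — this is asserted directly in the tests. Optimization
is L-BFGS-B with a moment-based start (Cn near the empirical trait
covariance, small Cs) plus seeded perturbed restarts (default 3 starts);
convergence uses gradient tolerance 1e-5 and at most 500 evaluations per
restart. Non-convergence of every restart flags the fit; the best optimum is
still reported and the caller decides.

### Fast likelihood paths and their oracle

Complete design: a one-off eigendecomposition of Rs (via SVD of G, cost
O(N·S²), when S ≪ N; otherwise an eigendecomposition in the space of
individuals) turns each evaluation into C independent diagonal GLS problems —
cost linear in N per evaluation after the factorization. Analytic gradients
are computed in the same diagonalized representation by differentiating the
covariance directly (the rotation is evaluated, not differentiated), and are
cross-checked against central finite differences in the tests.

Stratified design: V has entries Cs[cᵢ,cⱼ]·Rs[i,j] + δᵢⱼ·Cn[cᵢ,cᵢ], a
low-rank (≤ C·S) plus diagonal matrix. Because the diagonal is constant
within each context, every Woodbury product reduces to per-context Gram
matrices (GᵀG, FᵀG, ...) computed once per region, making evaluations
O(S²C²) independent of N. The stratified path uses finite-difference
gradients (2-point, via the optimizer): its parameter spaces have at most
C(C+1)/2 + C dimensions and evaluations are cheap after the Gram precompute,
so the duplicate Woodbury gradient algebra buys little.

A dense oracle builds the full (NC x NC or N x N) covariance and evaluates
the identical REML expression by direct factorization; the efficient paths
agree with it to < 1e-8 on randomized instances across all covariance kinds
and both layouts (property-tested, and re-checked in the acceptance suite).

### Empirical p-values

Permutation is not well defined for interaction tests, so the interaction and
heterogeneity nulls are parametric bootstraps: phenotype replicates sampled
from the fitted block (resp. rank-one) model, with the test refit on each
replicate using the same restart protocol as the observed fit (a replicate
whose refit does not converge is redrawn once with extra restarts). The
association test uses permutations of the genotype row order, which preserves
the trait-context covariance of Y; covariates stay with the phenotypes. Since
the no-genetics null fit does not involve the region, permutation replicates
refit only the full model and reuse the observed null fit (exact, not an
approximation). J nulls per region per test are pooled across the T tested
regions; p = (1 + #{null ≥ observed}) / (1 + J·T) with ties counted as
exceedances (conservative). The +1 smoothing avoids p = 0 and asymptotically
preserves the 1/(J·T) resolution of the pool, which corresponds to a
family-wise floor of 1/J under Bonferroni over regions. BH q-values are
computed per test across regions. Per-region RNG streams derive from
(global seed, region index), so chunked parallel scans are byte-identical to
serial ones.

## Synthetic data generator

The generator is first-class, tested code: it defines the study conditions
under which every statistical property of the package is demonstrated.

**Genotypes.** Cohorts are mosaics of simulated founder haplotypes. Founder
haplotypes get internal LD from a latent AR(1) Gaussian along the region
(correlation exp(−gap/10 kb) between adjacent sites) thresholded at
per-variant allele-frequency quantiles drawn from U(maf_min, 0.5); each
sampled haplotype copies founders piecewise with per-base-pair geometric
donor switches (default switch rate 1e-5/bp), so cohort LD decays with
physical distance at a tunable scale. Variants outside
[maf_min, 1 − maf_min] are dropped (default MAF ≥ 2%); a region keeping
fewer than two variants is an error. Defaults: 30-kb regions with 100
variants. An LD-free mode draws independent Binomial(2, maf) variants. A
two-subpopulation mode shares founder latents between pools and perturbs
only the allele-frequency thresholds, so divergence 0 produces no structure
and large divergence is visible on PC1 — used to validate PC adjustment.
The mosaic process is an emulation with a tunable LD scale, not a
coalescent-exact simulator, and founders are simulated rather than drawn
from a reference panel: the statistical contracts only require realistic
local LD, and the LD-free mode brackets the other extreme.

**Phenotypes.** Two-context traits are sums of four independent components,
each *empirically rescaled* to its exact target variance fraction per
replicate (divide by realized SD, multiply by target) so simulator
calibration is sharply testable: a regional genetic component (default
v_r = 2% per context; 4 causal variants per context, 2 in heterogeneity
mode), a population-structure component drawn through genome-wide background
genotypes, K = 10 hidden confounding factors, and iid Gaussian noise.
Structure and hidden components have cross-context correlation alpha = 0.6;
hidden factors take beta = 50% of the non-region variance, and the remaining
(1−beta)(1−v_r) is split equally between structure and noise
(`structure_fraction` = 0.5 — the exact split behind the published parameter
table is not recoverable from the available material; this reading is the
package's own choice and is exposed as a config field). Architectures:
persistent (identical W columns), rescaling (column 2 = eta x column 1;
eta = 1 is no interaction, eta = 0 context-exclusive, eta < 0 opposite
directions), heterogeneity (disjoint causal sets per context, with the
cross-context correlation r of the realized regional effect controlled by
rejection sampling to ±0.05, cap 10,000 draws; an explicit acceptance band,
e.g. 0.2 < r < 0.8, can be supplied instead). Under rescaling, both columns
of W are scaled by a single factor so the *cross-context average* regional
fraction equals v_r while per-context variances keep the 1 : eta² ratio —
per-context exact scaling would destroy the proportionality that defines the
architecture.

Misspecification modes for calibration checks: a single causal variant;
an added epistatic product term of a random variant pair (scaled to the
regional variance target, stored so tests can verify additivity); and heavy
tailed outliers, ±8 added to 0.1% of the N·C trait entries (count rounded,
minimum one). The three-locus illustration places persistent, rescaling
(eta = −0.5) and heterogeneity (r = 0) loci of 30 kb in one larger region,
each scaled to 5% of total phenotypic variance.

What the generator does *not* emulate: real LD block structure and allele
frequency spectra, related individuals, non-Gaussian trait families, probe
level measurement artifacts. Passing tests demonstrate the statistical
machinery under controlled Gaussian conditions, not robustness to every
property of real expression or lipid data.

## Variance decomposition

Explained set variance under a constrained kind is the mean over contexts of
Ĉs[c,c] divided by the empirical per-context trait variance (with Rs
normalized to unit mean diagonal, Ĉs[c,c] is the expected per-context set
variance under standardized genotypes). Attribution is by nested fits:
persistent = block's explained fraction; rescaling = rank-one's increment;
heterogeneity = full's increment. A cumulative maximum guards against
optimizer noise so increments are non-negative and sum exactly to the total;
in theory the nesting is monotone and the guard is inactive (property-tested
up to 1e-6 slack). Whether the reference analysis attributes via nested fits
or an algebraic split of the full-model Ĉs is not recoverable from the
available material; nested fits are this package's documented choice, and
only properties that are independent of that choice are asserted (zero
interaction fractions under persistent simulations, zero persistent fraction
under negative rescaling, calibrated totals under the full model).

## Single-variant baseline and lead-variant rules

The per-variant interaction baseline is a 1-df Wald test of equal effects
across the two contexts in a fixed-effect model whitened by the residual
trait-context covariance of the no-genetics fit (no per-variant covariance
re-estimation — keeps the scan O(S) and matches the comparator's role).
Region-level p is the minimum interaction p times either the variant count
(Bonferroni) or an effective test count: the smallest k whose top-k
eigenvalues of the variant correlation matrix capture 99.5% of its total
variance (configurable; an approximation in the spirit of published
effective-test estimators, not a reimplementation of any of them).
Lead-variant classification uses the published LD rules: distinct leads at
r² < 0.2 (both contexts significant), shared lead at r² > 0.8 (split
same/opposite direction by effect-sign concordance, with context-specific
secondary sub-labels), unresolved in between or when inputs are missing.
The univariate heterogeneity score is 1 − r² between per-context lead
variants when both are significant, else 0.

## Numerical choices and degenerate inputs

- Quantile normalization maps averaged ranks to Gaussian quantiles at
  (rank − 0.5)/n; constant vectors and n < 3 are errors. The 0.5 offset
  (rather than the Blom 3/8 correction) is configurable.
- PC computation drops monomorphic variants, standardizes, and fixes signs by
  making each eigenvector's largest-magnitude entry positive (deterministic
  output).
- Missing genotypes in input files are imputed to the rounded per-variant
  mean dosage with a logged count; multi-allelic VCF sites are skipped with
  a logged warning.
- Degenerate scan windows (no variants surviving the MAF filter) yield NA
  rows rather than errors.
- Eigenvalues of Rs and of constrained Cs are clipped at zero before use;
  Cholesky failure of Cn inside an optimization step returns a large
  objective value so the line search backs off.
- LLR ties with pooled nulls count as exceedances (conservative); whether
  the reference procedure does the same is unstated.

## Problem sizes in the test and acceptance suites

Simulation-heavy checks run at reduced scale, chosen as this package's own
desk-scale study conditions, with exact binomial 99% bands at the realized
replicate counts: type-I error on 100 persistent-only regions (N = 500,
J = 15); heterogeneity power on 60 repeats (N = 1,000, J = 30, target effect
correlations r ∈ {0, 0.2, 0.35}, all with r² < 0.16, assessed at FDR 5% with
BH across repeats); rescaling calibration with eta ∈ {0.3, −0.5} and the
eta = 1 no-interaction check on 30 regions each (J = 12); misspecification
calibration on 24 regions per mode (J = 10). The simulator calibration
quantities use the full published replicate counts (500 regions / 100
illustration replicates) since they require no model fitting.

## Known limitations

- The additional random-effect background term for related individuals is
  not implemented; PC adjustment is the supported path.
- Heterogeneity tests in stratified designs run but deserve caution:
  differential tagging across strata can mimic heterogeneity; the package
  does not add extra controls for this.
- Rejection sampling for large target effect correlations with disjoint
  causal sets can be slow or fail in low-LD regions (it raises after the
  attempt cap rather than silently biasing the draw).
- BLUP standard errors and confidence intervals on variance fractions are
  not provided.
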