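# Methods

## Per-gene differential variability

The Brown–Forsythe test scores each observation by its absolute deviation
from the group *median* and applies a one-way ANOVA to the scores. The
median centring makes the test robust to non-normal expression
distributions; it reduces to Levene's test when means replace medians.
Inputs are assumed to be pre-normalized continuous values (e.g. adjusted
log-CPM); no count-model dispersion estimation is attempted and no
covariates are adjusted here.

Conventions:

- Medians use the standard sample definition (mean of the middle pair for
  even n); no tie correction.
- A degenerate 0/0 F statistic — every deviation score identical within
  and between groups, e.g. a constant gene — is defined as statistic 0,
  p = 1, and logged. This matches the "no evidence of a variance
  difference" semantics and keeps genome-wide scans total.
- Benjamini–Hochberg adjustment (via statsmodels) is applied across all
  genes of a scan as one family.
- The reported `direction` is the sign of (case variance − control
  variance) using unbiased sample variances; it annotates results and
  never enters the test.
- Genes with near-constant expression are not pre-filtered; they simply
  yield p = 1.

## Gene-set dispersion test

For a gene set with d genes, sample i of group g gets the Mahalanobis
distance D_i = sqrt((x_i − μ_g)ᵀ S⁻¹ (x_i − μ_g)) to its own group
centroid (arithmetic mean), and the two groups' distance vectors are
compared by one-way ANOVA on the distances themselves (not their
squares). The Mahalanobis metric whitens the set's co-expression
structure, which makes the test invariant to any invertible linear
transformation of the gene-set expression — a property the test suite
checks numerically to 1e−8.

**Choice of covariance.** The default S is the pooled within-group
covariance. This choice is load-bearing. If instead each group's
distances are whitened by that group's *own* fitted covariance, the
identity Σ_i D_i² = (n−1)d pins the mean squared distance of every group
at the same value regardless of the data, which (a) makes the ANOVA
radically conservative under the null (empirical type-I ≈ 0 instead of
the nominal level) and (b) destroys power against scale alternatives
(≈ 0 even at n = 1000 under twofold inflation). The pooled choice keeps
the test calibrated (measured type-I 0.067 at nominal 0.05, d = 10,
n = 200/group, 1,000 replicates) and powerful. `per_group` and `total`
covariance modes remain available as config options for sensitivity
analysis, as does a `euclidean` metric flag that recovers the classic
unwhitened dispersion test.

**Modified variant.** Pool D₀ ∥ D₁, compute the 90th percentile t
(linear-interpolation convention) and the maximum c, replace every value
strictly greater than t by value × c, re-split by group, and run the same
ANOVA. Both the percentile convention and the strict inequality are
config-exposed. The boost constant is computed before any
multiplication; if c < 1 (impossible for whitened distances in d ≥ 2
except in pathological inputs) a warning is logged since the "boost"
would shrink the tail.

**Regularization and degeneracy.** A sample covariance with condition
number above 1e10 receives a ridge ε·trace(S)/d with ε = 1e−8; a group
with n ≤ d + 1 is rejected outright rather than silently shrunk, since a
fitted d-dimensional covariance needs more samples than dimensions.
Identical distance vectors yield F = 0, p = 1 by the same 0/0 convention
as the univariate test.

**Per-gene contributions.** The Garthwaite–Koch partition writes the
squared distance of a centred sample z as Σ_i (Wz)_i² with W the
symmetric principal square root of S⁻¹ (unique, permutation-equivariant,
and exactly conservative: the components are non-negative and sum to
zᵀS⁻¹z). For ranking genes, per-sample contributions are computed under
the pooled within-group covariance and averaged over the *case* samples
only, then normalized to shares. Averaging over the same samples that
define the whitening matrix is provably uninformative — the summed
contributions reduce to the diagonal of W S W = I, i.e. exactly uniform
shares — so a one-group aggregation on the common covariance scale is the
only version of this statistic that can reveal which genes inflate the
case group's dispersion. Aggregation over controls or both groups is
available via a parameter. Ties in shares are broken by gene ID.

**Scanning collections.** Sets are intersected with the matrix's genes;
sets with fewer than `min_genes` (default 10) genes present are skipped
and logged. The scanner reports nominal p-values and the dispersion
direction (which group has the larger mean distance); BH q-values across
sets are optional, with nominal-p ranking the default. No
permutation-based p-values are computed.

## Power simulation

Controls are drawn from MVN(μ₀, Σ₀) and each case sample from
MVN(μ₁, (1 + e^l) Σ₁), l ~ Uniform(0, α), in a balanced design (equal
per-group n). The inflation exponent l is drawn **per case sample**, not
once per dataset: a single per-dataset scale factor is a pure scale
change of the whole group, which the dispersion test's covariance
estimate absorbs, whereas per-sample heterogeneity is exactly the
"heterogeneous patient population" alternative the test targets. A
config flag (`per_sample_inflation=False`) allows per-dataset draws for
sensitivity analysis, and `inflation_enabled=False` is the null switch
used for type-I calibration.

Defaults follow the reference design: d = 23, α grid 1, 1.2, …, 5, n
grid 100, 200, …, 2000, 100 replicates per cell, rejection at p < 0.01.
Since the test is affine-invariant, when Σ₀ = Σ₁ the specific SPD matrix
is immaterial (checked by a same-seed equality test); the default uses an
AR(1) correlation matrix with ρ = 0.3 as a realistic stand-in for a gene
set's co-expression. Grid cells use independent RNG substreams keyed by
(seed, n-index, α-index, replicate), so any sub-grid reproduces in
isolation.

Under these conditions the pooled-covariance test is already at ceiling
power (≈ 1.0) for α = 1 at every n in the grid, for both variants; the
acceptance script reports the measured power at the two reference
settings (original at n = 1000, modified at n = 700). The modified
variant's power is never materially below the original's at matched
settings.

## evQTL scan

Per-group MAF is the folded allele frequency, minor-allele count over
2 × non-missing genotypes, making the filter invariant to allele coding;
SNPs are retained when MAF > 0.15 in *both* groups. For each SNP–gene
pair a Brown–Forsythe test across the genotype classes is run within
cases and controls separately; genotype classes with fewer than 5 samples
(configurable) are dropped from that SNP's test, and pairs with fewer
than two usable classes in a group are skipped with a log message.
Missing genotypes are excluded pairwise. Classification uses the strict
dual thresholds p_case < 1e−7 and p_control > 0.05 (and symmetrically);
no multiple-testing correction is applied to evQTL p-values, mirroring
the fixed-threshold calling convention. The pair universe is a
user-supplied pair list or all SNP × gene combinations; no cis-window is
hard-coded since variance effects are frequently trans-acting.

## Synthetic data

Generators are pure functions of scenario + seed and emit truth tables
for recovery scoring. They emulate: per-gene group-variance differences
(planted case sd = sqrt(variance_ratio) × control sd), gene sets with the
per-sample covariance-inflation mechanism above embedded in a null
matrix with a matching GMT, and SNPs (sampled under Hardy–Weinberg
equilibrium) whose genotype classes have unequal expression variances in
the case group only. Noise is Gaussian throughout, matching the
multivariate-normal simulation design the analyses assume; the
generators do not emulate normalization artifacts, batch effects,
heavy-tailed noise, or mean–variance coupling of counts, so passing
recovery tests demonstrates correctness of the statistical machinery on
the stated model, not robustness to real-data pathologies.

## Test and reporting sizes

The shipped test suite and acceptance script use desk-scale problem
sizes chosen to keep Monte-Carlo error small relative to the margins
being checked: 100-replicate power estimates at n = 1000/700, a
1,000-replicate type-I calibration at d = 10, n = 200/group, 400
global-null scans of 1,000 genes at n = 50/group (the zero-flag rate,
≈ 0.97 in repeated measurement, is compared against a 0.95 floor), and
single-scan recovery checks at the scenario sizes stated in the tests.

## Known limitations

- The ANOVA-on-distances p-value is approximate (distances are neither
  normal nor independent); calibration is verified empirically rather
  than guaranteed, and permutation p-values are deliberately out of
  scope.
- With the pooled covariance the dispersion test is highly sensitive to
  scale alternatives even at moderate n; power curves saturate quickly
  and are therefore reported at the reference settings rather than as a
  rising curve.
- The evQTL scan tests all supplied pairs without correction; callers
  controlling genome-wide error should choose thresholds accordingly.
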