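# Methods

## Study system and scope

The package analyses a two-part dataset structure: (a) a microsatellite
(SSR) survey of a clonal plant population scored at eight loci as sets
of fragment sizes per sample, and (b) a full-factorial greenhouse
experiment on six donor individuals (three per cytotype: homoploid
hybrid vs. allopolyploid) under two water regimes (well-watered vs.
drought) and two atmospheric CO₂ levels (ambient vs. elevated), with six
replicate pots (ramets) per individual × treatment cell. All analyses
run equally on user-supplied CSV tables or on the synthetic populations
generated by `traitscape.synth`.

## SSR genotype analysis

**Dominant presence/absence coding.** Allele dosage is unresolvable in
a dodecaploid, so a sample's state at a locus is the *set* of binned
fragment sizes. Samples identical at every locus form one multilocus
genotype; labels are assigned `A, B, C, …` by descending count, with
count ties broken lexicographically on the serialized allele string so
labelling never depends on input order. Frequencies are reported as
carrier percentages per stratum (hybrid, allopolyploid, total), rounded
half-up to one decimal to match conventional table formatting; each
stratum column of a per-locus table sums to 100 ± 0.1 after rounding.

**Binning.** Fragment sizes whose distance from the start of a bin is
strictly less than `bin_width` (default 1 bp) collapse to one allele,
represented by the count-weighted mean rounded to integer bp. The
strict inequality means integer input sizes pass through unchanged at
the default width. Suspected indel artefacts can be removed globally
via `(locus, size)` exclusions.

**Dissimilarity.** The distance between two samples is the number of
alleles present in exactly one of them (symmetric-difference count),
summed over loci. A locus with an empty set in either sample is treated
as a failed amplification and contributes zero rather than a maximal
difference; this deliberately avoids inflating divergence from missing
data, at the cost of the triangle inequality when null loci are present
(on fully scored data the distance is a metric, which the tests assert).

**Minimum spanning network.** A Kruskal minimum spanning tree over the
genotype dissimilarity matrix, augmented with every non-tree edge whose
weight equals the maximum edge weight on the tree path between its
endpoints. That condition is exactly membership in *some* minimum
spanning tree, so the network is the union of all MSTs and displays
tied alternative connections among equidistant genotypes instead of an
arbitrary tree choice.

**Allele counts.** Two summaries are reported and neither is
hard-coded: the number of distinct (locus, allele) pairs in the data,
and the allele complement of the modal genotype (16 under the default
synthetic loci). The distinction matters because rare gained alleles
make the first exceed the second.

## Imputation and trait-scape

**Regularized iterative PCA.** Missing trait cells are initialized with
column means; then the matrix is standardized (means and SDs recomputed
each pass), reconstructed at rank *S* (default 2) with each eigenvalue
shrunk by the mean of the trailing eigenvalues, and the missing cells
are refilled from the reconstruction. Iteration stops when the imputed
values change by less than `tol` (default 1e-8) in Frobenius norm, or
at `max_iter` (default 1000) with a `ConvergenceWarning`. The shrinkage
protects noisy data from overfitting while leaving exactly low-rank
matrices untouched, so a matrix of rank ≤ *S* has its masked entries
recovered essentially exactly. Observed entries are never modified.
The default *S* = 2 reflects that the ordination is interpreted on two
dimensions; it is exposed in the configuration.

**Ordination.** The trait-scape is a PCA on the completed replicate ×
trait matrix with traits standardized to unit variance (default). The
traits mix μm, dimensionless ratios, mm², cm, mm and counts, so a
covariance-matrix PCA would be dominated by leaf area's numeric range;
correlation-matrix PCA is the defensible choice and matches the default
of the standard ordination tooling. All *k* = 6 dimensions are
retained. Sign convention: each component's largest-magnitude loading
is made positive, making score signs reproducible across platforms.
A zero-variance trait under scaling raises an error naming the trait.

## Plasticity indices

The **multivariate plasticity index** for a group (donor individual, or
cytotype when replicates are pooled) and a treatment contrast is the
mean Euclidean distance over all n×m cross-environment pairs between
its ambient-reference replicates and its treatment replicates, computed
in the *full* 6-dimensional score space. Within-environment pairs never
enter. Because the full-rank standardized PCA is an isometry, MVPi in
score space equals MVPi on centered/scaled traits (tested to 1e-9);
the 2-D trait-scape plot is presentation only. The ambient reference
cell is (well-watered, ambient CO₂) throughout; the default contrasts
are the three treatment cells against that reference plus the CO₂
contrast within the drought level. MVPi is translation- and
rotation-invariant and bounded below by the distance between the two
environment centroids (both property-tested). Groups lacking ambient
replicates are reported as missing (NaN), never as zero. Both
aggregations — per-individual MVPi and cytotype-pooled MVPi — are
emitted by the pipeline, since either can be meant by a cytotype-level
plasticity comparison.

The **plant trait variation index** of an individual is the mean
distance of its ambient replicates to the centroid of *all* ambient
replicates pooled across individuals; it measures constitutive trait
divergence rather than environmental responsiveness.

Dead or removed pots never enter score computation; only survivors are
analysed.

## Inference

**Box-Cox.** λ maximizes the profile log-likelihood on a grid over
[−2, 2] in steps of 0.01, refined by a parabola through the best grid
point and its neighbours; |λ| < 1e-6 falls back to the exact log limit
(the naive formula suffers catastrophic cancellation near zero). λ is
chosen per response variable, not globally. Responses must be strictly
positive.

**Factorial ANOVA.** `response ~ cytotype * (water * co2)` with
sequential (type I) sums of squares in the written term order — the
design is near-balanced, so the choice is minor, but it is the
documented convention. Pots are technical replicates, so responses are
first aggregated to one mean per surviving individual × treatment cell
(24 rows, residual df 16 in the full design); `aggregate=False` skips
this for already-independent rows. Empty cells warn (sequential SS
remain computable); zero residual df is an error. Residual normality
is checked with Shapiro–Wilk and variance homogeneity with the
median-centered Levene (Brown–Forsythe) variant, the robust default.

**Tukey HSD** uses the exact studentized-range distribution with the
Tukey–Kramer allowance for unequal group sizes; at k = 2 it reduces
exactly to the pooled two-sample t-test (q = √2·|t|), which the tests
assert to 1e-9. One-way ANOVAs compare the trait variation index
across the six individuals (df = 5) and MVPi between cytotypes
(df = 1).

**Relative decrease** is 100·(treatment − reference)/reference with the
reference mean as 100%, rounded half-away-from-zero to integer percent
for reporting (13.8 → 5.9 g gives −57%; 9.5 → 5.0 g gives −47%).

## Leaf-area allometry

Leaf area is predicted from caliper measurements by OLS of area on the
single regressor width × length with intercept. The published
calibration `area = 86 + 0.63224·w·l` (R² ≥ 0.98) is available as
`reference_model()`; its units are instrument-native and are never
converted — the coefficients fix the scale. A constant regressor is an
error; fitted residuals are orthogonal to the regressor and R² equals
1 − SSE/SST (both tested).

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical shape* of the study:

* the 6 × 2 × 2 × 6 = 144-pot design with 21 dead/senescent and 9
  removed pots (chosen uniformly at random — mortality is treated as
  treatment-independent because only totals are known), leaving 114
  survivors;
* cell means/SDs anchored to the reported statistics where available:
  stomatal length 27.5 ± 2.1 μm (hybrid) vs 38.2 ± 3.0 μm
  (allopolyploid); biomass 13.8 ± 6.3 / 5.9 ± 2.4 g (hybrid
  well-watered/drought) and 9.5 ± 4.4 / 5.0 ± 1.8 g (allopolyploid),
  held constant across CO₂ levels;
* remaining cells chosen once as field-realistic values consistent with
  the qualitative cytotype contrasts (allopolyploid: fewer, thicker,
  taller stems, larger leaves; hybrid root:shoot peaking under
  well-watered × elevated CO₂ at 1.5 ± 0.35 and dropping to 0.9 ± 0.30
  under drought × elevated CO₂; drought shrinking leaf area and stem
  density by 20% and height by 15%);
* positive traits drawn from a normal truncated at zero; stem density
  rounded to a non-negative integer. Truncation negligibly raises the
  realized mean when mean/SD is small (≈ +0.23 g for hybrid well-watered
  biomass); traits with mean/SD ≳ 10, such as stomatal length, are
  unaffected to well below Monte-Carlo noise;
* missingness injected completely at random among survivors only
  (defaults: 5% stomatal length, 2% other functional traits) — the real
  missingness mechanism is unknown;
* SSR populations in which `round(dominant_fraction·n)` samples carry
  the modal genotype (default fraction 0.557) and the rest gain 1–4
  rare alleles or lose 1–3 modal alleles, mirroring the observed variant
  structure; losses never empty a locus (an empty set means failed
  amplification). The default eight loci carry 16 modal alleles in
  total. `rare_allele_rate` scales the deviating fraction; 0 yields a
  monomorphic population.

One integer seed drives everything through deterministic per-operation
sub-streams; repeated runs are byte-identical on serialized CSV.

**What passing tests do not show:** the generator draws independent
normal traits per cell, so it carries no within-individual trait
correlations beyond those induced by cell means, no legacy (field
origin) effects, no treatment-dependent mortality, and no informative
missingness. Quantities that depend on the real covariance structure —
the two-dimension explained variance, observed F statistics and the
exact plasticity-index values — are therefore not reproduced at desk
scale and are covered instead by property-based checks (isometry,
exhaustive MST minimality, imputation recovery, ANOVA type-I
calibration in [0.035, 0.065], and directional recovery of a built-in
cytotype × CO₂ interaction).

## Problem sizes and numerical choices

The test suite and acceptance script use the design sizes above
(144 pots, 79 SSR samples), 10,000-draw calibration samples, 2,000
null-ANOVA simulations on balanced 24-row datasets, 1,000 isometry
instances, 100 exhaustive-MST instances on ≤ 6 nodes (≤ 1,296 spanning
trees each, enumerated via Prüfer sequences) and 100-seed directional
runs. Tolerances: 1e-9 for linear-algebra identities, 1e-6 for
iteratively recovered quantities, 1e-12 for arithmetic identities.
Tie-breaks are deterministic everywhere (lexicographic genotype labels,
sign-fixed loadings, half-up rounding in reported percentages).

## Known limitations

* The dissimilarity's missing-locus rule sacrifices the triangle
  inequality in the presence of amplification failures (see above).
* Sequential SS are order-dependent in unbalanced designs; the term
  order is fixed and documented rather than configurable.
* The imputer's `transform` completes new rows against frozen axes and
  is only as good as the fitted subspace; the primary use is
  transductive completion of the training matrix.
* No mixed-effects models, no univariate plasticity indices, and no
  population-genetic summaries (Fst, heterozygosity) — out of scope.
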