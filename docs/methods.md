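# Methods

## The summary-statistics (indirect) scan

A per-variant linear association test of phenotype *y* on genotype dosage
*g* with full-rank covariates *Z* (intercept included) is, by the
Frisch–Waugh–Lovell decomposition, the univariate regression of the
residualized phenotype ỹ = Py on the residualized genotype g̃ = Pg, where
P = I − Z(ZᵀZ)⁻¹Zᵀ. With d = N − C − 1 residual degrees of freedom
(C counts the intercept; one further df is reserved for the genotype):

    β̂ = g̃ᵀỹ / g̃ᵀg̃
    SE(β̂)² = (1/d) ( ỹᵀỹ / g̃ᵀg̃ − β̂² )

If y = Xp is a linear combination of m feature phenotypes, every term of
these expressions can be rewritten in shareable summary statistics: the
per-feature coefficients **b** and standard errors **s**, the partial
covariance C = X̃ᵀX̃/d of the features, and the genotype partial variance,
recovered per feature by inverting the SE formula,

    Var(g̃)ᵢ = Var(x̃ᵢ) / (sᵢ² d + bᵢ²),

and averaged (unweighted arithmetic mean) across features. Then

    β̂ = bᵀp,   SE(β̂) = √( (1/d)( pᵀCp / Var(g̃) − β̂² ) ).

This is an algebraic identity, not an approximation, **provided** every
feature scan used the same complete-case sample, the same covariates, and
the same variance divisor d. That shared-sample requirement is why the
simulator produces complete data only, and why `PartialCovariance` records
its normalization constant: if the covariance were divided by N − 1 while
the scans used d, the reconstruction would be biased by the ratio of the
two. Exactness is enforced in the tests at 1e-8–1e-10 relative error
against an independent least-squares oracle (a full multiple regression on
the design [Z | g]), not just against the package's own direct scan.

Degenerate cases are flagged, never fatal: a variant whose residualized
dosage is constant yields NA statistics with a warning; a non-positive
variance bracket (possible only with mutually inconsistent user-supplied
inputs) yields an NA standard error; features with sᵢ²d + bᵢ² = 0 are
dropped from the genotype-variance mean. The indirect sample size is the
minimum over features with a nonzero projection coefficient — features that
do not enter y cannot restrict the sample a direct scan would have had.

p-values use the two-sided t reference with d degrees of freedom rather
than the normal approximation: at biobank N the two coincide, and t keeps
small-sample tests (and the test suite's small fixtures) exact.

## Phenotype definitions and linearization

Definitions are expression trees over features: boolean operators (AND, OR,
NOT), comparisons against constants, and elementwise arithmetic. On crisp
0/1 data the boolean operators are classical logic. Anonymized data is
fractional, so the operators must extend off the lattice; the default is the
min/max/fuzzy family (AND = min, OR = max, NOT = 1 − x), which preserves
[0, 1], reduces to classical logic on crisp inputs, and is monotone. The
product family (AND = ab, OR = a + b − ab) is available via `bool_mode=
"product"`; the two coincide exactly on crisp data, and which one a
production system should use on aggregated data is a modeling choice, not a
mathematical one — hence the option.

A nonlinear definition y is approximated by OLS against all features,
p̂ = argmin‖y − (α + Xp)‖². The intercept is fitted but excluded from the
projection handed to the indirect scan, because association statistics are
invariant to phenotype location shifts once covariates include an
intercept. The fit R² between y and its approximation ("phenotype fit
quality") is computed on the same data used for fitting — it is a gauge of
the approximation, not an out-of-sample estimate — and clipped at 0 for
pathological targets. Rank-deficient feature matrices (common after heavy
microaggregation, which collapses records onto few distinct rows) produce
the minimum-norm solution with a logged warning.

## Anonymization (MDAV)

The classical MDAV microaggregation is implemented unmodified: while at
least 3k records remain, form one group of k around the record farthest
from the current centroid and another around the record farthest from the
first; with 2k ≤ r < 3k remaining, one group of k around the farthest
record and the remainder as a final group; with r < 2k, a single group.
Records are released as group centroids. Consequences verified by the test
suite: group sizes lie in [k, 2k−1] with at most one group larger than k,
every released row occurs at least k times, and column means are conserved
to 1e-10 (centroid replacement conserves sums). All ties (farthest record,
k-nearest members) break toward the lowest original record index, making
the partition fully deterministic.

Distances are Euclidean on raw columns by default. For mixed
binary/quantitative data an optional per-column standardization of the
distance space is provided (centroids are always computed on the raw
scale); it is off by default since the indicator matrices the pipeline
targets are already on a common scale.

The fidelity experiment isolates the effect of anonymization: both the
reference and the comparison are *indirect* scans against non-anonymized
feature statistics, differing only in whether the projection was estimated
on anonymized data. Fidelity is the Pearson correlation of the two
chi-squared vectors.

## PCA acceleration

To scan m phenotypes with fewer regressions, the residualized phenotype
matrix is decomposed as X̃ = S Lᵀ (scores × orthonormal loadings from the
eigendecomposition of the partial covariance). Direct scans run on the
first q score columns; phenotype j is then exactly the linear combination
of the scores with coefficients L[j, 1..q] (exactly when q = m), so its
statistics are reconstructed indirectly. PCA is fit on covariate-
residualized phenotypes so the score covariance shares the d-divisor with
the scan machinery; the residual projection is idempotent, so re-
residualizing the scores inside the scan is harmless. Component signs are
fixed by making each loading column's largest-magnitude entry positive,
removing the eigendecomposition's sign ambiguity for reproducibility.

Reconstruction quality is measured two ways: GWAS fidelity (Pearson
correlation of chi-squared statistics against the direct scans) and a
significance confusion matrix at α = 5×10⁻⁸ treating direct significance as
truth (sensitivity, specificity, precision, F1). At q = m the round trip is
exact to ~1e-12 relative and the confusion matrix has FP = FN = 0; below
full rank the mean fidelity rises monotonically with the retained fraction
on data with correlated phenotype structure.

## The simulator

The generator emulates an additive variance-component design. Per
phenotype, total variance 1 is split into a fixed-SNP genetic share h²s, a
noise share δ, and a covariate/confounder share 1 − h²s − δ (configurations
with h²s + δ > 1 are rejected). The genetic component is built from a
causal subset of variants (causal_fraction of all variants) and split into
a shared part (one effect direction common to all phenotypes, proportion
θ) and per-phenotype independent parts; noise splits likewise with shared
proportion φ; confounder effect directions are correlated across
phenotypes at p_corr. Defaults (m = 10 phenotypes, causal_fraction = 0.5,
h²s = 0.5, θ = 0.8, δ = 0.3, φ = 0.6, p_corr = 0.8, 5 covariates) mirror a
standard validation configuration for multi-phenotype summary-statistics
methods.

Two implementation choices are deliberate. First, component vectors are
standardized *empirically*, so realized variance shares match the requested
proportions on the simulated sample rather than only in expectation.
Second, "independent" component vectors within a family are orthogonalized
(QR) against the shared component and each other: unadjusted random vectors
in an n- (or span-) dimensional space overlap at O(1/√dim), which would
leave spurious phenotype correlations precisely in the configurations
meant to have none. Orthogonalization requires at least m + 1 causal
variants (or covariates, for the confounder family); below that the raw
standardized directions are used and a small residual correlation is
unavoidable.

Projection coefficients for the random-projection protocol are standard
normal — any continuous distribution would do, since the equivalence being
tested is an identity in p. Binary (diagnosis-code-like) features are
generated by thresholding one-factor-correlated latent Gaussians at
prevalences drawn uniformly from a configurable range (default 5–30%),
giving sparse 0/1 columns with controllable positive association. Random
boolean definitions sample uniformly over the two-feature families
"x AND y", "x OR y", "x AND NOT y" with distinct features.

The simulator deliberately omits linkage disequilibrium, population
stratification, relatedness, sex chromosomes and missing calls. Passing
tests therefore demonstrate the algebraic correctness and the qualitative
fidelity/degradation trends of the methods, not their behavior under the
confounding structures of real cohort data — on real data the linear-model
identity still holds exactly (it is algebra), but fit qualities, fidelities
and confusion metrics will differ.

## Problem sizes and numerics

The validation protocol uses 2,000 samples × 1,000 variants × 10 phenotypes
with 100 random projections for the equivalence check, and m = 20
phenotypes for the PCA experiments; trend criteria (fidelity vs retained
fraction, fidelity vs k) average 5 replicates at 1,000 × 300 × 20. These
sizes put every Monte-Carlo assertion well inside its sampling error while
keeping the full suite under ten seconds; the identities being checked are
size-independent.

Numerical tolerances: zero residual sums of squares are detected at 1e-12
relative to the largest column; exactness assertions use 1e-8 to 1e-10
relative error (float64 lstsq noise across two independent solution paths);
chunk invariance is asserted at 1e-12 absolute because chunking only
re-slices identical vectorized arithmetic. Floating-point output is written
at 17 significant digits and read back with round-trip parsing, so file
round trips are bit-exact.

## Known limitations

- Only linear association models are supported; mixed-model summary
  statistics would each need method-specific covariance handling, which is
  out of scope.
- Heterogeneous per-variant sample sets across features violate the
  shared-sample assumption; the sample-size minimum is an accounting
  convention, not a correction.
- The covariance file format stores a single normalization constant;
  per-chromosome covariance matrices (as some mixed-model pipelines would
  require) are not modeled.
- `read_matrix` loads matrices into memory; the chunked/threaded paths
  apply to the scans themselves, not to file parsing.
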