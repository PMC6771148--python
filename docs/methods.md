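# Methods

## Model and assumptions

The package treats each observed quantitative measure as a noisy indicator
of one of a small number of correlated latent traits. For a pool of
row-disjoint datasets over a common catalog of p measures, the working model
is an oblique common-factor model on the correlation metric:

    R ≈ Λ Φ Λᵀ + Ψ

with Λ the p×k standardized loading matrix, Φ the k×k factor correlation
matrix, and Ψ the diagonal uniquenesses. The assumptions inherited from
factor analysis apply: (approximate) normality, linear relations between
measures, a large subject-to-measure ratio, and a genuine factor structure
in the correlations. Subjects must be disjoint across datasets; cross-dataset
record linkage is out of scope.

Harmonization rests on two constraints applied per dataset: every dataset
uses the *same* composite correlations, and the *same* Φ. Loadings of
measures a dataset never observed are exact zeros. Under these constraints
the per-dataset regression score weights W_d = (R_AA)⁻¹ Λ_A Φ produce factor
scores on one common scale, so the per-dataset score tables can be
concatenated and analyzed as a single dataset.

## Pipeline stages and numerical choices

**Pairwise-complete composite correlation.** Each entry is computed over the
pooled subjects observing both measures (pandas pairwise-complete Pearson).
Every pair must have ≥ 3 joint observations; pairs below that threshold are
an error — imputing entries *of the correlation matrix* is deliberately
unsupported. Dataset-specific effects on correlations are ignored by design.
Pairwise counts N are recorded for reporting but do not weight the factor
fit.

**PSD smoothing.** If the smallest eigenvalue of R is below −1e−8, R is
replaced by the nearest correlation matrix (alternating projections with
eigenvalue clipping, `statsmodels.stats.correlation_tools.corr_nearest`);
the adjustment and the pre-smoothing eigenvalue are recorded. Convergence is
verified by re-checking the spectrum.

**Conditioning gate.** Downstream stages refuse to run when the composite
matrix cannot support a factor model: condition number above 1e10
(numerically singular even after smoothing), or mean within-domain
correlation below 0.2 in any domain (no usable factor structure — in this
regime a factor explains < 4% of an indicator's variance). The 0.2 boundary
is where the method's assumptions genuinely fail; the condition-number gate
is set well above the ~1e9 values produced by legitimate extreme-correlation
designs but far below the point where float64 solves lose accuracy. Without
domain labels the fallback check is the mean absolute off-diagonal.

**Extraction.** Principal-axis factoring: initial communalities are squared
multiple correlations (fallback: max |row correlation| if R is
near-singular); the reduced matrix (communalities on the diagonal) is
eigen-decomposed, loadings formed from the top-k eigenpairs, communalities
re-estimated from squared loadings, iterated until the largest communality
change is < 1e−6 (max 5000 iterations — near-singular composites approach
the Heywood boundary h² = 1 and converge slowly; each iteration is one
small-matrix eigh, so the cost is negligible). A non-positive retained
eigenvalue is an error: the data cannot support k factors. Maximum-likelihood
extraction is out of scope.

**Rotation.** The factor correlations are the harmonization constraint, so
the rotation must be oblique; the default is oblimin (quartimin), solved by
gradient projection with 10 random orthogonal restarts (fixed internal seed;
the result is deterministic given R). Restarts matter: from a single start
the gradient-projection algorithm reliably lands in a degenerate local
optimum on block-symmetric matrices. Promax and no rotation are available.
After rotation, Φ is rescaled to an exact correlation matrix, each factor's
largest-magnitude loading is made positive, and factors are ordered by their
anchor measure, making output labels deterministic.

**Score weights and scoring.** W = R⁻¹ΛΦ (Thurstone regression weights).
Measurements are standardized with means/SDs pooled over every dataset
observing each measure — a per-dataset standardization would re-introduce
dataset shifts and break commensurability. Rows with individually missing
cells are scored with weights recomputed on the composite submatrix of the
measures the subject actually has, rather than zero-filled (zero-filling
shrinks scores toward the mean asymmetrically across datasets). A subject
observing no measures is an error.

**Per-dataset constrained fit.** Default `mode="refit"` re-estimates the
available-measure loadings by least squares against the composite submatrix
off-diagonals with Φ fixed, under the confirmatory pattern implied by the
composite model: each measure loads only on its dominant composite factor.
The pattern is what makes the fit identified — a dense per-dataset Λ has
more free parameters than off-diagonal residuals and can run away to
Heywood-type solutions. `mode="subset"` simply reuses the composite
loadings; because all datasets share the same correlations, the two modes
agree asymptotically (per-subject scores correlate > 0.995 in the simulated
designs), and the least-squares discrepancy function is a package choice —
the constrained fit could equally be cast as ML.

## Simulation design

The generator draws n i.i.d. 9-vectors from N(0, Σ), where Σ has
compound-symmetric 3×3 within-domain blocks (off-diagonal ρ_within) and
constant cross-domain entries ρ_between, then splits them into three equal
row-disjoint studies (defaults n = 3000, i.e. 3×1000). The *test condition*
deletes one measure per domain per study so that every measure survives in
exactly two studies and none is common to all three — the extreme
missingness pattern the harmonizer is designed for. Two deletion patterns
are provided (`aligned`, study s loses the s-th measure of each domain;
`rotated`, the lost index advances per domain) because the literature the
design follows does not pin the pattern down.

Under this parameterization the cross-domain *measure* correlation is
ρ_between directly, so the implied latent-trait correlation is
ρ_between/ρ_within (squared loadings ρ_within); parameter-recovery checks on
Φ target that implied value. Case status for the power study is defined once
on the complete data (measure 1 > 1 population SD, expected case fraction
≈ 0.159) and shared by all benchmarked methods, which therefore differ only
in how they analyze the outcome (measure 7, domain 3).

What the generator does *not* emulate: non-normal or ordinal measures,
dataset-specific shifts or scale differences, population substructure,
outliers, or unequal loadings within a domain. Passing tests therefore show
that the pipeline recovers what the idealized factor model can represent —
they do not certify performance on real cohort quirks, which is exactly the
gap the conditioning diagnostics are meant to surface at run time.

The clinical-cohort-like preset (`study2_preset`) is approximate and
synthetic: only the three between-trait correlations (0.952, 0.741, 0.763)
of the source cohort are published, and the within-domain level defaults to
0.75. The between values are applied at the *trait* level (measure-level
cross entries ρ_within·ρ_between); placing 0.952 at the measure level would
exceed the within-domain correlations and force an indefinite, structurally
incoherent matrix. With two traits correlated at 0.95 the factor solution
sits at the edge of rotational identifiability — the collapsed two-factor
solution can genuinely win the oblimin criterion on some samples — so
validation of this preset targets the identifiable structure (the two
best-determined traits and the top two canonical dimensions) rather than all
three diagonals.

## Benchmark methods

* **truth** — Welch t-test of the raw outcome on the complete data.
* **rosetta** — Welch t-test of the domain-matched factor score harmonized
  from the incomplete pool (factors matched to domains by maximal loading
  mass, Hungarian assignment). Pipeline refusals (conditioning gate) count
  as failures.
* **imputation** — multiple imputation by chained Bayesian normal-linear
  regressions, implemented vectorized in-package: each incomplete column is
  regressed on all others, σ² drawn from its scaled inverse-χ², β from its
  normal posterior, missing cells from the posterior predictive; m = 5
  chains × 50 sweeps (defaults), Welch test per completed dataset, Rubin's
  rules for pooling. With two-thirds of a column systematically missing and
  m = 5, Rubin's variance is inflated and the pooled test is mildly
  conservative (observed type-I ≈ 0.02 at nominal 0.05) — textbook MI
  behavior at high missing fractions, not an implementation artifact. A pool
  with no missing cells short-circuits to the complete-data test.
* **meta** — per-study Welch mean differences in the studies retaining the
  outcome, pooled by fixed-effect inverse variance (the closed form;
  cross-checked against statsmodels in the tests). A random-effects model is
  out of scope.

Power is the fraction of replicates with p < 0.05, failures counting as
non-rejections in the denominator; 25 replicates per grid cell by default.
The −log p summaries average over successful replicates only.

## Problem sizes used in the test suite

Fidelity and power checks run at the full study scale (n = 3000, 25
replicates). Calibration properties run at n = 600 (3×200): the type-I error
of a calibrated test does not depend on n (200 replicates at ρ_between = 0),
and power monotonicity in ρ_between is only informative away from the
saturation plateau that n = 3000 reaches immediately (100 replicates per
level). These sizes are the package's choices for a desk-scale reproduction.

## Known limitations

* The number of factors k is never inferred; the user must supply it.
* Factors correlated above ~0.9 are not reliably separable by any analytic
  oblique rotation from block-symmetric data; the canonical-correlation
  structure of the scores remains intact, but individual trait labels become
  unstable.
* Correlations are pooled across datasets without covariate adjustment or
  dataset random effects; heterogeneous cohorts violate this silently (the
  conditioning report cannot detect it).
* Pairs of measures never co-observed anywhere in the pool are a hard error,
  not an imputation target.
* The within-domain warning threshold (0.2) and the PSD tolerance (1e−8) are
  fixed defaults, not data-adaptive.
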