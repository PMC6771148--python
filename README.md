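# rosetta-harmonize

Latent-factor harmonization of row-disjoint datasets with only partially
overlapping measurements.

## The problem

Cohort studies that target the same constructs rarely collect the same
columns: one study measures reading with tests X and Y, another with Y and Z.
Whole measures are then *systematically missing* from entire datasets, which
rules out naive concatenation and strains multiple imputation (designed for
modest missing-at-random gaps). Meta-analysis combines per-study statistics
instead of data, at a cost in power and modeling flexibility.

This package harmonizes such collections into a single analyzable table of
per-subject latent trait scores. It is aimed at biostatisticians and
informatics researchers pooling public or multi-site cohort data in which
groups of quantitative measures are interchangeable indicators of common
latent traits.

## The method

Given datasets that are disjoint in subjects and only partially overlapping
in measures, with a catalog of p measures and a user-chosen number of
factors k:

1. **Composite correlation.** Every Pearson correlation r_ij is computed on
   the pooled set of subjects observing both i and j, across all datasets —
   each entry uses the largest sample the pool can offer, including pairs
   never co-observed within any single dataset.
2. **PSD smoothing.** Pairwise-complete assembly does not guarantee a
   positive semidefinite matrix; if needed, R is projected to the nearest
   correlation matrix. A conditioning gate refuses to continue when R is
   numerically singular or the within-domain correlations are too weak to
   carry a factor structure (mean within-domain r < 0.2).
3. **Factor model.** Principal-axis factoring with iterated communalities
   extracts Λ (p×k loadings) and h²; an oblique rotation (oblimin by
   default) yields the factor correlation matrix Φ; regression score weights
   are W = R⁻¹ΛΦ.
4. **Per-dataset constraints.** Each dataset reuses the *same* composite
   correlations and the *same* Φ — the constraint that makes factors
   equivalent across datasets. Loadings of measures a dataset never observed
   are structural zeros; the remaining loadings are re-estimated by a
   constrained least-squares fit (or copied, `mode="subset"`). Per-dataset
   weights W_d = (R_AA)⁻¹ Λ_A Φ are computed on the composite submatrix of
   the available measures A.
5. **Scores.** Each subject's k factor scores are their pooled-standardized
   available measurements times W_d. The per-dataset score tables are
   concatenated into one complete table — a mega-analysis-ready dataset with
   k columns (k < p) and no missing values.

The output is commensurate across datasets by construction; it is an
algorithm, not a hypothesis test — no fit statistics or p-values are
attached.

## Worked example

```python
import numpy as np
from rosetta import (
    SigmaSpec, StudyConfig, ExtractionConfig,
    simulate_control, apply_test_condition, harmonize, score_correlation_table,
)

# three studies of 1000 subjects, nine measures in three domains;
# each study loses a different measure per domain (no measure common to all)
spec = SigmaSpec(rho_within=0.75, rho_between=0.5)
control = simulate_control(spec, StudyConfig(n_total=3000, seed=42))
test = apply_test_condition(control, "aligned")

scores = harmonize(test, ExtractionConfig(k=3))
print(scores.frame.head(3).round(3))
print("factor correlations:\n", scores.model.Phi.round(3))

full = harmonize(control, ExtractionConfig(k=3))
table = score_correlation_table(scores, full)
print("diagonal fidelity:", table.diagonal.round(3))
```

prints

```
  subject_id dataset_id     D1     D2     D3
0   st1-0001     study1 -0.166 -0.666 -0.202
1   st1-0002     study1 -0.023  0.367 -0.429
2   st1-0003     study1  0.549  0.552  0.237
factor correlations:
 [[1.    0.671 0.701]
 [0.671 1.    0.677]
 [0.701 0.677 1.   ]]
diagonal fidelity: [0.981 0.98  0.98 ]
```

Each subject receives three complete trait scores (D1–D3) even though every
study is missing one measure per domain. The factor correlations sit near
0.5/0.75 ≈ 0.67, the trait correlation implied by the generating block
structure (cross-domain measure correlation 0.5, squared loadings 0.75). The
diagonal fidelity values are the Pearson correlations between each
harmonized trait score (computed from the incomplete pool) and the matching
trait score computed from the complete data: ≈ 0.98 here, i.e. almost
nothing is lost to the missingness.

The same pipelines are scriptable from the shell:

```bash
rosetta simulate --within 0.75 --between 0.5 --n 3000 --seed 17 --out sim/
rosetta harmonize --data sim/study1.csv --data sim/study2.csv --data sim/study3.csv \
    --catalog sim/catalog.csv --factors 3 --out scores.csv
rosetta benchmark --within 0.75 --between 0.4 --replicates 25 --seed 11 --out bench/
```

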