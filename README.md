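# traitscape

Multivariate trait plasticity and microsatellite clonal diversity for
hybrid and allopolyploid *Spartina* (syn. *Sporobolus*) cytotypes.

Whole genome duplication (WGD) changes cell sizes and, through
allometry, whole-plant functional traits. Whether it also changes
*phenotypic plasticity* — the ability of one genotype to express
different phenotypes in different environments — is best asked in
*Spartina*, where the homoploid F1 hybrid *S. × townsendii* and its
allododecaploid descendant *S. anglica* coexist in Wadden Sea salt
marshes with almost no genetic diversity. `traitscape` implements the
complete computational workflow for such a study, for ecologists and
evolutionary biologists analysing factorial greenhouse experiments on
clonal plants:

* **SSR clonal diversity** — multilocus genotype calling from per-locus
  allele (fragment-size) sets treated as dominant presence/absence
  markers, per-locus and per-genotype frequency tables, allele-difference
  dissimilarity matrices, and tie-retaining minimum spanning networks.
* **Trait-scape ordination** — regularized iterative PCA imputation of
  missing trait values followed by a standardized (correlation-matrix)
  PCA on the six functional traits (stomatal length, root:shoot ratio,
  leaf area, stem height, stem diameter, stem density).
* **Plasticity indices** — the multivariate plasticity index for a
  genotype across an ambient/treatment contrast,

  ```
  ED(X, Y) = sqrt( Σ_{i=1..k} (CV_i(X) − CV_i(Y))² )          (k = 6 traits)
  MVPi     = ( Σ_{x=1..n} Σ_{y=1..m} ED(x, y) ) / (n·m)
  ```

  the mean Euclidean distance in the full k-dimensional score space over
  all n×m cross-environment replicate pairs, plus the plant trait
  variation index (mean distance of an individual's ambient replicates
  to the pooled ambient centroid). Because the full-rank standardized
  PCA is an isometry, these equal the corresponding distances computed
  directly on centered, unit-variance trait values.
* **Inference** — per-response Box-Cox transformation (profile-ML λ),
  three-way factorial ANOVA `response ~ cytotype * (water * co2)` with
  sequential sums of squares, Tukey HSD post-hoc comparisons
  (exact studentized-range distribution), Shapiro–Wilk and
  Brown–Forsythe/Levene assumption checks, one-way ANOVAs on the
  indices, and relative biomass-decrease summaries.
* **Allometry** — the leaf-area calibration
  `area = 86 + 0.63224 · width · length` as a fit/predict model.
* **Synthetic data** — a generator for the full-factorial design
  (6 individuals × 2 water × 2 CO₂ × 6 replicate pots = 144 pots, with
  21 dead/senescent and 9 removed, leaving 114 analysed survivors) and
  for clonal SSR populations dominated by one multilocus genotype, so
  the entire pipeline is testable without any data download.

The estimator-style components (`IterativePCAImputer`, `TraitScapePCA`,
`LeafAreaModel`) follow scikit-learn conventions (`fit`/`transform`/
`predict`, trailing-underscore fitted attributes) and compose with
sklearn pipelines.

## Worked example

```python
import numpy as np, pandas as pd
import traitscape as ts

design = ts.DesignSpec(seed=1)                     # 144-pot factorial design
records = ts.generate_greenhouse(design, ts.default_trait_model())
print(len(records), int(records.survived.sum()))
# 144 114

survivors = records[records.survived].reset_index(drop=True)
completed = ts.impute_missing(survivors[list(ts.FUNCTIONAL_TRAITS)])
scape = ts.fit_trait_scape(completed)
print(np.round(scape.explained_variance_ratio_[:2], 3))
# [0.459 0.201]

full = pd.concat([survivors.drop(columns=list(ts.FUNCTIONAL_TRAITS)),
                  completed], axis=1)
res = ts.plasticity_by_contrast(scape, full, group_by="cytotype")
print(res.indices.round(3).head(4).to_string(index=False))
#         group           contrast  mvpi  n  m
# allopolyploid DR-aCO2 vs WW-aCO2 3.070 16 14
# allopolyploid WW-eCO2 vs WW-aCO2 2.589 16 13
# allopolyploid DR-eCO2 vs WW-aCO2 3.061 16 10
# allopolyploid DR-eCO2 vs DR-aCO2 2.511 14 10
```

`records` is one row per pot with factor levels, a survival flag and the
measured traits; `impute_missing` completes the survivors' trait matrix;
the first two trait-scape dimensions here explain 46% + 20% of the
standardized trait variance; and each `mvpi` row is the mean pairwise
score-space distance between the `n` ambient-reference pots and the `m`
treatment pots of one cytotype (e.g. drought under ambient CO₂ vs the
well-watered/ambient reference). A factorial ANOVA on biomass with
Box-Cox transformation shows the expected dominant water-availability
effect on this synthetic population:

```python
anova = ts.factorial_anova(records, "biomass", transform="boxcox")
print(anova.table.round(3)[["df", "F", "PR(>F)"]])
#                                df        F  PR(>F)
# C(cytotype)                   1.0   39.937   0.000
# C(water)                      1.0  280.041   0.000
# ...
# Residual                     16.0      NaN     NaN
```

The same analyses are available from the shell:

```bash
traitscape --seed 1 -o runs/demo all        # every stage + manifest.json
traitscape --seed 1 -o runs/ssr ssr         # genotypes, frequencies, MSN
```

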