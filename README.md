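# wingmorph

Traditional versus geometric morphometrics for discriminating
closely-related bat species from wing form.

European horseshoe bats (*Rhinolophus*) overlap in size and are
notoriously similar in external morphology. Field workers and
ecomorphologists have long compared species with wing *ratios* — tip
length ratio T_l, tip area ratio T_s, wingtip shape index
I = T_s/(T_l − T_s), aspect ratio A = b²/S, wing loading WL = Mg₀/S —
or with digit lengths size-corrected against forearm length, while
landmark-based geometric morphometrics promises to capture localized,
relational shape differences those summaries miss. `wingmorph` is a
tested, reusable implementation of that whole comparison for anyone who
works with 2D wing (or other) landmark data:

- **TPS I/O** for digitized landmark files plus specimen/measurement CSVs;
- **generalized Procrustes analysis** (full Procrustes scaling), tangent
  projection, and a nested **Procrustes ANOVA** that audits digitizing
  error across fixations and photos;
- **allometric correction** by pooled within-group regression of shape on
  centroid size (CS), with a permutation homogeneity-of-slopes test;
- the three classical **traditional variable sets** (ratios; ratios with
  relative wing loading WL/M^⅓ and the tail-to-wing area ratio; digit
  length residuals on forearm) derived from the same landmarks;
- **leave-one-out cross-validated discriminant analysis** — pairwise LDA
  and multi-group canonical variate analysis with pseudo-inverse pooled
  covariances — plus PCA reduction with Anderson's test;
- **between-group PCA** ordination (unweighted species means, specimen
  scores, percent of total variance), pairwise **Procrustes-distance
  permutation tests**, and mirrored "bat-like" wireframe exports;
- a **synthetic-data generator** that emulates the five-species study
  design (n = 6/7/22/20/21, 17 landmarks, 2 fixations, 3 photos kept,
  hierarchical digitizing error, static and evolutionary allometry) with
  recorded ground truth, so every stage is testable end to end without
  any data download.

## Worked example

Simulate a study and run the full comparison (all numbers below are the
actual output of this command):

```bash
wingmorph run --seed 4 --out out/ --n-perm 199
```

```
                     overall  R_hipposideros  R_blasii  R_euryale  R_mehelyi  R_ferrumequinum  pairwise_average  pairwise_min  pairwise_max
method1                 47.4            66.7      57.1       40.9       25.0             66.7              79.4          55.2          97.7
method2                 48.7            33.3      57.1       50.0       35.0             61.9              83.9          54.8         100.0
method3                 51.3            66.7     100.0       68.2       30.0             33.3              81.6          56.1         100.0
method4                100.0           100.0     100.0      100.0      100.0            100.0              98.1          86.2         100.0
method4_uncorrected     93.4           100.0     100.0       90.9       85.0            100.0              98.3          90.5         100.0

allometry: 14.39% of within-species shape variance
bwgPC percents: 87.52, 2.32, 1.02, 0.78
bwgPC1 ~ size R^2: 0.815 (p = 0.005)
```

Reading this: each row is one variable set, each cell a leave-one-out
correct classification rate in percent. The ratio-based sets (methods 1
and 2) and the digit-length residuals (method 3) separate the
size-extreme species but confuse the intermediate ones; the full
landmark configuration (method 4) identifies every bat, and still
reaches 93.4% when the allometric correction is skipped — worse than
with correction, better than any traditional set. The pooled
within-group regression attributes 14.4% of within-species shape
variance to size; the first between-group principal component carries
87.5% of total shape variance and its scores are strongly predicted by
centroid size (R² = 0.82), the signature of evolutionary allometry.
`out/` receives the rate tables, the Procrustes-distance/p-value matrix,
the Procrustes ANOVA, a bwgPC1–bwgPC2 scatterplot and per-species
wireframe SVGs against the grand mean.

Other entry points: `wingmorph simulate` writes a TPS + CSV dataset,
`wingmorph compare` prints only the rate table, `wingmorph shapes`
exports the ordination and wireframes; `--profile full` raises the
permutation count to 10,000. The same pipeline runs on real data with
`--tps landmarks.tps --table specimens.csv`.

As a library:

```python
from wingmorph import (default_config, simulate_dataset, gpa,
                       project_tangent, average_replicates,
                       pooled_within_group_regression, between_group_pca)

ds = simulate_dataset(default_config(seed=1))
aligned = gpa([c.coords for c in ds.configurations],
              provenance=ds.specimen_table)
shapes = average_replicates(project_tangent(aligned), aligned)
model = pooled_within_group_regression(shapes)
ordination = between_group_pca(model.corrected_dataset(shapes))
```

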