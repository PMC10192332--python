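# amlmeta

Ensemble meta-clustering for patient stratification from mixed
clinical/genetic cohort data, modelled on intensively treated acute myeloid
leukemia (AML) cohorts.

## The problem

Risk stratification in AML is usually hypothesis-driven (decision-tree
rules over a handful of genetic markers). An alternative is unsupervised
learning over *all* baseline information — demographics, laboratory values,
karyotype, mutation flags — but any single clustering algorithm is an
arbitrary choice and different algorithms give different partitions.
`amlmeta` implements the ensemble answer:

1. **Preprocess** a mixed-type patient table into a numeric matrix:
   features present in < 1% of patients are dropped, categoricals are
   one-hot encoded (unknown → all-zero block), continuous labs are
   median-imputed and z-scored. Outcome and post-baseline columns
   (CR, EFS/RFS/OS, transplant status) are firewalled out of clustering.
2. **Grid** over 11 transformation algorithms × target dimensionalities
   2–6 × 11 clustering algorithms = **605 combinations**, each repeated for
   10 seeded iterations. Every run is scored with silhouette,
   Calinski-Harabasz and Davies-Bouldin indices and vetted by a **sanity
   check**: 2–10 clusters, every cluster ≥ 10% of the cohort. Incompatible
   pairings fail gracefully and are discarded.
3. **Meta-cluster**: the label vectors of all passing runs are stacked into
   a block one-hot membership matrix *M* (one indicator block per run), so
   ‖*M<sub>i</sub>* − *M<sub>j</sub>*‖² = 2 × #(runs that separate patients
   *i* and *j*). Principal component analysis maps *M* to 3-D and mean
   shift on that embedding yields the final consensus clusters — averaging
   all valid runs instead of picking a "winner".
4. **Outcome statistics** per final cluster, vs the remaining patients:
   logistic-regression odds ratios for complete remission, Kaplan-Meier
   medians + log-rank tests and Cox hazard ratios (Efron ties) for
   EFS/RFS/OS, Fisher / Shapiro-gated ANOVA-vs-Kruskal-Wallis baseline
   contrasts, Benjamini-Hochberg adjustment per test family (α = 0.05,
   two-sided).
5. **Label transfer**: cluster assignments become class labels; naive
   Bayes, gradient boosting, random forest and logistic regression are
   compared on a stratified 80:20 split (macro one-vs-rest AUROC,
   precision, recall, F1) and the best model assigns clusters to an
   external cohort, preprocessed strictly with the original cohort's
   fitted statistics.

Real multi-center AML registries are not redistributable, so the package
ships a synthetic cohort generator (`amlmeta.cohort`) with planted
clusters: cluster-specific mutation prevalences, karyotype mixes,
log-normal labs, MCAR missingness, and cluster-linked outcomes
(Bernoulli CR; exponential survival with exponential censoring, median
ln 2/λ). Every pipeline stage is tested against it.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from amlmeta import (generate_cohort, assemble_matrix, reduced_registry, run_grid,
                     build_membership_matrix, reduce_and_cluster, outcome_report,
                     train_and_evaluate)
from amlmeta.cohort import separated_spec
from amlmeta.grid import collect_passing
from amlmeta.stats import report_to_frame

spec = separated_spec(n_patients=800, seed=42)     # 4 planted clusters
cohort = generate_cohort(spec)
matrix = assemble_matrix(cohort)
results = run_grid(reduced_registry(), matrix, master_seed=42, n_iterations=10)
passing = collect_passing(results)
model = reduce_and_cluster(build_membership_matrix(passing), d=3)
print(adjusted_rand_score(cohort.true_labels, model.labels))
report = outcome_report(cohort, model.labels)
print(report_to_frame(report)[["cluster", "n", "cr_rate", "cr_or", "os_median", "os_hr"]])
```

prints (reduced 32-combination demo grid, ~1 minute):

```
clustering matrix: 800 patients x 45 features
320 of 320 grid runs passed the sanity check
4 meta-clusters (mean-shift bandwidth 11.83)
adjusted Rand index vs planted clusters: 0.994
 cluster   n  cr_rate  cr_or  os_median  os_hr
       0 211    0.858  6.221     37.052  0.471
       1 202    0.327  0.231      8.100  3.104
       2 194    0.644  1.361     24.119  0.809
       3 193    0.513  0.665     17.291  1.123
```

The consensus recovers the four planted clusters almost exactly
(ARI 0.994). Cluster 1 is the planted high-risk group: complete-remission
odds less than a quarter of the remaining patients (OR 0.23), median
overall survival 8.1 months against a planted 8 months, and a three-fold
hazard (HR 3.10); cluster 0 mirrors the planted favorable group.

## Command line

```sh
amlmeta simulate --spec aml --n 1383 --seed 0 --out cohort
amlmeta preprocess --in cohort.csv --schema cohort.schema.yaml --out matrix.csv
amlmeta grid --matrix matrix.csv --registry full --seed 0 --out grid.csv
amlmeta run --seed 0 --out demo_run          # whole pipeline, demo-sized
amlmeta run --seed 0 --out full_run --full   # full 605-combination grid
```

`amlmeta run` persists every stage (cohort, matrix, grid metrics, 3-D
meta-embedding, outcome report, transfer report) plus a manifest of
SHA-256 checksums; reruns with the same master seed are byte-identical.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch on a freshly simulated demo
cohort (simulate → preprocess → grid → meta-cluster → outcome statistics →
label transfer) under the given seed and writes the results JSON.

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
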