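# Methods

This note documents the statistical procedures implemented in `amlmeta`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not establish.

## Preprocessing

Order is fixed and deterministic: sparse filter → one-hot → median
imputation → z-score.

* **Sparse filter.** Binary features (and individual categorical levels)
  present in strictly less than 1% of patients are removed *before*
  one-hot expansion; a feature at exactly the threshold survives.
  Continuous features are never removed. Rationale: distance-based
  embeddings destabilize when near-empty indicator dimensions inflate the
  model space relative to the sample size.
* **Unknown categoricals.** A patient with a missing categorical value
  receives an all-zero indicator block. This is the unique fixed-dimension
  encoding in which the feature contributes nothing to that patient's
  position in the model space — the rectangular-matrix equivalent of
  dropping the feature for that patient only. Patients whose level was
  removed by the sparse filter are treated the same way.
* **Imputation.** Continuous missing values take the column median of the
  *observed* values — single-valued and reproducible, unlike multiple
  imputation, which would produce a different clustering on every rerun.
  Missing binary flags (absent by default in the generator, possible in
  real data) are filled with 0 under the same absence-of-evidence
  convention. Outcome columns are never imputed; analyses drop the
  affected patients.
* **Scaling.** Continuous columns are standardized with the sample (n−1)
  standard deviation; the parameters are retained so values can be mapped
  back to original units exactly. Zero-variance columns map to all zeros
  rather than erroring, because one-hot blocks can legitimately become
  constant after filtering. Whether to impute before or after scaling is
  underdetermined; imputing first means the scaler sees a complete column
  and the imputed value lands exactly at z = 0 by construction of the
  median only when mean = median — the choice is logged and affects
  results only marginally.
* **Outcome firewall.** Columns declared `outcome_*` or `post_baseline`
  (CR, survival times/flags, transplant status) are excluded from the
  clustering matrix structurally — the matrix constructor rejects them —
  and this is asserted end-to-end in the tests.

## The grid

11 embedding algorithms × dimensionalities {2,…,6} × 11 clustering
algorithms = 605 combinations, each run for 10 iterations with
per-(combination, iteration) seeds derived from the master seed via
`numpy.random.SeedSequence` spawn keys, so results are identical under any
execution order or parallelization.

The registry ships with: PCA, kernel PCA (RBF), truncated SVD, FastICA,
factor analysis, NMF on shifted data, metric MDS, Isomap, locally linear
embedding, spectral embedding, t-SNE; and k-means, mini-batch k-means,
Ward and average-linkage agglomerative, Birch, Gaussian mixture, spectral
clustering, mean shift, DBSCAN, OPTICS, affinity propagation. Both lists
are configuration — counts are asserted, identities are a reasonable
covering set of sklearn's standard offerings, not a canonical truth.

Open choices, resolved as follows:

* **k selection.** Algorithms that need a preset cluster count sweep
  k = 2…10 within the run and keep the silhouette-best partition, so every
  combination contributes exactly one partition per iteration.
* **Noise points.** DBSCAN/OPTICS noise labels are reassigned to the
  nearest cluster centroid (Euclidean, in the embedded space) before the
  sanity check; an all-noise run fails.
* **Failures.** Any exception inside a combination (target dimensionality
  exceeding the input rank, non-convergence, degenerate partitions) is
  captured as a failed result with a reason string; the grid never aborts.

**Sanity check.** A partition passes iff it has between 2 and 10 clusters
and every cluster holds at least ⌈0.10 · n⌉ patients (boundaries
inclusive). The 10%-minimum implies the 10-cluster cap. All iterations of
every passing run feed meta-clustering (no best-of-10 selection; averaging
valid outputs is the point).

**Internal indices.** Silhouette (mean over points of (b−a)/max(a,b)) and
Calinski-Harabasz come from scikit-learn; Davies-Bouldin is computed
in-module from its definition with difference-based distances, because the
expanded-form ‖x‖²−2x·y+‖y‖² shortcut loses ~1e−8 to cancellation and the
tests require 1e−9 agreement with independent from-the-formula oracles.

## Meta-clustering

The membership representation is a block one-hot matrix: each passing run
contributes one indicator column per cluster it found. For patients i, j
the squared Euclidean row distance is exactly 2 × (number of runs that
separate them) — verified against a brute-force disagreement count — so
this is, up to scaling, evidence-accumulation consensus clustering in
feature form. PCA (full SVD, deterministic) reduces the matrix to 3
dimensions (matching the 3-D visual export; configurable) and mean shift
labels every patient.

**Bandwidth.** Consensus embeddings are strongly bimodal: near-zero
distances within consensus groups, large distances between them. With g
equal groups only ~1/g of pairwise distances are within-group, so a raw
0.3 distance quantile can land *on the between-group separation* (measured:
with 4 equal planted clusters it returns the inter-blob distance itself
and mean shift collapses everything to one cluster). The auto policy is
therefore **0.5 × the 0.3-quantile of pairwise embedding distances**: the
quantile estimates the separation scale, and a flat kernel resolves groups
only when its radius is below that separation. On the planted-partition
benchmark any bandwidth in roughly [5, 13] recovers the four clusters
(ARI 0.994); the halved quantile gives 11.8. A (near-)zero estimate means
the ensemble is unanimous; patients are then grouped by identical embedding
rows, which reproduces the shared partition exactly. The final cluster
count remains bandwidth-sensitive in general — an explicit bandwidth can
always be supplied.

## Outcome statistics

All comparisons are cluster-vs-remainder on a membership indicator
("comparison to the overall sample" is ill-posed for a regression against
a sample containing the cluster itself). Two-sided, α = 0.05.

* **CR odds ratio**: 2×2 cross-product with Wald 95% CI — algebraically
  the indicator logistic regression estimate (asserted against a
  statsmodels fit in tests). Zero cells get the Haldane-Anscombe 0.5
  correction and a flag.
* **Survival**: lifelines Kaplan-Meier (median = first time the curve
  reaches 0.5, infinity when never reached), k-group log-rank, Cox with
  Efron tie handling (ties are measure-zero in the exponential generator
  but real data has them) and Newton precision 1e−9 so estimates agree
  with a brute-force partial-likelihood maximizer to 1e−3. Additional
  covariates extend the model for multivariable analysis.
* **Baseline contrasts**: Fisher exact for 2×2; seeded Monte-Carlo Fisher
  (100 000 tables from the fixed-margin hypergeometric null, probability
  ordering, +1 correction) for larger tables. Continuous variables take
  ANOVA only when Shapiro-Wilk accepts normality in every group (groups
  subsampled to 5 000 for the test's validity range); otherwise
  Kruskal-Wallis. Constant variables return p = 1, flagged.
* **Multiplicity**: Benjamini-Hochberg step-up within each declared family
  (the CR odds ratios form one family; each baseline-variable panel forms
  another).

## Label transfer

Stratified 80:20 split (stratification by meta-cluster keeps every cluster
in both halves). Multiclass AUROC is macro one-vs-rest; precision, recall
and F1 are macro. Selection is AUROC-argmax with ties broken by panel
order (naive Bayes, gradient boosting, random forest, logistic
regression). The selected architecture is refit on 100% of the original
cohort before external assignment — the 80% fit was only for model
comparison. External cohorts are transformed with the original cohort's
fitted preprocessing statistics only (no leakage; asserted in tests), and
a missing-feature external cohort triggers a refit on the expanded-feature
intersection.

## Synthetic cohorts

The generator emulates the statistical shape of an intensively treated
adult AML registry: ~20 binary mutation flags at cluster-specific
prevalences, a 6-level karyotype categorical, log-normal WBC/LDH/platelets
and normal age/Hb/blast labs, MCAR missingness (5.9% karyotype, 0.2–7.4%
labs, none for age/sex/mutations), Bernoulli CR, and per-cluster
exponential EFS/RFS/OS with independent exponential censoring (median
survival ln 2/λ gives closed-form checks). The default `aml` spec plants
4 clusters with weights 424:256:536:167 / 1383 echoing a
NPM1/FLT3-ITD-driven, an adverse TP53/complex-karyotype, an intermediate
CBF-enriched and a favorable CEBPA-driven profile; default cohort sizes
are 1383 (original) and 664 (external). The `separated` spec used in the
recovery experiments plants 4 equal clusters with prevalence gaps of 0.55
across 40 binary features and 1.5-sd staggered shifts in 5 continuous
features.

Known departures from real registries: features are conditionally
independent given the cluster (no mutation co-occurrence structure beyond
what the cluster induces), missingness is MCAR, survival is exponential
(constant hazards, no cure fraction), and planted clusters are crisper
than biology. A green recovery test therefore establishes that the
pipeline machinery recovers structure *that matches its assumptions*; it
does not certify performance on real cohorts, whose cluster count and
quality-metric ranges are data-dependent.

## Numerical and degenerate-input conventions

* Seeds everywhere derive from a single master seed and stay below 2³¹.
* PCA uses the full (deterministic) SVD solver in meta-clustering.
* Zero-variance columns → zeros; all-missing continuous column → error.
* Metrics are undefined (distinctly signalled) for < 2 clusters or an
  all-singleton partition.
* Davies-Bouldin ratios with coincident centroids are excluded from the
  per-cluster maximum; a two-cluster duplicated-point partition scores 0.

## Limitations

* The grid's algorithm identities and per-algorithm hyperparameters are a
  configuration default, not a tuned set; t-SNE/MDS/spectral members are
  slow on cohorts of thousands, so demos use a 4 × 2 × 4 reduced registry.
* Mean-shift's cluster count depends on the bandwidth policy; the auto
  rule is principled for bimodal consensus geometries but not universal.
* Multivariable Cox support accepts arbitrary covariate frames; no
  proportional-hazards diagnostics are included.
* No competing-risk models; relapse-free survival is analyzed as a single
  right-censored endpoint.
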