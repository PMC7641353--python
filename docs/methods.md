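# Methods

This note documents the models and procedures implemented in `mmtme`, the
assumptions behind them, the tunable parameters and their defaults, what the
synthetic-cohort generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Data model

Expression is held linear-scale internally (genes × samples, non-negative
finite intensities); log2 inputs are converted once at load, controlled by
an explicit flag rather than a heuristic, because mixing and tumor
subtraction are linear-space operations. Percentages are 0–100 in every
user-facing table, fractions 0–1 internally. Clinical records carry PFS/OS
months with event flags, treatment-stage time points (pretreatment,
postinduction, post_transplant, postconsolidation, postmaintenance), ISS
stage, a binary tumor gene-expression risk flag, cytogenetic flags, and —
when available — the offset in days between a sample and clinical relapse
and a complete-remission flag. Missing values stay missing.

## Signature augmentation

New purified cell types are added to a base signature one at a time.
Candidates are ranked by a Welch t-test of the target type's replicates
against all other replicates (ascending p; ties by descending |log2 fold
change|, then gene id; only positive-fold-change genes are eligible; genes
already in the matrix are excluded). For each candidate count g = 1..g_max
the augmented matrix of per-type mean expression is scored by its condition
number κ = σ_max/σ_min, computed on columns scaled to unit Euclidean norm so
κ measures collinearity between cell-type profiles rather than intensity
scale; the g minimizing κ is kept. `condition_number()` itself returns the
raw singular-value ratio unless column standardization is requested. The
procedure is sequential (types added in the given order) and fully
deterministic; when every evaluated g is numerically rank-deficient a
warning is emitted and the largest evaluated g is kept. Sequential greedy
addition was chosen over joint optimization for determinism and because it
matches the add-types-to-an-existing-matrix workflow; on the synthetic
panel the resulting matrix supports >95 % self-recovery of every purified
type.

## Deconvolution

Per bulk sample, the solver restricts to genes shared with the signature
(≥ 10 required), scales signature columns and the bulk vector to unit norm
(scale invariance across platforms; coefficients are mapped back to the
original scale so they stay proportional to cell fractions), and fits an
elastic-net regression without intercept — mixing 0.05, penalty chosen by
3-fold internal cross-validation over a 25-point path down to 10⁻⁵ of the
maximal penalty — once per repeat on a random ⌈0.8·G⌉-gene subsample
(10 repeats by default, all seeded). Raw coefficients are the mean over
repeats; percentages clamp negatives to zero and renormalize rows to 100.
Rows whose clamped coefficients are all zero are flagged, never silently
renormalized. The tiny-mixing elastic net follows the digital-cell-quantifier
family of solvers; the repeat/subsample scheme stabilizes the penalty choice.
Coordinate descent visits columns in a fixed order, so permuting signature
columns reproduces permuted outputs only to solver tolerance (≈0.01
percentage points), not bit-exactly.

Spillover is measured by deconvolving each purified replicate and averaging
the percentage vectors per purified type (rows sum to 1). Merge proposals
cluster spillover rows by average linkage under 1 − Pearson correlation and
cut at a distance threshold (default 0.1); pairs declared biologically
distinct are split back out of any shared cluster. The collapsed 18- and
19-type maps used downstream are shipped as named fixtures
(`MERGE_27_TO_18`, `MERGE_27_TO_19`, differing in whether the memory-plasma
compartment stays separate) rather than recomputed, since the collapse used
in practice also encodes biological judgment.

Concordance against external estimates reports Pearson r, RMSE in the input
units, and the Fisher-z significance p = 2·Φ̄(|atanh r|·√(n−3)); the
t-distribution variant agrees within 0.01 at n = 20.

## Tumor-signal removal

For sample s with tumor fraction f_s, the matched CD138⁺ profile (fallback:
the signature's tumor column) is rescaled to the sample's total intensity
and subtracted: env = max(0, wbm − f_s·t); the result is rescaled so its
total equals the pre-removal total × (1 − f_s) — the microenvironment's
share of the RNA signal. Subtraction happens in linear intensity space;
log-space subtraction is non-physical for admixtures. Samples with
f > 0.99 are flagged tumor-saturated and excluded from clustering rather
than zeroed. When the bulk profile is an exact f·tumor + (1−f)·environment
admixture the environment is recovered to machine precision (up to the
documented global rescale).

## Microenvironment clustering

Inputs are pseudo-CD138⁻ profiles. Stages:

1. per-sample total-intensity normalization to the median total — tumor
   removal leaves each sample at a (1−f) share of its original intensity,
   which would otherwise leak tumor burden into the distances through the
   log pseudo-count;
2. gene selection: top ⌈10 %·G⌉ genes by variance of log2(x+1), ties broken
   lexicographically;
3. log2(x+1), then per-gene z-scoring — without it the shared mean
   expression profile imposes a ≈0.97 correlation floor between all samples
   and cluster structure is invisible to correlation distance;
4. PCA to 20 components (clipped to the data size with a warning);
5. average-linkage hierarchical clustering under 1 − Pearson on the scores;
6. for k in 2..10, cut the dendrogram and score the partition with a
   spherical-Gaussian BIC (shared variance, k·(d+1) parameters); k is the
   BIC argmin;
7. clusters smaller than 3 % of samples are relabeled "orphan"; retained
   clusters are renumbered by decreasing size and centroids recomputed from
   members only.

Steps 1 and 3 are this package's additions to the fixed log2/PCA/BIC recipe;
they are the standard preprocessing of expression-heatmap clustering, and
without them the planted-partition benchmark is unrecoverable. With outliers
present the BIC argmin exceeds the number of real clusters — the extra cuts
isolate outlier twigs that the orphan rule then strips — so the number of
*retained* clusters (`n_clusters`), not k, is the scientific quantity. New
samples are assigned to the centroid of maximal Pearson correlation in the
fitted PCA space (same normalization and z-scoring, training statistics);
correlations below a floor (default 0.2) give "orphan"; ≥ 80 % coverage of
the model's gene set is required, missing genes are dropped with a warning.

Cluster dynamics across treatment: for each cluster and each post-baseline
time point, an exact two-sided binomial test of the time point's cluster
count against the pretreatment proportion, Benjamini–Hochberg across all
tests, flagged at FDR < 0.05; patient-level transition count tables between
consecutive time points are emitted alongside.

## Survival statistics

* **KM / restricted mean.** Product-limit estimate (lifelines); the
  restricted mean is the exact area under the step function up to the
  horizon (default: largest observed time; comparisons use a shared
  horizon), with SE from the Greenwood-based area formula
  Var = Σ_events A(t_i)²·d_i/(r_i(r_i−d_i)), A(t_i) the area from t_i to
  the horizon. Verified against R `survival::survfit` `rmean`/`se(rmean)`
  to seven digits.
* **Log-rank.** Standard χ² over groups (lifelines), df = groups − 1.
* **Quartile hazard ratios.** Upper vs lowest quartile, middle half
  excluded; quartile boundaries by linear (type-7) interpolation, boundary
  ties to the lower group; binary features pass straight through. Cox fits
  use the Efron tie approximation throughout.
* **Lasso Cox.** Standardized features, L1 path (scikit-survival coxnet),
  penalty chosen by 5-fold cross-validated Efron log partial likelihood,
  refit on the full data; nonzero coefficients are the surviving features.
  An explicit penalty overrides CV; penalty 0 gives the unpenalized fit.
* **Stepwise Cox.** Seed with the lowest-univariate-p feature; iterate
  {add the candidate with the smallest nested-model likelihood-ratio χ²(1)
  p-value if p < 0.1; then repeatedly remove the worst non-protected
  feature with coefficient p > 0.05}; age and sex are protected; stops when
  no candidate enters or a model state repeats (cycle guard, warned). The
  LR test replaces a residual-variance F-test, which has no analog in a
  partial likelihood.
* **Survival tree.** Conditional-inference recursive partitioning: at each
  node, log-rank (Savage) scores a_i = δ_i − Λ̂(t_i) are computed from the
  node's own data; for each feature the maximally selected standardized
  linear-rank χ² over its decile thresholds (≥ 20 subjects per side) is the
  node statistic; its p-value comes from permuting the scores (10⁴ by
  default, seeded, vectorized) and is Bonferroni-corrected across features;
  the node splits when adjusted p ≤ α = 0.01. Ties at the permutation floor
  are broken by the statistic standardized against its own permutation
  distribution, which removes the selection advantage of many-threshold
  continuous features over binary flags. Leaves report n, events, and the
  restricted mean on the root's horizon. `path_splits()` returns the
  stratification chain (root split, then the split among the remaining
  low-flag population, and so on).
* **Differential tests.** Exact rank-sum (unpaired) or signed-rank
  (paired) per feature, BH FDR, log2 fold change of linear group means
  with pseudo-count 1; passing requires FDR ≤ 0.05 and, when the filter is
  on, |log2FC| > 0.66. Relapse-window comparison selects post-baseline
  samples within 180 days before to 30 days after relapse versus
  complete-remission samples, runs the unpaired test without the
  fold-change filter, and reports both the 0.20 and 0.05 FDR tiers.
* **Contingency tests.** χ² independence without continuity correction —
  Pearson X² by default, the likelihood-ratio G² as an option (the printed
  demographic p-values this package reproduces follow the likelihood-ratio
  statistic; Pearson agrees to ~0.01 on all rows except the Age ≥ 65 row);
  expected counts are returned and a flag raised when any is below 5.
  Fisher's exact test is two-sided with the conditional-MLE odds ratio.
  BH adjustment is the standard step-up, monotone and capped at 1.

## Synthetic cohort

The generator emulates a treated newly-diagnosed-myeloma cohort: 354
patients by default, each with a pretreatment WBM sample, matched CD138⁺
tumor profile, and a ~55 % chance per later time point of a follow-up
sample. All noise is multiplicative log-normal on linear intensities
(unit mean, configurable CV — additive Gaussian would produce negative
intensities). Everything is deterministic given the seed.

* **Reference panel.** 2,700 genes, 27 cell types (a 22-leukocyte panel
  plus tumor plasma cells, a memory-plasma compartment, adipocytes,
  osteoblasts, osteoclasts), 10 markers per type expressed 12–24× above a
  shared background, 3 replicates per type at CV 0.15. The 10 % marker
  density puts the top-10 %-variance gene cut in the same regime as a
  ~20k-gene array, where it captures the discriminative genes.
* **Clusters.** Five planted microenvironment compositions drawn from
  Dirichlet distributions (concentration 1500 ⇒ ≈10 % within-cluster CV
  for a 10 % cell type — well-separated clusters): a low-osteoblast
  cluster, an M2-skewed cluster, an NK-rich cluster, a high-granulocyte
  cluster (granulocyte-lineage types ×2.2), and the adverse
  low-granulocyte cluster 5 (mast/eosinophil/neutrophil/monocyte ×0.18,
  T cells moderately up, tumor fraction Beta(6,10) versus Beta(4,12)
  elsewhere — the tumor-burden confound the pipeline must separate from
  the microenvironment signal). A 3 % orphan rate draws unstructured
  compositions. WBM = f·tumor + (1−f)·environment, both components scaled
  to a common total intensity so f is the tumor's share of RNA signal.
* **Outcomes.** PFS/OS are exponential with rate λ₀·exp(Σβ·x); censoring
  is independent exponential (≈60 % PFS events). The planted features are
  the tumor risk flag (prevalence 20 %, enriched 1.8× in cluster 5 while
  holding the marginal prevalence fixed), ISS stage III (26 %, enriched
  1.6×), the bottom quartile of true WBM mast percentage, and cluster-5
  membership. Effect sizes (HR 8 / 3.4 / 2.8 / 1.1) encode the intended
  risk *hierarchy* with deliberately wide gaps: the log-rank score
  statistic saturates for large effects and realization noise at n = 354
  would otherwise reorder the tree's splits between runs. They are
  structural-recovery settings, not estimates of any real cohort's effect
  sizes; with them the stratification chain (risk flag → stage →
  granulocyte estimate) is recovered in ~14/15 generator seeds.
* **Relapse dynamics.** Post-baseline samples falling in the relapse
  window have granulocyte-lineage fractions multiplied by 0.4; after
  treatment, patients migrate toward the high-granulocyte cluster with
  cluster-specific probabilities, driving the cluster-dynamics tests.
* **Not emulated.** Probe-level array artifacts, batch effects, sequencing
  counts, gene–gene correlation beyond cell-type admixture, informative
  censoring, and time-varying hazards. Passing tests therefore demonstrate
  that the *algorithms* recover planted structure under realistic noise and
  confounding — not that real marrow data are this well behaved.

The printed demographic contingency tables and the relapsed-cohort
enrichment 2×2 are packaged verbatim as `table1_fixture()` so the
contingency machinery can be exercised against published numbers.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use: 40 noiseless and 200 noisy
mixtures for deconvolution recovery; 25 samples for tumor-removal
exactness; the full 354-sample cohort for clustering and the end-to-end
pipeline; 1000 replicates for log-rank/χ² type-I calibration; 100
replicates (1000 permutations each) for tree null calibration; n = 2000
for quartile-HR and stepwise-Cox recovery; 10⁴ permutations for the
end-to-end tree. Every stochastic step draws from a seeded generator;
`scripts/acceptance.py` derives all sub-seeds from its `--seed` argument.

## Known limitations

* The deconvolution penalty path is cross-validated per repeat, so runtime
  scales with samples × repeats; very large cohorts should lower
  `deconv_repeats`.
* BIC-argmin k inflates in the presence of outliers by design (see above);
  consumers should read `n_clusters`.
* The stepwise procedure inherits the known instability of stepwise
  selection; the trace records every add/remove for audit.
* The survival tree searches decile thresholds only; effects concentrated
  between deciles can be missed at small n.
* Merge proposals depend on the spillover estimate, which itself depends on
  deconvolution settings; the shipped 18/19-type maps are fixtures, not
  recomputations.
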