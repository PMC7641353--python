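# mmtme — bone-marrow tumor-microenvironment profiling for multiple myeloma

Multiple myeloma grows inside the bone marrow, and the *non-tumor* cellular
content of that marrow — the tumor microenvironment (TME) — carries
prognostic information that tumor-centric risk tools (ISS stage, tumor
gene-expression risk scores, cytogenetics) miss. `mmtme` implements the
complete computational pipeline for characterizing the whole-bone-marrow
(WBM) TME from bulk gene expression:

1. **Signature-matrix augmentation** — extend a base leukocyte signature
   matrix with new purified cell types (tumor plasma cells and
   marrow-resident types), choosing each type's marker-gene count `g` to
   minimize the condition number κ = σ<sub>max</sub>/σ<sub>min</sub> of the
   column-standardized signature, so the deconvolution basis stays well
   conditioned.
2. **Bulk deconvolution** — a digital-cell-quantifier-style solver: per
   sample, repeated elastic-net regressions (mixing α = 0.05, penalty by
   internal cross-validation) of the bulk profile on the signature columns
   over random 80 % gene subsamples; averaged coefficients are clamped at
   zero and renormalized to percentages.
3. **Spillover analysis and cell-type collapsing** — deconvolve purified
   samples to measure which types are systematically mis-assigned, cluster
   the spillover rows (average linkage, 1 − Pearson), and merge confusable
   types (a 27 → 18 and a 27 → 19 collapse ship as named fixtures).
4. **Tumor-signal removal** — per sample, subtract the matched CD138⁺ tumor
   profile at the estimated tumor fraction *f*:
   env = max(0, wbm − f·t), rescaled to the (1 − f) share of total
   intensity, yielding pseudo-CD138⁻ microenvironment profiles.
5. **Microenvironment clustering** — top-10 %-variance genes, log2,
   per-gene z-score, PCA, average-linkage hierarchical clustering under
   correlation distance; the number of clusters is the BIC argmin over
   dendrogram cuts; clusters under 3 % of samples become "orphans". New
   samples are assigned by nearest centroid correlation.
6. **Outcome statistics** — Kaplan–Meier with restricted means ± 1 SE
   (matching R `survfit`), log-rank tests, Q4-vs-Q1 quartile hazard ratios,
   lasso Cox (cross-validated penalty), the stepwise Cox procedure
   (enter p < 0.1, remove p > 0.05, age/sex protected), permutation-tested
   conditional-inference survival trees (split only when the Bonferroni-
   adjusted permutation p ≤ 0.01), Wilcoxon differential tests with
   Benjamini–Hochberg FDR and |log2FC| > 0.66 filtering, relapse-window
   comparisons (180 days before to 30 days after relapse), and the χ² /
   Fisher contingency tests for cohort demographics.

A **synthetic-cohort generator** stands in for patient data: it plants
reference profiles with type-specific markers, bulk mixtures with known
proportions, matched tumor/WBM pairs with known tumor fraction, five
microenvironment clusters (including an adverse "low-granulocyte" cluster
with depleted mast cells/eosinophils/neutrophils/monocytes and higher tumor
burden), and censored survival times following a proportional-hazards model
in the planted risk features. Every pipeline stage is therefore testable
against known ground truth, offline.

## Worked example

```python
import numpy as np
from mmtme import (generate_cohort, SignatureMatrix, augment_signature,
                   dcq_deconvolve, collapse_proportions, MERGE_27_TO_19,
                   remove_tumor_signal, fit_clusters, PipelineConfig,
                   logrank_test, km_restricted_mean)
from mmtme.io_config import ExpressionMatrix
from mmtme.synthetic_data import CELL_TYPES_27

cohort = generate_cohort(seed=0)              # 354 patients, 27 cell types
pre = cohort.pretreatment_samples()

refs = cohort.refs                            # build the 27-type signature
base_types = list(CELL_TYPES_27[:22])
base_genes = [g for i, _ in enumerate(base_types)
              for g in refs.mean_profiles.index[i*10:(i+1)*10]]
base = SignatureMatrix(refs.mean_profiles.loc[base_genes, base_types])
sig = augment_signature(base, refs, list(CELL_TYPES_27[22:]), g_max=30)

wbm = ExpressionMatrix(cohort.wbm.data[pre])
props = dcq_deconvolve(wbm, sig, seed=1)      # percent per cell type
merged = collapse_proportions(props, MERGE_27_TO_19)

f = (props.percentages["MM.plasma.cells"] / 100).clip(0, 0.99)
env = remove_tumor_signal(wbm, ExpressionMatrix(cohort.cd138.data[pre]), f)
model, labels = fit_clusters(env.expression, PipelineConfig())
print(model.k, model.n_clusters)              # 10 5

gran = merged.percentages[["Mast.cells", "Eosinophils",
                           "Neutrophils", "Monocytes"]].sum(axis=1)
low = min(
    (lab for lab in labels.labels.unique() if lab != "orphan"),
    key=lambda lab: gran[(labels.labels == lab).to_numpy()].mean(),
)
mask = (labels.labels == low).to_numpy()
clin = {r.sample_id: r for r in cohort.clinical}
t = np.array([clin[s].pfs_months for s in pre])
e = np.array([clin[s].pfs_event for s in pre])
print(logrank_test([(t[mask], e[mask]), (t[~mask], e[~mask])])["p"])
lo = km_restricted_mean(t[mask], e[mask], horizon=t.max())
hi = km_restricted_mean(t[~mask], e[~mask], horizon=t.max())
print(f"{lo.restricted_mean:.0f}±{lo.restricted_mean_se:.0f} vs "
      f"{hi.restricted_mean:.0f}±{hi.restricted_mean_se:.0f} months")
```

This prints `10 5` — the BIC cut isolates the handful of planted outlier
samples into twigs that the 3 % orphan rule strips away, leaving five
retained clusters — then a log-rank p-value of `2.8e-14` and
`26±4 vs 74±6 months`: the recovered low-granulocyte cluster has a
dramatically shorter restricted-mean progression-free survival than the
other clusters combined, exactly the planted adverse-microenvironment
signal.

A command-line interface mirrors the pipeline stages
(`mmtme simulate | build-signature | deconvolve | spillover | remove-tumor |
cluster | assign | survival | table-tests`); run `mmtme --help`.

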