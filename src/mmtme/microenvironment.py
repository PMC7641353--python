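"""Pseudo-CD138- microenvironment profiles and their clustering.

The tumor's share of each whole-marrow expression profile is subtracted at
the estimated tumor fraction f, leaving a microenvironment-only profile;
high-variance genes of those profiles are clustered (average linkage,
correlation distance, in PCA space) with the number of clusters chosen by a
spherical-Gaussian BIC over dendrogram cuts.  Small clusters become
"orphans".  New samples are assigned to the nearest centroid by correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io_config import ExpressionMatrix, PipelineConfig, ValidationError
from .signature_builder import SignatureMatrix
from .synthetic_data import ORPHAN_LABEL, TUMOR_TYPE

TUMOR_SATURATED_F = 0.99


# ---------------------------------------------------------------------------
# Tumor-signal removal
# ---------------------------------------------------------------------------


@dataclass
class PseudoEnvironmentProfile:
    """Microenvironment expression after tumor removal.

    ``tumor_fraction`` records f per sample; ``provenance`` says whether the
    matched CD138+ profile or the signature tumor column was subtracted.
    Samples with f > 0.99 are flagged tumor-saturated and listed in
    ``excluded`` (kept out of clustering, not silently zeroed).
    """

    expression: ExpressionMatrix
    tumor_fraction: pd.Series
    provenance: dict
    excluded: list = field(default_factory=list)


def remove_tumor_signal(
    wbm: ExpressionMatrix,
    cd138: Optional[ExpressionMatrix],
    f,
    sig: Optional[SignatureMatrix] = None,
) -> PseudoEnvironmentProfile:
    """Subtract the tumor profile at fraction f from each WBM sample.

    Per sample s: env = max(0, wbm_s - f_s * t_s), where t_s is the matched
    CD138+ column rescaled to the sample's total intensity (fallback: the
    signature tumor column).  The result is rescaled so each sample's total
    equals its pre-removal total times (1 - f_s), i.e. the microenvironment's
    share of the RNA signal.
    """
    f = pd.Series(f).reindex(wbm.sample_ids)
    if f.isna().any():
        raise ValidationError("tumor fraction missing for some samples")
    if ((f < 0) | (f > 1)).any():
        raise ValidationError("tumor fractions must be in [0, 1]")
    if wbm.scale != "linear":
        raise ValidationError("tumor removal operates on linear-scale data")

    sig_tumor = None
    if sig is not None and TUMOR_TYPE in sig.cell_types:
        shared = [g for g in wbm.gene_ids if g in set(sig.genes)]
        sig_tumor = sig.data.loc[shared, TUMOR_TYPE]

    out = {}
    provenance = {}
    excluded = []
    for s in wbm.sample_ids:
        y = wbm.data[s].to_numpy()
        fs = float(f[s])
        if fs > TUMOR_SATURATED_F:
            excluded.append(s)
            out[s] = y
            provenance[s] = "tumor-saturated"
            continue
        if cd138 is not None and s in set(cd138.sample_ids):
            t = cd138.data[s].reindex(wbm.gene_ids)
            if t.isna().any():
                raise ValidationError(f"CD138 profile for {s} misses genes")
            t = t.to_numpy()
            provenance[s] = f"matched:{s}"
        elif sig_tumor is not None:
            t = sig_tumor.reindex(wbm.gene_ids).fillna(0.0).to_numpy()
            provenance[s] = "signature-column"
        else:
            raise ValidationError(
                f"sample {s}: no matched CD138+ profile and no signature tumor column"
            )
        total = y.sum()
        if t.sum() > 0:
            t = t * (total / t.sum())
        env = np.maximum(0.0, y - fs * t)
        target = total * (1.0 - fs)
        if env.sum() > 0:
            env = env * (target / env.sum())
        out[s] = env
    em = ExpressionMatrix(pd.DataFrame(out, index=wbm.gene_ids)[wbm.sample_ids])
    return PseudoEnvironmentProfile(em, f, provenance, excluded)


# ---------------------------------------------------------------------------
# High-variance gene selection
# ---------------------------------------------------------------------------


def select_high_variance_genes(expr: ExpressionMatrix, fraction: float = 0.10) -> list:
    """Top ceil(fraction * G) genes by variance of log2(linear + 1).

    Ties broken lexicographically by gene id; all-constant input is an error.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    logx = np.log2(expr.values + 1.0) if expr.scale == "linear" else expr.values
    var = pd.Series(np.var(logx, axis=1, ddof=0), index=expr.gene_ids)
    if (var == 0).all():
        raise ValidationError("all genes constant: variance ranking undefined")
    n_keep = int(np.ceil(fraction * len(var)))
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[:n_keep]


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """Fitted microenvironment clustering.

    ``k`` is the BIC-argmin cut of the dendrogram; clusters smaller than
    ``min_cluster_fraction`` of samples are relabeled orphan, so the number
    of retained clusters (``n_clusters``) can be smaller than k.  Centroids
    are stored both in log2 gene space and in the fitted PCA space (used for
    assignment of new samples).  ``gene_log2_mean``/``gene_log2_std`` and
    ``target_total`` record the preprocessing (total-intensity
    normalization, log2, per-gene z-score) applied before PCA so new
    samples can be projected identically.
    """

    gene_set: list
    k: int
    centroids: pd.DataFrame               # genes x retained clusters (log2 scale)
    pca_centroids: pd.DataFrame           # PCA dims x retained clusters
    gene_log2_mean: pd.Series
    gene_log2_std: pd.Series
    target_total: float
    pca_components: pd.DataFrame          # genes x dims
    bic_trace: dict
    min_cluster_fraction: float
    linkage: str = "average"
    distance: str = "pearson"
    pca_dims: int = 20
    orphan_label: str = ORPHAN_LABEL

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[1]


@dataclass
class ClusterAssignment:
    labels: pd.Series      # sample -> cluster label (int) or orphan
    similarity: pd.Series  # correlation with assigned centroid (nan for fit-time)


def _xmeans_bic(X: np.ndarray, labels: np.ndarray) -> float:
    """Spherical-Gaussian BIC of a hard partition (x-means formulation)."""
    n, d = X.shape
    ks = np.unique(labels)
    k = len(ks)
    if n <= k:
        return np.inf
    rss = 0.0
    sizes = []
    for c in ks:
        pts = X[labels == c]
        sizes.append(len(pts))
        rss += ((pts - pts.mean(axis=0)) ** 2).sum()
    sigma2 = max(rss / (d * (n - k)), 1e-12)
    loglik = 0.0
    for n_c in sizes:
        loglik += (
            n_c * np.log(n_c / n)
            - n_c * d / 2 * np.log(2 * np.pi * sigma2)
            - d * (n_c - 1) / 2
        )
    n_params = k * (d + 1)
    return float(n_params * np.log(n) - 2 * loglik)


def fit_clusters(
    expr: ExpressionMatrix,
    config: Optional[PipelineConfig] = None,
    gene_set: Optional[list] = None,
):
    """Cluster samples on high-variance genes; BIC-selected dendrogram cut.

    Returns (ClusterModel, ClusterAssignment).  Labels are 1..n_clusters in
    decreasing cluster-size order (first-sample index breaks ties), orphans
    labeled ``"orphan"``.
    """
    config = config or PipelineConfig()
    n = expr.shape[1]
    if n < 10:
        raise ValidationError(f"need >= 10 samples to cluster, got {n}")
    # library-size normalization: tumor removal leaves each sample at a
    # (1 - f) share of its original intensity, which would otherwise leak
    # tumor burden into the distances via the log pseudo-count
    target_total = float(np.median(expr.values.sum(axis=0)))
    totals = expr.values.sum(axis=0)
    totals[totals == 0] = 1.0
    norm = ExpressionMatrix(expr.data * (target_total / totals), scale=expr.scale)
    if gene_set is None:
        gene_set = select_high_variance_genes(norm, config.variance_gene_fraction)
    sub = norm.subset_genes(gene_set)
    logx = np.log2(sub.values + 1.0) if sub.scale == "linear" else sub.values
    # per-gene z-score so the shared mean expression profile does not swamp
    # between-cluster differences in the correlation distance
    g_mean = logx.mean(axis=1)
    g_std = logx.std(axis=1)
    g_std[g_std == 0] = 1.0
    Xz = ((logx.T - g_mean) / g_std)  # samples x genes

    dims = min(config.pca_dims, n - 1, Xz.shape[1])
    if dims < config.pca_dims:
        warnings.warn(
            f"pca_dims clipped from {config.pca_dims} to {dims}", RuntimeWarning
        )
    pca = PCA(n_components=dims, svd_solver="full", random_state=0)
    scores = pca.fit_transform(Xz)

    dist = pdist(scores, metric="correlation")
    Z = hierarchy.linkage(dist, method="average")
    k_max = min(config.cluster_k_max, n - 1)
    bic_trace = {}
    labels_by_k = {}
    for k in range(config.cluster_k_min, k_max + 1):
        lab = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        bic_trace[k] = _xmeans_bic(scores, lab)
    k_best = min(bic_trace, key=lambda k: (bic_trace[k], k))
    raw_labels = labels_by_k[k_best]

    # orphan rule and deterministic relabeling by decreasing size
    min_size = config.min_cluster_fraction * n
    sizes = pd.Series(raw_labels).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_size]
    first_idx = {c: int(np.argmax(raw_labels == c)) for c in kept}
    kept.sort(key=lambda c: (-sizes[c], first_idx[c]))
    relabel = {c: i + 1 for i, c in enumerate(kept)}

    final = np.array(
        [relabel.get(c, ORPHAN_LABEL) for c in raw_labels], dtype=object
    )
    centroids = {}
    pca_centroids = {}
    for c in kept:
        mask = raw_labels == c
        centroids[relabel[c]] = logx[:, mask].mean(axis=1)
        pca_centroids[relabel[c]] = scores[mask].mean(axis=0)
    model = ClusterModel(
        gene_set=list(gene_set),
        k=k_best,
        centroids=pd.DataFrame(centroids, index=gene_set),
        pca_centroids=pd.DataFrame(pca_centroids),
        gene_log2_mean=pd.Series(g_mean, index=gene_set),
        gene_log2_std=pd.Series(g_std, index=gene_set),
        target_total=target_total,
        pca_components=pd.DataFrame(pca.components_.T, index=gene_set),
        bic_trace=bic_trace,
        min_cluster_fraction=config.min_cluster_fraction,
        pca_dims=dims,
    )
    assignment = ClusterAssignment(
        labels=pd.Series(final, index=expr.sample_ids),
        similarity=pd.Series(np.nan, index=expr.sample_ids),
    )
    return model, assignment


def assign_clusters(
    new_expr: ExpressionMatrix,
    model: ClusterModel,
    corr_floor: float = 0.2,
) -> ClusterAssignment:
    """Nearest-centroid assignment by Pearson correlation in PCA space.

    Requires >= 80% coverage of the model's gene set; missing genes are
    dropped from the projection with a warning.  Samples whose best
    correlation falls below ``corr_floor`` become orphans.
    """
    present = [g for g in model.gene_set if g in set(new_expr.gene_ids)]
    coverage = len(present) / len(model.gene_set)
    if coverage < 0.8:
        raise ValidationError(
            f"only {coverage:.0%} of the model gene set present (need >= 80%)"
        )
    if coverage < 1.0:
        warnings.warn(
            f"{len(model.gene_set) - len(present)} model genes missing; dropped",
            RuntimeWarning,
        )
    totals = new_expr.values.sum(axis=0)
    totals[totals == 0] = 1.0
    norm = ExpressionMatrix(
        new_expr.data * (model.target_total / totals), scale=new_expr.scale
    )
    sub = norm.subset_genes(present)
    logx = np.log2(sub.values + 1.0) if sub.scale == "linear" else sub.values
    comp = model.pca_components.loc[present].to_numpy()
    mean = model.gene_log2_mean.loc[present].to_numpy()
    std = model.gene_log2_std.loc[present].to_numpy()
    scores = ((logx.T - mean) / std) @ comp
    cents = model.pca_centroids.to_numpy()  # dims x clusters

    labels = {}
    sims = {}
    for i, s in enumerate(new_expr.sample_ids):
        v = scores[i]
        best_lab, best_r = ORPHAN_LABEL, -np.inf
        for j, lab in enumerate(model.pca_centroids.columns):
            cv = cents[:, j]
            if v.std() == 0 or cv.std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(v, cv)[0, 1])
            if r > best_r:
                best_lab, best_r = lab, r
        if best_r < corr_floor:
            best_lab = ORPHAN_LABEL
        labels[s] = best_lab
        sims[s] = best_r
    return ClusterAssignment(
        labels=pd.Series(labels).reindex(new_expr.sample_ids),
        similarity=pd.Series(sims).reindex(new_expr.sample_ids),
    )


# ---------------------------------------------------------------------------
# Cluster dynamics across treatment
# ---------------------------------------------------------------------------


def cluster_dynamics(
    labels: pd.Series,
    timepoints: pd.Series,
    patients: Optional[pd.Series] = None,
    fdr_threshold: float = 0.05,
):
    """Test per-cluster proportion shifts against pretreatment.

    For each cluster and each later timepoint, an exact two-sided binomial
    test of that timepoint's cluster count against the pretreatment
    proportion; Benjamini-Hochberg across all tests.  Also returns the
    timepoint-to-timepoint transition count tables (Sankey source data) for
    patients sampled at consecutive timepoints.
    """
    labels = labels.astype(object)
    df = pd.DataFrame({"label": labels, "timepoint": timepoints.reindex(labels.index)})
    if patients is not None:
        df["patient"] = patients.reindex(labels.index)
    if "pretreatment" not in set(df["timepoint"]):
        raise ValidationError("pretreatment samples are required as the reference")
    tps = [tp for tp in
           ("pretreatment", "postinduction", "post_transplant",
            "postconsolidation", "postmaintenance")
           if tp in set(df["timepoint"])]
    pre = df[df["timepoint"] == "pretreatment"]
    n_pre = len(pre)
    clusters = sorted(set(df["label"]), key=str)

    rows = []
    for cl in clusters:
        p0 = (pre["label"] == cl).sum() / n_pre
        for tp in tps[1:]:
            sub = df[df["timepoint"] == tp]
            count = int((sub["label"] == cl).sum())
            n = len(sub)
            if p0 in (0.0, 1.0):
                p = 1.0 if count == int(p0 * n) else 0.0
            else:
                p = stats.binomtest(count, n, p0).pvalue
            rows.append({
                "cluster": cl, "timepoint": tp, "count": count, "n": n,
                "proportion": count / n if n else np.nan,
                "pretreatment_proportion": p0, "binomial_p": p,
            })
    result = pd.DataFrame(rows)
    if len(result):
        result["fdr"] = multipletests(result["binomial_p"], method="fdr_bh")[1]
        result["flagged"] = result["fdr"] < fdr_threshold
    transitions = {}
    if patients is not None:
        for a, b in zip(tps[:-1], tps[1:]):
            da = df[df["timepoint"] == a].set_index("patient")["label"]
            db = df[df["timepoint"] == b].set_index("patient")["label"]
            shared = da.index.intersection(db.index)
            if len(shared):
                transitions[(a, b)] = pd.crosstab(
                    da.loc[shared], db.loc[shared], dropna=False
                )
    return result, transitions
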