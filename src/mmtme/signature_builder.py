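"""Signature-matrix augmentation by condition-number minimization.

Starting from a base leukocyte signature matrix, new purified cell types are
added one at a time: candidate genes are ranked by how specifically they mark
the new type (Welch t-test of target replicates vs all others, positive fold
change only), and the number of genes kept is the one that minimizes the
condition number kappa = sigma_max/sigma_min of the column-standardized
augmented matrix.  A low kappa means the regression basis used for
deconvolution is well conditioned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_config import ValidationError
from .synthetic_data import ReferenceProfileSet


@dataclass
class SignatureMatrix:
    """Signature genes x cell types deconvolution basis."""

    data: pd.DataFrame                       # genes x cell_types, non-negative
    provenance: dict = field(default_factory=dict)  # gene -> "base" | "added:<type>"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate genes in signature matrix")
        if (self.data.to_numpy() < 0).any():
            raise ValidationError("signature values must be non-negative")
        zero_cols = self.data.columns[(self.data == 0).all(axis=0)]
        if len(zero_cols):
            raise ValidationError(f"all-zero signature columns: {list(zero_cols)}")
        if not self.provenance:
            self.provenance = {g: "base" for g in self.data.index}

    @property
    def genes(self) -> list:
        return list(self.data.index)

    @property
    def cell_types(self) -> list:
        return list(self.data.columns)

    @property
    def kappa(self) -> float:
        return condition_number(self.data.to_numpy(), column_standardize=True)


def condition_number(matrix, column_standardize: bool = False) -> float:
    """sigma_max / sigma_min of a matrix; +inf when numerically rank-deficient.

    With ``column_standardize`` columns are scaled to unit Euclidean norm
    first so that kappa reflects collinearity between cell-type profiles
    rather than intensity scale differences; the signature builder uses that
    mode when scoring candidate gene sets.
    """
    m = np.asarray(matrix, dtype=float)
    if m.size == 0 or m.ndim != 2:
        raise ValidationError("condition_number needs a non-empty 2-D matrix")
    if not np.isfinite(m).all():
        raise ValidationError("matrix entries must be finite")
    if column_standardize:
        norms = np.linalg.norm(m, axis=0)
        if (norms == 0).any():
            return float("inf")
        m = m / norms
    s = np.linalg.svd(m, compute_uv=False)
    smin = s.min()
    if smin <= s.max() * np.finfo(float).eps * max(m.shape):
        return float("inf")
    return float(s.max() / smin)


def rank_candidate_genes(
    refs: ReferenceProfileSet,
    target_type: str,
    existing_types,
    exclude_genes=(),
) -> pd.DataFrame:
    """Rank marker candidates for ``target_type`` against all other types.

    Welch t-test of target replicates vs pooled others per gene; ascending
    p-value, ties broken by descending |log2 fold change| then gene id.
    Only genes with positive fold change toward the target are candidates;
    genes already in the base matrix are excluded.
    """
    existing_types = list(existing_types)
    if not existing_types:
        raise ValidationError("existing_types must be non-empty")
    target_samples = refs.replicates_of(target_type)
    if len(target_samples) < 2:
        raise ValidationError(f"target type {target_type} has < 2 replicates")
    other_samples = [
        s for s, ct in refs.replicate_map.items() if ct != target_type
    ]
    X = refs.profiles.data
    tgt = X[target_samples].to_numpy()
    oth = X[other_samples].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(tgt, oth, axis=1, equal_var=False)
    # zero within-group variance gives nan; a clean separation is maximally
    # significant, identical means are uninformative
    sep = tgt.min(axis=1) > oth.max(axis=1)
    p = np.where(np.isnan(p), np.where(sep, 0.0, 1.0), p)
    log2fc = np.log2(tgt.mean(axis=1) + 1) - np.log2(oth.mean(axis=1) + 1)
    df = pd.DataFrame(
        {"gene": X.index, "p_value": p, "log2fc": log2fc}
    )
    df = df[~df["gene"].isin(set(exclude_genes))]
    df = df[df["log2fc"] > 0]
    df = df.sort_values(
        by=["p_value", "log2fc", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return df


def augment_signature(
    base: SignatureMatrix,
    refs: ReferenceProfileSet,
    new_types,
    g_max: int = 100,
) -> SignatureMatrix:
    """Add new cell-type columns to a base signature, one type at a time.

    For each new type, candidate gene counts g = 1..g_max are evaluated; the
    g minimizing the condition number of the augmented (column-standardized)
    matrix is kept.  Column values are mean purified expression from
    ``refs``.  Deterministic; a rank-deficiency warning is emitted when every
    evaluated g is singular.
    """
    if g_max < 1:
        raise ValidationError("g_max must be >= 1")
    new_types = list(new_types)
    for nt in new_types:
        if nt in base.cell_types:
            raise ValidationError(f"type {nt} already in base matrix")
        if nt not in refs.cell_types:
            raise ValidationError(f"type {nt} missing from reference profiles")

    current = base.data.copy()
    provenance = dict(base.provenance)
    for nt in new_types:
        types_now = list(current.columns) + [nt]
        missing = [t for t in types_now if t not in refs.cell_types]
        if missing:
            raise ValidationError(
                f"reference profiles lack types needed to fill new rows: {missing}"
            )
        ranked = rank_candidate_genes(
            refs, nt, list(current.columns), exclude_genes=current.index
        )
        candidates = [g for g in ranked["gene"] if g in refs.mean_profiles.index]
        if not candidates:
            raise ValidationError(f"no candidate marker genes for {nt}")
        g_lim = min(g_max, len(candidates))
        means = refs.mean_profiles
        best_g, best_kappa = None, np.inf
        for g in range(1, g_lim + 1):
            genes_g = list(current.index) + candidates[:g]
            kappa = condition_number(
                means.loc[genes_g, types_now].to_numpy(), column_standardize=True
            )
            if kappa < best_kappa:
                best_g, best_kappa = g, kappa
        if best_g is None:
            warnings.warn(
                f"augmentation for {nt}: matrix rank-deficient for every "
                f"evaluated gene count; keeping g={g_lim}",
                RuntimeWarning,
            )
            best_g = g_lim
        chosen = candidates[:best_g]
        genes_new = list(current.index) + chosen
        rebuilt = means.loc[genes_new, types_now].copy()
        # keep the base matrix's own values for its genes/types
        rebuilt.loc[current.index, current.columns] = current
        current = rebuilt
        for g in chosen:
            provenance[g] = f"added:{nt}"
    return SignatureMatrix(current, provenance)
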