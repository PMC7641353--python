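"""Bulk-expression deconvolution and spillover-aware cell-type collapsing.

The solver follows a digital-cell-quantifier style: per bulk sample, an
elastic-net regression (mixing 0.05, penalty by internal cross-validation)
of the bulk vector on the signature columns, repeated over random gene
subsamples, coefficients averaged.  Negative coefficients are clamped to
zero and rows renormalized to percentages.  Spillover on purified samples
quantifies which cell types are systematically mis-deconvolved as others and
drives the merge proposals (27 -> 18 in the collapse shipped as a fixture).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.linear_model import ElasticNetCV
from sklearn.exceptions import ConvergenceWarning

from .io_config import ExpressionMatrix, ValidationError
from .signature_builder import SignatureMatrix
from .synthetic_data import ReferenceProfileSet

MIN_SHARED_GENES = 10


@dataclass
class CellProportions:
    """Per-sample cell-type estimates.

    ``raw`` keeps the (possibly negative) averaged regression coefficients;
    ``percentages`` is clamp(raw, 0) renormalized to 100 per row.  Samples
    whose clamped coefficients are all zero are flagged, not normalized.
    """

    raw: pd.DataFrame           # samples x cell_types
    percentages: pd.DataFrame   # samples x cell_types, rows sum to 100
    flagged_samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ok = ~self.percentages.index.isin(self.flagged_samples)
        sums = self.percentages.loc[ok].sum(axis=1)
        if len(sums) and not np.allclose(sums, 100.0, atol=1e-6):
            raise ValidationError("percentage rows must sum to 100")

    @property
    def sample_ids(self) -> list:
        return list(self.percentages.index)

    @property
    def cell_types(self) -> list:
        return list(self.percentages.columns)


def _percentages_from_raw(raw: pd.DataFrame):
    clamped = raw.clip(lower=0.0)
    sums = clamped.sum(axis=1)
    flagged = list(clamped.index[sums <= 0])
    pct = clamped.copy()
    ok = sums > 0
    pct.loc[ok] = clamped.loc[ok].div(sums[ok], axis=0) * 100.0
    pct.loc[~ok] = 0.0
    return pct, flagged


def dcq_deconvolve(
    bulk: ExpressionMatrix,
    sig: SignatureMatrix,
    n_repeats: int = 10,
    gene_subsample: float = 0.8,
    en_mixing: float = 0.05,
    seed: int = 0,
) -> CellProportions:
    """Estimate cell-type proportions for every bulk sample.

    Bulk and signature are restricted to shared genes and column-scaled to
    unit Euclidean norm before regression (scale invariance across
    platforms); fitted coefficients are mapped back to the original scale
    before averaging so they remain proportional to cell fractions.
    """
    if not 0 < gene_subsample <= 1:
        raise ValidationError("gene_subsample must be in (0, 1]")
    if not 0 <= en_mixing <= 1:
        raise ValidationError("en_mixing must be in [0, 1]")
    shared = [g for g in sig.genes if g in set(bulk.gene_ids)]
    if len(shared) < MIN_SHARED_GENES:
        raise ValidationError(
            f"only {len(shared)} genes shared between bulk and signature "
            f"(need >= {MIN_SHARED_GENES})"
        )
    X_full = sig.data.loc[shared].to_numpy()
    Y = bulk.data.loc[shared].to_numpy()
    G, K = X_full.shape
    n_sub = int(np.ceil(gene_subsample * G))
    rng = np.random.default_rng(seed)
    subsets = [
        np.sort(rng.choice(G, size=n_sub, replace=False)) for _ in range(n_repeats)
    ]
    # l1_ratio=0 (pure ridge) is unsupported by the coordinate-descent path;
    # floor at a tiny lasso share
    l1 = max(en_mixing, 1e-3)
    raw = np.zeros((bulk.shape[1], K))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for s in range(bulk.shape[1]):
            y_full = Y[:, s]
            coefs = np.zeros((n_repeats, K))
            for r, idx in enumerate(subsets):
                Xs = X_full[idx]
                ys = y_full[idx]
                col_norms = np.linalg.norm(Xs, axis=0)
                col_norms[col_norms == 0] = 1.0
                y_norm = np.linalg.norm(ys)
                if y_norm == 0:
                    continue
                model = ElasticNetCV(
                    l1_ratio=l1,
                    eps=1e-5,
                    alphas=25,
                    cv=3,
                    fit_intercept=False,
                    max_iter=5000,
                    tol=1e-6,
                    random_state=0,
                )
                model.fit(Xs / col_norms, ys / y_norm)
                coefs[r] = model.coef_ * y_norm / col_norms
            raw[s] = coefs.mean(axis=0)
    raw_df = pd.DataFrame(raw, index=bulk.sample_ids, columns=sig.cell_types)
    pct, flagged = _percentages_from_raw(raw_df)
    if flagged:
        warnings.warn(f"all-negative coefficient rows flagged: {flagged}", RuntimeWarning)
    return CellProportions(raw_df, pct, flagged)


# ---------------------------------------------------------------------------
# Spillover and merging
# ---------------------------------------------------------------------------


@dataclass
class SpilloverMatrix:
    """Row-stochastic mean deconvolved composition of purified samples.

    Rows: the purified input type; columns: the estimated types.  Entry
    (t, u) is the average fraction of type-t signal attributed to type u.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValidationError("spillover rows must sum to 1")

    @property
    def is_square(self) -> bool:
        return list(self.data.index) == list(self.data.columns)


def compute_spillover(
    refs: ReferenceProfileSet,
    sig: SignatureMatrix,
    n_repeats: int = 10,
    gene_subsample: float = 0.8,
    en_mixing: float = 0.05,
    seed: int = 0,
) -> SpilloverMatrix:
    """Deconvolve each purified replicate and average per purified type."""
    if not refs.replicate_map:
        raise ValidationError("reference set has no replicates")
    props = dcq_deconvolve(
        refs.profiles, sig, n_repeats=n_repeats, gene_subsample=gene_subsample,
        en_mixing=en_mixing, seed=seed,
    )
    pct = props.percentages / 100.0
    groups = pct.groupby(
        pd.Series(refs.replicate_map).reindex(pct.index)
    ).mean()
    groups = groups.div(groups.sum(axis=1), axis=0)
    order = [t for t in sig.cell_types if t in groups.index]
    extra = [t for t in groups.index if t not in order]
    return SpilloverMatrix(groups.loc[order + extra])


@dataclass
class CellTypeMerge:
    """Total mapping source type -> merged type."""

    mapping: dict
    keep_separate: frozenset = frozenset()

    def merged_types(self) -> list:
        seen = []
        for t in self.mapping.values():
            if t not in seen:
                seen.append(t)
        return seen


def propose_merges(
    spill: SpilloverMatrix,
    distance_threshold: float = 0.1,
    keep_separate=(),
) -> CellTypeMerge:
    """Collapse confusable types by clustering spillover rows.

    Average-linkage hierarchical clustering under 1 - Pearson correlation,
    cut at ``distance_threshold``.  Pairs listed in ``keep_separate`` are
    biologically distinct and are split out of any shared cluster into their
    own merged types.
    """
    if not spill.is_square:
        raise ValidationError("spillover matrix must be square to propose merges")
    if not 0 < distance_threshold < 2:
        raise ValidationError("distance_threshold must be in (0, 2)")
    types = list(spill.data.index)
    rows = spill.data.to_numpy()
    corr = np.corrcoef(rows)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=distance_threshold, criterion="distance")

    keep_pairs = {frozenset(p) for p in keep_separate}
    clusters: dict[int, list] = {}
    for t, lab in zip(types, labels):
        clusters.setdefault(lab, []).append(t)
    mapping = {}
    for members in clusters.values():
        offenders = set()
        for pair in keep_pairs:
            a, b = tuple(pair)
            if a in members and b in members:
                offenders |= {a, b}
        grouped = [t for t in members if t not in offenders]
        if grouped:
            name = grouped[0] if len(grouped) == 1 else "/".join(grouped)
            for t in grouped:
                mapping[t] = name
        for t in members:
            if t in offenders:
                mapping[t] = t
    mapping = {t: mapping[t] for t in types}
    return CellTypeMerge(mapping, frozenset(keep_pairs))


def collapse_proportions(props: CellProportions, merge: CellTypeMerge) -> CellProportions:
    """Sum member percentages into merged types; row sums preserved."""
    missing = [t for t in props.cell_types if t not in merge.mapping]
    if missing:
        raise ValidationError(f"merge mapping does not cover: {missing}")
    targets = []
    for t in props.cell_types:
        m = merge.mapping[t]
        if m not in targets:
            targets.append(m)
    groups = pd.Series({t: merge.mapping[t] for t in props.cell_types})
    raw = props.raw.T.groupby(groups).sum().T[targets]
    pct = props.percentages.T.groupby(groups).sum().T[targets]
    return CellProportions(raw, pct, list(props.flagged_samples))


# 27 -> 18 and 27 -> 19 collapse maps shipped as named fixtures (synthetic
# analogs of the published post hoc combinations; the 19-type variant keeps
# the memory-plasma compartment separate for survival modeling).
def _merge_fixture(split_plasma_memory: bool) -> CellTypeMerge:
    groups = [
        ["B.cells.naive", "B.cells.memory"],
        ["Plasma.cells"] + ([] if split_plasma_memory else ["PlasmaMemory"]),
        ["MM.plasma.cells"],
        ["T.cells.CD8"],
        ["T.cells.CD4.naive", "T.cells.CD4.memory.resting",
         "T.cells.CD4.memory.activated", "T.cells.follicular.helper",
         "T.cells.regulatory"],
        ["T.cells.gamma.delta"],
        ["NK.cells.resting", "NK.cells.activated"],
        ["Monocytes"], ["Macrophages.M0"], ["Macrophages.M1"], ["Macrophages.M2"],
        ["Dendritic.cells.resting", "Dendritic.cells.activated"],
        ["Mast.cells.resting", "Mast.cells.activated"],
        ["Eosinophils"], ["Neutrophils"],
        ["Adipocytes"], ["Osteoblasts"], ["Osteoclasts"],
    ]
    if split_plasma_memory:
        groups.append(["PlasmaMemory"])
    names = {
        "B.cells.naive": "B.cells",
        "T.cells.CD4.naive": "T.cells.CD4",
        "NK.cells.resting": "NK.cells",
        "Dendritic.cells.resting": "Dendritic.cells",
        "Mast.cells.resting": "Mast.cells",
    }
    mapping = {}
    for members in groups:
        name = names.get(members[0], members[0]) if len(members) > 1 else members[0]
        if len(members) > 1 and members[0] == "Plasma.cells":
            name = "Plasma.cells"
        for m in members:
            mapping[m] = name
    return CellTypeMerge(mapping)


MERGE_27_TO_18 = _merge_fixture(split_plasma_memory=False)
MERGE_27_TO_19 = _merge_fixture(split_plasma_memory=True)


# ---------------------------------------------------------------------------
# Concordance against external estimates
# ---------------------------------------------------------------------------


def concordance_metrics(estimates, truth) -> dict:
    """Pearson r, RMSE (input units) and Fisher-z correlation p-value.

    fisher_z_p is the two-sided normal p for atanh(r) * sqrt(n - 3), the
    standard significance transform for a correlation coefficient.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape or est.ndim != 1 or len(est) < 3:
        raise ValidationError("need equal-length 1-D vectors with n >= 3")
    if not (np.isfinite(est).all() and np.isfinite(tru).all()):
        raise ValidationError("inputs must be finite")
    n = len(est)
    rmse = float(np.sqrt(np.mean((est - tru) ** 2)))
    if est.std() == 0 or tru.std() == 0:
        warnings.warn("zero-variance input: correlation undefined", RuntimeWarning)
        return {"pearson_r": None, "rmse": rmse, "fisher_z_p": None, "n": n}
    r = float(np.corrcoef(est, tru)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        z = np.arctanh(r) * np.sqrt(n - 3)
        p = float(2 * stats.norm.sf(abs(z)))
    return {"pearson_r": r, "rmse": rmse, "fisher_z_p": p, "n": n}
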