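"""Synthetic bone-marrow cohorts with known ground truth.

Emulates the inputs of a whole-bone-marrow (WBM) myeloma study: purified
reference profiles for 27 cell types (a 22-leukocyte panel plus tumor plasma
cells and four marrow-resident types), bulk WBM mixtures with known
proportions, matched CD138+ tumor profiles with known tumor fraction,
planted microenvironment clusters (one "low-granulocyte" adverse cluster),
and censored survival outcomes whose hazard follows a proportional-hazards
model in the planted features.

Noise is multiplicative log-normal on linear intensities, the natural model
for non-negative microarray-like data.  Every generator is deterministic
given its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io_config import (
    LINEAR,
    ClinicalRecord,
    ExpressionMatrix,
    ValidationError,
)

# 22-leukocyte panel plus the five types added for marrow deconvolution.
LM22_LIKE_TYPES = (
    "B.cells.naive", "B.cells.memory", "Plasma.cells",
    "T.cells.CD8", "T.cells.CD4.naive", "T.cells.CD4.memory.resting",
    "T.cells.CD4.memory.activated", "T.cells.follicular.helper",
    "T.cells.regulatory", "T.cells.gamma.delta",
    "NK.cells.resting", "NK.cells.activated",
    "Monocytes", "Macrophages.M0", "Macrophages.M1", "Macrophages.M2",
    "Dendritic.cells.resting", "Dendritic.cells.activated",
    "Mast.cells.resting", "Mast.cells.activated",
    "Eosinophils", "Neutrophils",
)
ADDED_TYPES = ("MM.plasma.cells", "PlasmaMemory", "Adipocytes", "Osteoblasts", "Osteoclasts")
CELL_TYPES_27 = LM22_LIKE_TYPES + ADDED_TYPES
TUMOR_TYPE = "MM.plasma.cells"

# the correlated myeloid-lineage estimates whose depletion defines the
# adverse microenvironment
GRANULOCYTE_TYPES = (
    "Mast.cells.resting", "Mast.cells.activated",
    "Eosinophils", "Neutrophils", "Monocytes",
)

LOW_GRANULOCYTE_CLUSTER = 5
ORPHAN_LABEL = "orphan"


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=shape)


# ---------------------------------------------------------------------------
# Reference profiles
# ---------------------------------------------------------------------------


@dataclass
class ReferenceProfileSet:
    """Purified per-replicate profiles plus per-type means."""

    cell_types: list
    profiles: ExpressionMatrix            # genes x replicate samples
    replicate_map: dict                   # sample_id -> cell_type
    mean_profiles: pd.DataFrame           # genes x cell_types

    def __post_init__(self) -> None:
        counts = pd.Series(list(self.replicate_map.values())).value_counts()
        for ct in self.cell_types:
            if counts.get(ct, 0) < 2:
                raise ValidationError(f"cell type {ct} has fewer than 2 replicates")

    def replicates_of(self, cell_type: str) -> list:
        return [s for s, ct in self.replicate_map.items() if ct == cell_type]


def generate_reference_profiles(
    n_genes: int = 400,
    cell_types=CELL_TYPES_27,
    markers_per_type: int = 10,
    noise_cv: float = 0.15,
    n_replicates: int = 3,
    seed: int = 0,
    marker_fold: float = 12.0,
) -> ReferenceProfileSet:
    """Build purified reference profiles with type-specific marker genes.

    Each cell type gets ``markers_per_type`` genes expressed ``marker_fold``
    (>= 8) times above its background level in that type only; replicates are
    the type mean times log-normal noise with the given CV.
    """
    cell_types = list(cell_types)
    if n_genes < len(cell_types) * markers_per_type:
        raise ValidationError(
            f"n_genes={n_genes} cannot host {len(cell_types)}x{markers_per_type} markers"
        )
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    if marker_fold < 8:
        raise ValidationError("marker_fold must be >= 8 so markers dominate background")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    base = rng.uniform(20.0, 200.0, size=n_genes)  # shared background intensity
    means = np.tile(base[:, None], (1, len(cell_types)))
    for j, ct in enumerate(cell_types):
        rows = slice(j * markers_per_type, (j + 1) * markers_per_type)
        means[rows, j] *= marker_fold * rng.uniform(1.0, 2.0, size=markers_per_type)
    mean_profiles = pd.DataFrame(means, index=genes, columns=cell_types)

    cols, rep_map = {}, {}
    for ct in cell_types:
        for r in range(n_replicates):
            sid = f"{ct}_rep{r + 1}"
            cols[sid] = mean_profiles[ct].to_numpy() * _lognormal_factors(rng, noise_cv, n_genes)
            rep_map[sid] = ct
    profiles = ExpressionMatrix(pd.DataFrame(cols, index=genes), scale=LINEAR)
    return ReferenceProfileSet(cell_types, profiles, rep_map, mean_profiles)


# ---------------------------------------------------------------------------
# Bulk mixtures
# ---------------------------------------------------------------------------


def generate_mixtures(
    refs: ReferenceProfileSet,
    n_samples: int,
    dirichlet_alpha,
    noise_cv: float = 0.1,
    seed: int = 0,
    sample_prefix: str = "mix",
):
    """Dirichlet-proportion bulk mixtures of the reference mean profiles.

    Returns (ExpressionMatrix, true_proportions DataFrame); proportion rows
    sum to 1 and the noiseless bulk equals the proportion-weighted sum of
    the per-type mean profiles.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if alpha.shape != (len(refs.cell_types),) or (alpha <= 0).any():
        raise ValidationError("dirichlet_alpha must be positive, one entry per cell type")
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(alpha, size=n_samples)  # samples x types
    means = refs.mean_profiles.to_numpy()         # genes x types
    bulk = means @ props.T
    bulk = bulk * _lognormal_factors(rng, noise_cv, bulk.shape)
    sample_ids = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    em = ExpressionMatrix(
        pd.DataFrame(bulk, index=refs.mean_profiles.index, columns=sample_ids)
    )
    tp = pd.DataFrame(props, index=sample_ids, columns=refs.cell_types)
    return em, tp


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------


@dataclass
class ClusterSpec:
    """Planted microenvironment cluster: composition tilt and tumor burden."""

    label: int
    weight: float
    multipliers: dict = field(default_factory=dict)   # cell type -> composition multiplier
    tumor_beta: tuple = (4.0, 12.0)                   # Beta(a, b) for tumor fraction f


@dataclass
class CohortParams:
    """Generator settings for a full synthetic cohort.

    Hazard model: PFS and OS times are exponential with per-patient rate
    baseline * exp(sum coef_i * feature_i); censoring is an independent
    exponential.  Features: gep70_high, iss3, mast_low (bottom quartile of
    the true WBM mast-cell percentage) and low-granulocyte cluster
    membership.  Effect sizes follow the printed group contrasts of the
    study this emulates in ORDER (risk flag strongest, then stage, then the
    mast contrast) with deliberately wide gaps so the planted hierarchy is
    the dominant signal at n = 354; they are structural-recovery settings,
    not estimates of the study's effect sizes.  ``force_tumor_fraction``
    overrides the per-cluster Beta draw with a constant f (0 disables tumor
    admixture entirely — useful for exactness checks).
    """

    n_patients: int = 354
    clusters: list = None
    orphan_fraction: float = 0.03
    noise_cv: float = 0.1
    dirichlet_concentration: float = 1500.0
    hazard_coefs: dict = None
    baseline_hazard_pfs: float = 1.0 / 110.0   # per month
    baseline_hazard_os: float = 1.0 / 220.0
    censoring_rate: float = 1.0 / 130.0
    gep70_prevalence: float = 0.20
    iss3_prevalence: float = 0.26
    gep70_c5_enrichment: float = 1.8
    iss3_c5_enrichment: float = 1.6
    followup_timepoint_prob: float = 0.55
    relapse_window_depletion: float = 0.4
    round_months: bool = False
    n_genes: int = 2700
    markers_per_type: int = 10
    ref_noise_cv: float = 0.15
    force_tumor_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.clusters is None:
            self.clusters = default_clusters()
        if self.hazard_coefs is None:
            # risk hierarchy mirrors the printed conditional-inference tree:
            # tumor risk flag strongest, then stage, then the mast contrast
            self.hazard_coefs = {
                "gep70_high": np.log(8.0),
                "iss3": np.log(3.4),
                "mast_low": np.log(2.8),
                "low_gran_cluster": np.log(1.1),
            }
        low_gran = [c for c in self.clusters if c.label == LOW_GRANULOCYTE_CLUSTER]
        if len(self.clusters) < 2 or not low_gran:
            raise ValidationError(
                "need >= 2 planted clusters including the low-granulocyte one"
            )
        for c in self.clusters:
            for k in c.multipliers:
                if k not in CELL_TYPES_27:
                    raise ValidationError(f"cluster {c.label}: unknown cell type {k}")
        extra = set(self.hazard_coefs) - {"gep70_high", "iss3", "mast_low", "low_gran_cluster"}
        if extra:
            raise ValidationError(f"unknown hazard coefficients: {sorted(extra)}")


def default_clusters() -> list:
    """Five planted microenvironment clusters.

    Cluster 5 is the adverse low-granulocyte state: depleted mast cells,
    eosinophils, neutrophils and monocytes, elevated T cells, and a higher
    tumor burden (Beta(6, 10) vs Beta(4, 12)), reproducing the tumor-burden
    confound the pipeline must separate from the microenvironment signal.
    """
    gran_low = {ct: 0.18 for ct in GRANULOCYTE_TYPES}
    t_up = {
        "T.cells.CD8": 1.5, "T.cells.CD4.naive": 1.4,
        "T.cells.CD4.memory.resting": 1.4,
    }
    return [
        ClusterSpec(1, 0.17, {"Osteoblasts": 0.15, "Adipocytes": 0.25,
                              "Macrophages.M1": 0.3, "Dendritic.cells.resting": 0.35,
                              "Osteoclasts": 0.4}),
        ClusterSpec(2, 0.15, {"Macrophages.M2": 3.5, "Osteoblasts": 2.5,
                              "Osteoclasts": 0.3}),
        ClusterSpec(3, 0.08, {"NK.cells.resting": 3.5, "NK.cells.activated": 3.5,
                              "Osteoclasts": 2.5, "Osteoblasts": 0.4}),
        ClusterSpec(4, 0.30, {ct: 2.2 for ct in GRANULOCYTE_TYPES}),
        ClusterSpec(5, 0.30, {**gran_low, **t_up}, tumor_beta=(6.0, 10.0)),
    ]


# baseline microenvironment composition (fractions over the 26 non-tumor types)
_BASE_ENV = {
    "B.cells.naive": 0.02, "B.cells.memory": 0.015, "Plasma.cells": 0.025,
    "T.cells.CD8": 0.07, "T.cells.CD4.naive": 0.04,
    "T.cells.CD4.memory.resting": 0.04, "T.cells.CD4.memory.activated": 0.02,
    "T.cells.follicular.helper": 0.015, "T.cells.regulatory": 0.015,
    "T.cells.gamma.delta": 0.01,
    "NK.cells.resting": 0.03, "NK.cells.activated": 0.02,
    "Monocytes": 0.09, "Macrophages.M0": 0.04, "Macrophages.M1": 0.02,
    "Macrophages.M2": 0.03, "Dendritic.cells.resting": 0.015,
    "Dendritic.cells.activated": 0.01,
    "Mast.cells.resting": 0.06, "Mast.cells.activated": 0.04,
    "Eosinophils": 0.06, "Neutrophils": 0.17,
    "PlasmaMemory": 0.01, "Adipocytes": 0.08,
    "Osteoblasts": 0.05, "Osteoclasts": 0.05,
}

_TIMEPOINT_DAYS = {
    "pretreatment": 0,
    "postinduction": 90,
    "post_transplant": 200,
    "postconsolidation": 300,
    "postmaintenance": 540,
}

# cluster transition toward the high-granulocyte remission state after therapy
_POST_TREATMENT_SHIFT = {1: 0.7, 2: 0.35, 3: 0.3, 4: 0.0, 5: 0.55}


@dataclass
class SyntheticCohort:
    refs: ReferenceProfileSet
    wbm: ExpressionMatrix
    cd138: ExpressionMatrix
    true_proportions: pd.DataFrame        # samples x 27 types, rows sum to 1
    true_tumor_fraction: pd.Series
    true_cluster: pd.Series               # planted label per sample (int or "orphan")
    clinical: list
    generator_params: CohortParams

    def pretreatment_samples(self) -> list:
        return [r.sample_id for r in self.clinical if r.timepoint == "pretreatment"]


def _env_alpha(params: CohortParams, spec: ClusterSpec) -> np.ndarray:
    env_types = [ct for ct in CELL_TYPES_27 if ct != TUMOR_TYPE]
    w = np.array([_BASE_ENV[ct] * spec.multipliers.get(ct, 1.0) for ct in env_types])
    w = w / w.sum()
    return w * params.dirichlet_concentration


def generate_cohort(params: Optional[CohortParams] = None, seed: int = 0) -> SyntheticCohort:
    """Generate a full matched WBM / CD138+ cohort with survival outcomes.

    WBM column = f * tumor_profile + (1 - f) * microenvironment mixture,
    all times multiplicative log-normal noise; the matched CD138+ column is
    the tumor mean profile times noise.  All ground truth is retained.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    refs = generate_reference_profiles(
        n_genes=params.n_genes,
        markers_per_type=params.markers_per_type,
        noise_cv=params.ref_noise_cv,
        seed=int(rng.integers(2 ** 31)),
    )
    env_types = [ct for ct in CELL_TYPES_27 if ct != TUMOR_TYPE]
    env_means = refs.mean_profiles[env_types].to_numpy()
    tumor_mean = refs.mean_profiles[TUMOR_TYPE].to_numpy()
    genes = refs.mean_profiles.index

    specs = {c.label: c for c in params.clusters}
    weights = np.array([c.weight for c in params.clusters], dtype=float)
    weights = weights / weights.sum()

    n = params.n_patients
    pat_cluster = rng.choice([c.label for c in params.clusters], size=n, p=weights)
    orphan_mask = rng.random(n) < params.orphan_fraction

    # patient-level clinical covariates; the adverse cluster is enriched for
    # high-risk disease, as in the cohort this emulates
    gep70 = np.zeros(n, dtype=bool)
    iss = np.zeros(n, dtype=int)
    for i in range(n):
        adverse = pat_cluster[i] == LOW_GRANULOCYTE_CLUSTER
        w = weights[[c.label for c in params.clusters].index(LOW_GRANULOCYTE_CLUSTER)]
        ge, ie = params.gep70_c5_enrichment, params.iss3_c5_enrichment
        # keep the marginal prevalence fixed while enriching the adverse cluster
        g_base = params.gep70_prevalence / (w * ge + (1 - w))
        p_gep = g_base * (ge if adverse else 1.0)
        gep70[i] = rng.random() < p_gep
        i_base = params.iss3_prevalence / (w * ie + (1 - w))
        p3 = i_base * (ie if adverse else 1.0)
        p1 = max(0.05, 0.37 * (0.5 if adverse else 1.3))
        p1 = min(p1, 1 - p3)
        iss[i] = rng.choice([1, 2, 3], p=[p1, 1 - p1 - p3, p3])
    age = rng.normal(58.5, 9.0, size=n).clip(30, 80)
    sex = rng.choice(["F", "M"], size=n, p=[0.39, 0.61])

    # per-patient pretreatment sample composition and tumor fraction
    def draw_sample(cluster_label, is_orphan, in_relapse_window=False):
        if is_orphan:
            alpha = rng.dirichlet(np.ones(len(env_types))) * params.dirichlet_concentration
            alpha = np.maximum(alpha, 1e-3)
            f = rng.beta(2, 10)
        else:
            spec = specs[cluster_label]
            alpha = _env_alpha(params, spec)
            f = rng.beta(*spec.tumor_beta)
        if params.force_tumor_fraction is not None:
            f = float(params.force_tumor_fraction)
        env = rng.dirichlet(alpha)
        if in_relapse_window:
            idx = [env_types.index(ct) for ct in GRANULOCYTE_TYPES]
            env[idx] *= params.relapse_window_depletion
            env = env / env.sum()
        return env, f

    # survival outcomes from the planted proportional-hazards model
    pre_env = []
    pre_f = np.zeros(n)
    for i in range(n):
        env, f = draw_sample(pat_cluster[i], orphan_mask[i])
        pre_env.append(env)
        pre_f[i] = f
    pre_env = np.array(pre_env)
    mast_idx = [env_types.index("Mast.cells.resting"), env_types.index("Mast.cells.activated")]
    mast_pct = 100.0 * (1 - pre_f) * pre_env[:, mast_idx].sum(axis=1)
    mast_low = mast_pct <= np.quantile(mast_pct, 0.25)

    coefs = params.hazard_coefs
    lin = (
        coefs["gep70_high"] * gep70
        + coefs["iss3"] * (iss == 3)
        + coefs["mast_low"] * mast_low
        + coefs["low_gran_cluster"] * (pat_cluster == LOW_GRANULOCYTE_CLUSTER)
    )
    rate_pfs = params.baseline_hazard_pfs * np.exp(lin)
    rate_os = params.baseline_hazard_os * np.exp(0.7 * lin)
    t_pfs = rng.exponential(1.0 / rate_pfs)
    t_os = np.maximum(rng.exponential(1.0 / rate_os), t_pfs)
    if params.censoring_rate > 0:
        c = rng.exponential(1.0 / params.censoring_rate, size=n)
    else:
        c = np.full(n, np.inf)
    pfs_months = np.minimum(t_pfs, c)
    pfs_event = t_pfs <= c
    os_months = np.minimum(t_os, c)
    os_event = t_os <= c
    if params.round_months:
        pfs_months = np.maximum(np.round(pfs_months), 0.5)
        os_months = np.maximum(np.round(os_months), 0.5)

    # assemble samples over timepoints
    wbm_cols, cd_cols, prop_rows, fs, cluster_labels, records = {}, {}, [], [], [], []
    sample_index = []
    for i in range(n):
        pid = f"P{i:04d}"
        relapse_day = t_pfs[i] * 30.44 if pfs_event[i] else None
        current = pat_cluster[i]
        for tp, day in _TIMEPOINT_DAYS.items():
            if tp != "pretreatment":
                if rng.random() > params.followup_timepoint_prob:
                    continue
                if day > os_months[i] * 30.44:
                    continue
                if not orphan_mask[i] and rng.random() < _POST_TREATMENT_SHIFT[current]:
                    current = 4
            sid = f"{pid}_{tp}"
            offset = None
            in_window = False
            if relapse_day is not None:
                offset = int(round(relapse_day - day))
                in_window = (
                    tp != "pretreatment"
                    and -30 <= offset <= 180
                )
            if tp == "pretreatment":
                env, f = pre_env[i], pre_f[i]
            else:
                env, f = draw_sample(current, orphan_mask[i], in_window)
            tumor_profile = tumor_mean * _lognormal_factors(rng, params.noise_cv, len(genes))
            env_profile = (env_means @ env) * _lognormal_factors(rng, params.noise_cv, len(genes))
            # scale both components to a common total intensity so f is the
            # fraction of RNA signal contributed by the tumor
            total = env_means.sum(axis=0).mean() * 1.0
            tumor_profile *= tumor_mean.sum() / tumor_profile.sum() * total / tumor_mean.sum()
            env_profile *= total / env_profile.sum()
            wbm_cols[sid] = f * tumor_profile + (1 - f) * env_profile
            cd_cols[sid] = tumor_profile
            full = np.zeros(len(CELL_TYPES_27))
            for j, ct in enumerate(CELL_TYPES_27):
                if ct == TUMOR_TYPE:
                    full[j] = f
                else:
                    full[j] = (1 - f) * env[env_types.index(ct)]
            prop_rows.append(full)
            fs.append(f)
            cluster_labels.append(ORPHAN_LABEL if orphan_mask[i] else int(current))
            sample_index.append(sid)
            remission = None
            if tp != "pretreatment":
                remission = not in_window and (
                    relapse_day is None or relapse_day - day > 365
                )
            records.append(
                ClinicalRecord(
                    patient_id=pid,
                    sample_id=sid,
                    timepoint=tp,
                    pfs_months=float(pfs_months[i]),
                    pfs_event=bool(pfs_event[i]),
                    os_months=float(os_months[i]),
                    os_event=bool(os_event[i]),
                    iss_stage=int(iss[i]),
                    gep70_high=bool(gep70[i]),
                    cytogenetic_flags=frozenset(
                        ["del17p"] if rng.random() < (0.15 if gep70[i] else 0.08) else []
                    ),
                    age_years=float(age[i]),
                    sex=str(sex[i]),
                    tumor_pct_pathologist=float(np.clip(
                        100 * fs[-1] + rng.normal(0, 5), 0, 100)),
                    relapse_date_offset_days=offset,
                    complete_remission=remission,
                )
            )

    wbm = ExpressionMatrix(pd.DataFrame(wbm_cols, index=genes))
    cd138 = ExpressionMatrix(pd.DataFrame(cd_cols, index=genes))
    props = pd.DataFrame(prop_rows, index=sample_index, columns=list(CELL_TYPES_27))
    return SyntheticCohort(
        refs=refs,
        wbm=wbm,
        cd138=cd138,
        true_proportions=props,
        true_tumor_fraction=pd.Series(fs, index=sample_index, name="tumor_fraction"),
        true_cluster=pd.Series(cluster_labels, index=sample_index, name="cluster"),
        clinical=records,
        generator_params=params,
    )


def minimal_cohort_params(**overrides) -> CohortParams:
    """Small, fast preset for unit tests (60 patients, 200 genes)."""
    defaults = dict(n_patients=60, n_genes=1350, markers_per_type=5,
                    followup_timepoint_prob=0.4)
    defaults.update(overrides)
    return CohortParams(**defaults)


# ---------------------------------------------------------------------------
# Printed contingency tables (study inputs)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyFixture:
    """Per-cluster success/total counts for one demographics row."""

    name: str
    successes: tuple
    totals: tuple
    printed_p: Optional[float] = None

    def as_table(self) -> np.ndarray:
        s = np.asarray(self.successes)
        t = np.asarray(self.totals)
        return np.vstack([s, t - s])


_T1_TOTALS = (59, 54, 28, 76, 107, 30)
_T1_TOTALS_CYTO = (58, 52, 27, 74, 104, 30)


def table1_fixture() -> dict:
    """The printed baseline-demographics counts per microenvironment cluster
    (columns: clusters 1-5 then orphan) and the relapsed-refractory trial
    low-mast enrichment 2x2 (207/295 relapsed vs 87/320 pretreatment)."""
    rows = {
        "Age65": ContingencyFixture("Age65", (18, 17, 3, 24, 32, 10), _T1_TOTALS, 0.284),
        "Female": ContingencyFixture("Female", (21, 13, 10, 32, 53, 8), _T1_TOTALS, 0.023),
        "White": ContingencyFixture("White", (54, 50, 27, 67, 90, 26), _T1_TOTALS, 0.326),
        "ISS1": ContingencyFixture("ISS1", (17, 26, 12, 44, 17, 14), _T1_TOTALS, 0.001),
        "ISS2": ContingencyFixture("ISS2", (23, 22, 11, 22, 45, 9), _T1_TOTALS, 0.485),
        "ISS3": ContingencyFixture("ISS3", (19, 6, 5, 10, 45, 7), _T1_TOTALS, 0.001),
        "Albumin": ContingencyFixture("Albumin", (23, 13, 9, 20, 49, 10), _T1_TOTALS, 0.043),
        "B2M_ge_3.5": ContingencyFixture(
            "B2M_ge_3.5", (35, 21, 12, 21, 81, 13), _T1_TOTALS, 0.001),
        "B2M_gt_5.5": ContingencyFixture(
            "B2M_gt_5.5", (19, 6, 5, 10, 45, 7), _T1_TOTALS, 0.001),
        "Creatinine": ContingencyFixture(
            "Creatinine", (5, 3, 1, 2, 4, 1), _T1_TOTALS, None),
        "Hb": ContingencyFixture("Hb", (24, 12, 6, 14, 68, 10), _T1_TOTALS, 0.001),
        "LDH": ContingencyFixture("LDH", (8, 10, 5, 12, 31, 7), _T1_TOTALS, 0.171),
        "Cytogenetic": ContingencyFixture(
            "Cytogenetic", (17, 18, 8, 22, 53, 13), _T1_TOTALS_CYTO, 0.026),
    }
    rows["STRATUS_mast_low"] = ContingencyFixture(
        "STRATUS_mast_low", (207, 87), (295, 320), None
    )
    return rows
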