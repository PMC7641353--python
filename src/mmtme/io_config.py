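"""Tabular I/O and pipeline configuration.

Expression data are stored linear-scale internally (genes x samples); log2
inputs are converted once at load, flagged explicitly rather than guessed.
Percentages are 0-100 everywhere user-facing, fractions 0-1 internally.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

LINEAR = "linear"
LOG2 = "log2"

TIMEPOINTS = (
    "pretreatment",
    "postinduction",
    "post_transplant",
    "postconsolidation",
    "postmaintenance",
)


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples intensity table.

    ``data`` is a DataFrame indexed by gene id with sample-id columns.
    ``scale`` records whether values are linear intensities or log2; all
    pipeline arithmetic (mixing, tumor subtraction) assumes linear scale.
    """

    data: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValidationError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("expression values must be finite")
        if self.scale == LINEAR and (values < 0).any():
            raise ValidationError("linear-scale expression values must be non-negative")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_linear(self) -> "ExpressionMatrix":
        """Return a linear-scale copy (2**x for log2 input)."""
        if self.scale == LINEAR:
            return self
        return ExpressionMatrix(np.power(2.0, self.data), scale=LINEAR)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], scale=self.scale)


def read_expression_matrix(path, fmt: str = "tsv", scale: str = LINEAR) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV/CSV or GCT 1.2.

    First column holds gene ids, header row sample ids.  GCT files carry a
    ``#1.2`` version line and a dimensions line before the header; the
    Description column is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas names the line
            raise ValidationError(f"malformed {fmt} file {path}: {exc}") from exc
    elif fmt == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ValidationError(f"{path}: expected '#1.2' header, got {version!r} (line 1)")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise ValidationError(f"{path}: malformed dimensions line (line 2)")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
        df = df.drop(columns=["Description"], errors="ignore")
        if df.shape != (n_genes, n_samples):
            raise ValidationError(
                f"{path}: dimensions line says {n_genes}x{n_samples}, data is {df.shape}"
            )
    else:
        raise ValidationError(f"unknown format {fmt!r}; use tsv, csv or gct")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    em = ExpressionMatrix(df, scale=scale)
    return em.to_linear()


def write_expression_matrix(em: ExpressionMatrix, path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt in ("tsv", "csv"):
        em.data.to_csv(path, sep="\t" if fmt == "tsv" else ",", index_label="gene_id")
    elif fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{em.shape[0]}\t{em.shape[1]}\n")
            out = em.data.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValidationError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Clinical records
# ---------------------------------------------------------------------------


@dataclass
class ClinicalRecord:
    """One bone-marrow sample with its patient-level outcome data.

    Times are months; ``relapse_date_offset_days`` is (relapse date - sample
    date), positive when the sample precedes relapse.  Missing values stay
    missing (None), never imputed.
    """

    patient_id: str
    sample_id: str
    timepoint: str
    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool
    iss_stage: Optional[int] = None
    gep70_high: Optional[bool] = None
    cytogenetic_flags: frozenset = frozenset()
    age_years: Optional[float] = None
    sex: Optional[str] = None
    tumor_pct_pathologist: Optional[float] = None
    relapse_date_offset_days: Optional[int] = None
    complete_remission: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"unknown timepoint {self.timepoint!r}; allowed: {', '.join(TIMEPOINTS)}"
            )
        for name in ("pfs_months", "os_months"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be a non-negative real, got {v!r}")
        if self.iss_stage is not None and self.iss_stage not in (1, 2, 3):
            raise ValidationError(f"iss_stage must be 1, 2 or 3, got {self.iss_stage!r}")
        if self.tumor_pct_pathologist is not None and not (
            0 <= self.tumor_pct_pathologist <= 100
        ):
            raise ValidationError("tumor_pct_pathologist must be in [0, 100]")


_BOOL_MAP = {"1": True, "0": False, "true": True, "false": False, "yes": True, "no": False}


def _parse_bool(v, column: str):
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    s = str(v).strip().lower()
    if s in _BOOL_MAP:
        return _BOOL_MAP[s]
    if s in ("1.0", "0.0"):
        return s == "1.0"
    raise ValidationError(f"column {column}: cannot parse boolean from {v!r}")


def _parse_opt(v, cast):
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return cast(v)


def read_clinical_table(path) -> list[ClinicalRecord]:
    """Read a clinical CSV into typed records.

    Required columns: patient_id, sample_id, timepoint, pfs_months,
    pfs_event, os_months, os_event.  Optional: iss_stage, gep70_high,
    cytogenetic_flags (semicolon-separated), age_years, sex,
    tumor_pct_pathologist, relapse_date_offset_days, complete_remission.
    """
    df = pd.read_csv(path)
    required = [
        "patient_id", "sample_id", "timepoint",
        "pfs_months", "pfs_event", "os_months", "os_event",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        flags = row.get("cytogenetic_flags")
        if isinstance(flags, str) and flags.strip():
            cyto = frozenset(f.strip() for f in flags.split(";") if f.strip())
        else:
            cyto = frozenset()
        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                sample_id=str(row["sample_id"]),
                timepoint=str(row["timepoint"]),
                pfs_months=float(row["pfs_months"]),
                pfs_event=bool(_parse_bool(row["pfs_event"], "pfs_event")),
                os_months=float(row["os_months"]),
                os_event=bool(_parse_bool(row["os_event"], "os_event")),
                iss_stage=_parse_opt(row.get("iss_stage"), lambda v: int(float(v))),
                gep70_high=_parse_bool(row.get("gep70_high"), "gep70_high"),
                cytogenetic_flags=cyto,
                age_years=_parse_opt(row.get("age_years"), float),
                sex=_parse_opt(row.get("sex"), str),
                tumor_pct_pathologist=_parse_opt(row.get("tumor_pct_pathologist"), float),
                relapse_date_offset_days=_parse_opt(
                    row.get("relapse_date_offset_days"), lambda v: int(float(v))
                ),
                complete_remission=_parse_bool(
                    row.get("complete_remission"), "complete_remission"
                ),
            )
        )
    seen: dict[str, str] = {}
    for r in records:
        if r.sample_id in seen and seen[r.sample_id] != r.timepoint:
            raise ValidationError(f"sample {r.sample_id} mapped to two timepoints")
        seen[r.sample_id] = r.timepoint
    return records


def write_clinical_table(records: list[ClinicalRecord], path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["cytogenetic_flags"] = ";".join(sorted(r.cytogenetic_flags))
        d["pfs_event"] = int(r.pfs_event)
        d["os_event"] = int(r.os_event)
        for b in ("gep70_high", "complete_remission"):
            if d[b] is not None:
                d[b] = int(d[b])
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All scalar thresholds and tunables used across the pipeline.

    Defaults are the study's reported operating points: top 10% variance
    genes for clustering, stepwise entry/removal at p<0.1 / p>0.05, survival
    trees at permutation p=0.01, differential expression at FDR 0.05 with
    |log2FC|>0.66, the 8.97% mast-cell threshold, and the 180/30-day
    relapse window.
    """

    variance_gene_fraction: float = 0.10
    stepwise_enter_p: float = 0.1
    stepwise_remove_p: float = 0.05
    tree_alpha: float = 0.01
    tree_permutations: int = 10_000
    de_fdr: float = 0.05
    de_abs_log2fc: float = 0.66
    mast_low_threshold_pct: float = 8.97
    relapse_window_before_days: int = 180
    relapse_window_after_days: int = 30
    dynamics_fdr: float = 0.05
    rng_seed: int = 0
    # deconvolution
    en_mixing: float = 0.05
    deconv_repeats: int = 10
    gene_subsample: float = 0.8
    # clustering
    cluster_k_min: int = 2
    cluster_k_max: int = 10
    min_cluster_fraction: float = 0.03
    pca_dims: int = 20
    assign_corr_floor: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "stepwise_enter_p", "stepwise_remove_p", "tree_alpha",
            "de_fdr", "dynamics_fdr",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0,1), got {v}")
        for name in ("variance_gene_fraction", "gene_subsample", "min_cluster_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0,1], got {v}")
        if not 0 <= self.en_mixing <= 1:
            raise ValidationError("en_mixing must be in [0,1]")
        if self.cluster_k_min < 1 or self.cluster_k_max < self.cluster_k_min:
            raise ValidationError("invalid cluster k range")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
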