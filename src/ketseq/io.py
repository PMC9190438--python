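"""Expression-data containers, TSV readers/writers, FPKM normalization and
covariation-based sample QC.

Matrices are genes x samples.  Counts are raw fragment counts; expression
values are FPKM-style (count * 1e9 / (length_bp * library_size)), the
package's stand-in for the sFPKM unit used in the source datasets (the
additional insert-size / genomic-contamination adjustments of that unit are
not modeled).

TSV dialect: first column ``gene``, header row of sample ids, tab
separated, '.' decimal, no quoting.  Metadata TSV columns: sample_id,
animal_id, region, sex, group.  Missing values are rejected — the pipeline
has no imputation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "CountMatrix",
    "ExpressionMatrix",
    "compute_fpkm",
    "qc_exclude",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
]

#: Time groups of the infusion design, in temporal order.
GROUPS = ("Control", "1h", "10h", "Recovery")

_META_COLS = ["sample_id", "animal_id", "region", "sex", "group"]


def _check_meta(meta: pd.DataFrame, columns) -> pd.DataFrame:
    missing = set(_META_COLS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    if set(meta["sample_id"]) != set(columns):
        raise ValueError("metadata sample ids do not match matrix columns")
    return meta.set_index("sample_id", drop=False).loc[list(columns)].reset_index(drop=True)


@dataclass
class CountMatrix:
    """Integer gene x sample counts with gene lengths and library sizes."""

    counts: pd.DataFrame
    gene_lengths: pd.Series
    library_sizes: pd.Series
    meta: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.isna().any().any():
            raise ValueError("counts contain missing values")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive and cover all genes")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any():
            raise ValueError("library sizes must cover all samples")
        if self.meta is not None:
            self.meta = _check_meta(self.meta, self.counts.columns)

    @property
    def genes(self):
        return self.counts.index

    @property
    def samples(self):
        return self.counts.columns


@dataclass
class ExpressionMatrix:
    """Non-negative real gene x sample expression values (sFPKM role)."""

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression values contain missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        self.meta = _check_meta(self.meta, self.values.columns)

    def samples_of(self, group: str = None, region: str = None, sex: str = None):
        """Sample ids matching the given metadata filters."""
        m = self.meta
        mask = np.ones(len(m), dtype=bool)
        if group is not None:
            mask &= (m["group"] == group).to_numpy()
        if region is not None:
            mask &= (m["region"] == region).to_numpy()
        if sex is not None:
            mask &= (m["sex"] == sex).to_numpy()
        return list(m.loc[mask, "sample_id"])

    def group_means(self, region: str, sex: str) -> pd.DataFrame:
        """Gene x group mean expression for one region x sex experiment."""
        cols = {}
        for g in GROUPS:
            ids = self.samples_of(group=g, region=region, sex=sex)
            if ids:
                cols[g] = self.values[ids].mean(axis=1)
        if not cols:
            raise ValueError(f"no samples for experiment ({region}, {sex})")
        return pd.DataFrame(cols)


def compute_fpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Normalize counts to FPKM: count * 1e9 / (length_bp * library_size)."""
    if (counts.library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    vals = counts.counts.to_numpy(dtype=float) * 1e9
    vals /= counts.gene_lengths.to_numpy(dtype=float)[:, None]
    vals /= counts.library_sizes.to_numpy(dtype=float)[None, :]
    values = pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)
    if counts.meta is None:
        raise ValueError("count matrix has no sample metadata")
    return ExpressionMatrix(values=values, meta=counts.meta.copy())


def qc_exclude(expr: ExpressionMatrix, min_correlation: float = 0.9):
    """Exclude samples that fail to covary with their experiment.

    For each (region, sex) experiment the Pearson correlation of every
    sample's log2(value + 1) profile with the experiment's median profile is
    computed; samples below ``min_correlation`` are excluded.

    Returns ``(kept, excluded, report)`` where report is a DataFrame with
    one row per sample (sample_id, region, sex, correlation, excluded).
    """
    logv = np.log2(expr.values + 1.0)
    rows = []
    for (region, sex), sub in expr.meta.groupby(["region", "sex"], sort=False):
        ids = list(sub["sample_id"])
        if len(ids) < 3:
            raise ValueError(f"experiment ({region}, {sex}) has fewer than 3 samples")
        block = logv[ids]
        med = block.median(axis=1)
        for sid in ids:
            r = float(np.corrcoef(block[sid], med)[0, 1])
            rows.append((sid, region, sex, r, r < min_correlation))
    report = pd.DataFrame(rows, columns=["sample_id", "region", "sex", "correlation", "excluded"])
    kept = list(report.loc[~report["excluded"], "sample_id"])
    excluded = list(report.loc[report["excluded"], "sample_id"])
    if not kept:
        raise ValueError("all samples excluded by QC")
    return kept, excluded, report


# ---------------------------------------------------------------------------
# TSV round-trip


def write_matrix_tsv(df: pd.DataFrame, path, index_name: str = "gene") -> None:
    out = df.copy()
    out.index.name = index_name
    # no float_format: pandas writes repr(), the shortest round-trip form
    out.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        raise ValueError(f"{path}: matrix contains missing values")
    return df


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    meta[_META_COLS].to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "animal_id": str})
    missing = set(_META_COLS) - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    if meta[_META_COLS].isna().any().any():
        raise ValueError(f"{path}: metadata contains missing values")
    return meta
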