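"""Cohort data model: expression, segmented copy number, sample metadata.

A :class:`Cohort` aligns three tables on a shared sample axis:

* expression — genes x samples, log2(RSEM-like + 1) values;
* copy_number — fixed-width genome segments (100 kb by default) x samples,
  on the convention that 0 is diploid and positive values are amplified;
* metadata — per-sample ER status, subtype label, overall-survival time in
  days and an event flag (1 = death observed, 0 = censored).

All genomic coordinates are 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geomapper import log2_transform

ANNOTATION_COLS = ["gene_id", "chrom", "start", "end", "strand"]
METADATA_COLS = ["sample", "er_status", "subtype", "os_days", "os_event"]

_FLOAT_FMT = "%.6g"


@dataclass
class Cohort:
    expression: pd.DataFrame  # genes x samples, log2 scale
    copy_number: pd.DataFrame  # columns: chrom, start, end, <samples...>
    metadata: pd.DataFrame  # indexed by sample id

    def __post_init__(self) -> None:
        samples = list(self.expression.columns)
        cn_samples = [c for c in self.copy_number.columns if c not in ("chrom", "start", "end")]
        if cn_samples != samples:
            raise ValueError("expression and copy-number matrices must share an identically ordered sample axis")
        if not self.metadata.index.equals(pd.Index(samples)):
            raise ValueError("metadata index must match the sample axis")
        if not np.all(np.isfinite(self.expression.to_numpy())):
            raise ValueError("expression must be finite after log2 transformation")

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def segment_grid(self) -> pd.DataFrame:
        """The (chrom, start, end) segment table without sample columns."""
        return self.copy_number[["chrom", "start", "end"]]


def read_annotation(path) -> pd.DataFrame:
    """Read a BED-like gene annotation TSV (gene_id, chrom, start, end, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(ANNOTATION_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation is missing columns: {sorted(missing)}")
    bad = df[df.start >= df.end]
    if len(bad):
        raise ValueError(f"annotation has {len(bad)} records with start >= end")
    return df[ANNOTATION_COLS]


def write_annotation(df: pd.DataFrame, path) -> None:
    df[ANNOTATION_COLS].to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column gene_id), raw scale."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)


def read_copy_number(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_copy_number(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    missing = set(METADATA_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    return df.set_index("sample")


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample", float_format=_FLOAT_FMT)


def read_cohort(expression_path, copy_number_path, metadata_path) -> Cohort:
    """Load a cohort from TSV files, applying log2(x + 1) to raw expression."""
    raw = read_expression(expression_path)
    expr = log2_transform(raw)
    cn = read_copy_number(copy_number_path)
    meta = read_metadata(metadata_path)
    return Cohort(expression=expr, copy_number=cn, metadata=meta)
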