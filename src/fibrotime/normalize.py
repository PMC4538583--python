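"""Count-matrix ingestion, expressed-gene filtering and RPKM normalization.

The expression unit used throughout the pipeline is RPKM (reads per kilobase
of transcript per million mapped reads),

    RPKM_ij = 1e9 * k_ij / (L_i * N_j)

where ``k_ij`` is the raw count of gene *i* in sample *j*, ``L_i`` the gene
(exon) length in bp, and ``N_j`` the total number of counted reads in sample
*j* computed *before* any gene filtering.  Genes are considered expressed only
if their raw count is positive in every sample; this guarantees strictly
positive RPKM so the log2 transform never needs a pseudocount.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

REQUIRED_SAMPLE_COLUMNS = ("cell_line", "pd", "replicate")


class SchemaError(ValueError):
    """Raised when a count matrix or sample sheet violates its contract."""


@dataclasses.dataclass
class CountMatrix:
    """Raw gene counts with per-sample metadata and gene lengths.

    Parameters
    ----------
    counts
        Genes x samples matrix of non-negative integer counts.
    sample_meta
        Indexed by sample id; must provide ``cell_line``, ``pd`` (numeric
        population doubling) and ``replicate`` columns for every sample.
    gene_lengths
        Gene length in bp, indexed like the count rows.
    total_counts
        Per-sample sequencing depth (sum of counts before any filtering).
        Computed from ``counts`` when omitted; carried through filtering so
        RPKM denominators always refer to the pre-filter depth.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_lengths: pd.Series
    total_counts: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape[1] == 0:
            raise SchemaError("count matrix has no samples")
        arr = c.to_numpy()
        if len(c) and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise SchemaError("counts must be integers")
            self.counts = c = c.round().astype(np.int64)
            arr = c.to_numpy()
        if (arr < 0).any():
            raise SchemaError("counts must be non-negative")
        missing = [col for col in REQUIRED_SAMPLE_COLUMNS if col not in self.sample_meta.columns]
        if missing:
            raise SchemaError(f"sample sheet missing columns: {missing}")
        absent = c.columns.difference(self.sample_meta.index)
        if len(absent):
            raise SchemaError(f"samples without metadata: {list(absent)}")
        self.sample_meta = self.sample_meta.loc[c.columns]
        lengths = self.gene_lengths.reindex(c.index)
        if lengths.isna().any():
            raise SchemaError("gene lengths missing for some genes")
        if (lengths <= 0).any():
            raise SchemaError("gene lengths must be positive")
        self.gene_lengths = lengths.astype(float)
        if self.total_counts is None:
            self.total_counts = c.sum(axis=0).astype(np.int64)
        else:
            self.total_counts = self.total_counts.reindex(c.columns)
            if self.total_counts.isna().any():
                raise SchemaError("total_counts missing for some samples")

    @property
    def gene_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[list(sample_ids)],
            sample_meta=self.sample_meta.loc[list(sample_ids)],
            gene_lengths=self.gene_lengths,
            total_counts=self.total_counts[list(sample_ids)],
        )


@dataclasses.dataclass
class ExpressionMatrix:
    """RPKM or log2-RPKM values with a scale tag."""

    values: pd.DataFrame
    scale: str  # "rpkm" or "log2rpkm"

    def __post_init__(self) -> None:
        if self.scale not in ("rpkm", "log2rpkm"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.scale == "rpkm" and (self.values.to_numpy() < 0).any():
            raise ValueError("RPKM values must be non-negative")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


def filter_expressed(cm: CountMatrix) -> CountMatrix:
    """Retain genes whose raw count is > 0 in every sample (order preserved).

    Genes with a zero anywhere are removed; removing everything is legal and
    only warns.  Idempotent.  Pre-filter sample depths are preserved so that
    downstream RPKM denominators are unaffected by filtering.
    """
    mask = (cm.counts > 0).all(axis=1)
    if not mask.any():
        warnings.warn("no gene is expressed in every sample; result is empty")
    return CountMatrix(
        counts=cm.counts.loc[mask],
        sample_meta=cm.sample_meta,
        gene_lengths=cm.gene_lengths.loc[mask],
        total_counts=cm.total_counts,
    )


def compute_rpkm(cm: CountMatrix) -> ExpressionMatrix:
    """RPKM_ij = 1e9 * k_ij / (L_i * N_j), N_j the pre-filter sample depth."""
    totals = cm.total_counts
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero total count for sample(s): {list(zero.index)}")
    denom = np.outer(cm.gene_lengths.to_numpy(), totals.to_numpy(dtype=float))
    values = pd.DataFrame(
        cm.counts.to_numpy(dtype=float) * 1e9 / denom,
        index=cm.counts.index,
        columns=cm.counts.columns,
    )
    return ExpressionMatrix(values=values, scale="rpkm")


def log2_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2 of an all-positive RPKM matrix (no pseudocount)."""
    if em.scale != "rpkm":
        raise ValueError("log2_transform expects an RPKM-scale matrix")
    if (em.values.to_numpy() <= 0).any():
        raise ValueError(
            "non-positive RPKM encountered; filter to expressed genes "
            "(raw count > 0 in every sample) before log2"
        )
    return ExpressionMatrix(values=np.log2(em.values), scale="log2rpkm")
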