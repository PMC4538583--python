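"""TSV readers/writers for the pipeline's flat-file interfaces.

All tables are plain tab-separated text: a counts matrix (gene_id rows x
sample columns), a sample sheet (sample_id, cell_line, pd, replicate), a gene
lengths table (gene_id, length_bp) and, optionally, ground-truth labels from
the simulator.  The same schemas accept real data.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .normalize import CountMatrix, ExpressionMatrix, SchemaError


def read_counts_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"counts file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise SchemaError(f"{path}: no sample columns")
    return df


def read_samples_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample sheet not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("cell_line", "pd", "replicate"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return df


def read_lengths_tsv(path) -> pd.Series:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene lengths file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length_bp" not in df.columns:
        raise SchemaError(f"{path}: missing column 'length_bp'")
    return df["length_bp"]


def read_count_matrix(counts_tsv, samples_tsv, lengths_tsv) -> CountMatrix:
    return CountMatrix(
        counts=read_counts_tsv(counts_tsv),
        sample_meta=read_samples_tsv(samples_tsv),
        gene_lengths=read_lengths_tsv(lengths_tsv),
    )


def write_count_matrix(cm: CountMatrix, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "lengths": outdir / "lengths.tsv",
    }
    cm.counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    cm.sample_meta.rename_axis("sample_id").to_csv(paths["samples"], sep="\t")
    cm.gene_lengths.rename("length_bp").rename_axis("gene_id").to_csv(
        paths["lengths"], sep="\t"
    )
    return {k: str(v) for k, v in paths.items()}


def write_expression_tsv(em: ExpressionMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    em.values.rename_axis("gene_id").to_csv(path, sep="\t")


def read_expression_tsv(path, scale: str) -> ExpressionMatrix:
    return ExpressionMatrix(values=pd.read_csv(path, sep="\t", index_col=0), scale=scale)
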