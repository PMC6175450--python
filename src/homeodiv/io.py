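"""Tabular and sequence I/O for the pipeline's plain-text formats.

Formats
-------
expression TSV : columns ``gene_id, tissue, day, fpkm, fpkm_sd`` (long form,
    one row per gene/tissue/timepoint), emulating a summarised Cufflinks
    tracking table.
gene-map TSV   : one row per polyploid gene with its best reference
    (Arabidopsis) hit and set-membership flags.
hit-table TSV  : tab-separated BLAST-like table.  The native format has
    columns ``query, subject, pident, bitscore, evalue``; full 12-column
    tabular BLAST (outfmt 6) files are accepted and the needed columns
    extracted.
pairs TSV      : two columns, one homologous pair per row.
FASTA          : via Bio.SeqIO.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

EXPRESSION_COLUMNS = ["gene_id", "tissue", "day", "fpkm", "fpkm_sd"]
GENEMAP_COLUMNS = [
    "polyploid_gene_id",
    "reference_gene_id",
    "score",
    "evalue",
    "in_flowering_set",
    "in_tf_set",
    "in_circadian_set",
    "syntenic",
]
HIT_COLUMNS = ["query", "subject", "pident", "bitscore", "evalue"]
OUTFMT6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    return df[EXPRESSION_COLUMNS]


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def expression_matrix(
    df: pd.DataFrame, tissue: str
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Pivot one tissue's long table to (gene_ids, fpkm, fpkm_sd, days).

    Rows of the returned matrices follow the sorted gene-id order; columns
    follow increasing day.
    """
    sub = df[df["tissue"] == tissue]
    if sub.empty:
        raise ValueError(f"no rows for tissue {tissue!r}")
    fpkm = sub.pivot_table(index="gene_id", columns="day", values="fpkm", sort=True)
    sd = sub.pivot_table(index="gene_id", columns="day", values="fpkm_sd", sort=True)
    if fpkm.isna().any().any():
        raise ValueError("ragged expression table: missing gene/day combinations")
    genes = [str(g) for g in fpkm.index]
    days = fpkm.columns.to_numpy(dtype=float)
    return genes, fpkm.to_numpy(dtype=float), sd.reindex(fpkm.index).to_numpy(dtype=float), days


def read_genemap(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENEMAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene map missing columns: {sorted(missing)}")
    for col in GENEMAP_COLUMNS[4:]:
        df[col] = df[col].astype(bool)
    return df[GENEMAP_COLUMNS]


def write_genemap(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a hit table, tolerating full 12-column tabular BLAST output."""
    df = pd.read_csv(path, sep="\t")
    if set(HIT_COLUMNS) <= set(df.columns):
        return df[HIT_COLUMNS]
    # headerless outfmt 6
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] == len(OUTFMT6_COLUMNS):
        df.columns = OUTFMT6_COLUMNS
        return df[HIT_COLUMNS]
    raise ValueError(
        f"unrecognised hit table format with {df.shape[1]} columns: {path}"
    )


def write_hit_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("pairs table needs two id columns")
    return df


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
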