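"""Readers and writers for the plain-text genomic formats the pipeline consumes.

All writers are byte-deterministic for a fixed input: column order, float
formatting (shortest round-trip repr via pandas defaults) and line endings
are fixed, so identical in-memory objects always serialise identically.
Coordinates are 0-based half-open throughout, matching BED/bedGraph.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .errors import ParseError

_FASTA_WIDTH = 60

ANNOTATION_COLUMNS = ["gene_id", "chrom", "tss_0based", "strand"]
BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
BEDGRAPH_COLUMNS = ["chrom", "start", "end", "value"]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file into a dict of chromosome -> uppercase sequence."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate FASTA record {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED6 (or BED4+) file into chrom/start/end/name[/score/strand]."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(
            {"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=int),
             "end": pd.Series(dtype=int), "name": pd.Series(dtype=str)}
        )
    if df.shape[1] < 4:
        raise ParseError(f"{path}: expected >=4 BED columns, got {df.shape[1]}")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["name"] = df["name"].astype(str)
    return df


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    out = df.copy()
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    out[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] != 4:
        raise ParseError(f"{path}: bedGraph needs 4 columns, got {df.shape[1]}")
    df.columns = BEDGRAPH_COLUMNS
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["value"] = df["value"].astype(float)
    return df


def write_bedgraph(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[BEDGRAPH_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Read the 4-column TSS annotation (gene_id, chrom, tss_0based, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation columns {missing}")
    df = df[ANNOTATION_COLUMNS].copy()
    df["tss_0based"] = df["tss_0based"].astype(int)
    return df


def write_annotation(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)
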