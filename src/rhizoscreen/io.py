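"""Readers and writers for the pipeline's on-disk formats.

Formats: protein FASTA (single-line records), tab-separated tables with a
header line (UTF-8, '.' decimal, floats printed with %.6g), and Newick for
trees. The FASTA reader is strict: duplicate ids, empty files and
non-alphabetic residues are reported with the offending line number.
"""
from __future__ import annotations

import os

import pandas as pd

from .errors import DataError, ParseError
from .proteome import GroupAssignment, ProteinRecord, Proteome

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list:
    """Read protein records in file order.

    The record id is the first whitespace-delimited header token; the rest of
    the header is the description. Wrapped sequence lines are joined and
    uppercased.
    """
    records: list = []
    seen: dict = {}
    header: tuple | None = None  # (id, description, line_no)
    chunks: list = []

    def flush():
        if header is None:
            return
        rid, desc, line_no = header
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"record {rid!r} has no sequence", path, line_no)
        records.append(ProteinRecord(rid, seq, desc))

    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise ParseError("header line with no id", path, line_no)
                rid = parts[0]
                if rid in seen:
                    raise ParseError(
                        f"duplicate record id {rid!r} (first seen at line {seen[rid]})",
                        path, line_no,
                    )
                seen[rid] = line_no
                header = (rid, parts[1] if len(parts) > 1 else "", line_no)
                chunks = []
            else:
                if header is None:
                    raise ParseError("sequence data before first header", path, line_no)
                if not line.isalpha():
                    bad = next(ch for ch in line if not ch.isalpha())
                    raise ParseError(f"non-alphabetic residue {bad!r}", path, line_no)
                chunks.append(line.upper())
    flush()
    if not records:
        raise ParseError("empty FASTA file", path)
    return records


def write_fasta(records, path) -> None:
    """Write records (a Proteome or an iterable of ProteinRecord), one
    sequence line per record."""
    if isinstance(records, Proteome):
        records = records.records
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n{rec.seq}\n")


def read_proteome(path, strain: str | None = None) -> Proteome:
    """Read a per-strain FASTA file as a Proteome (strain = file stem)."""
    if strain is None:
        strain = os.path.splitext(os.path.basename(path))[0]
    return Proteome(strain, read_fasta(path))


# ---------------------------------------------------------------------------
# Tables


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except Exception as exc:
        raise ParseError(f"could not read TSV: {exc}", path) from exc


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns {missing}", path)


def read_groups(path) -> GroupAssignment:
    """Read a strain→group TSV (columns: strain, group) into a validated
    GroupAssignment; labels are case-insensitive."""
    df = read_tsv(path, dtype=str)
    _require_columns(df, ["strain", "group"], path)
    if df["strain"].duplicated().any():
        dup = df["strain"][df["strain"].duplicated()].iloc[0]
        raise ParseError(f"duplicate strain {dup!r} in groups table", path)
    return GroupAssignment(dict(zip(df["strain"], df["group"])))


def read_gene_order(path) -> pd.DataFrame:
    """Read the per-strain gene order table (strain, scaffold, index, gene_id)."""
    df = read_tsv(path, dtype={"strain": str, "scaffold": str, "gene_id": str})
    _require_columns(df, ["strain", "scaffold", "index", "gene_id"], path)
    df["index"] = df["index"].astype(int)
    dup = df.duplicated(subset=["strain", "scaffold", "index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ParseError(
            f"duplicate gene index {row['index']} on {row['strain']}/{row['scaffold']}", path
        )
    return df


def read_genome_summary(path) -> pd.DataFrame:
    """Read a genome summary table (strain, group, size_mb, gc_pct, cds)."""
    df = read_tsv(path)
    _require_columns(df, ["strain", "group", "size_mb", "gc_pct", "cds"], path)
    if df["strain"].duplicated().any():
        raise ParseError("duplicate strain ids in genome summary", path)
    if (df["size_mb"] <= 0).any():
        raise DataError("genome sizes must be positive")
    if ((df["gc_pct"] <= 0) | (df["gc_pct"] >= 100)).any():
        raise DataError("GC mol% must lie in (0, 100)")
    if (df["cds"] < 1).any():
        raise DataError("CDS counts must be >= 1")
    return df


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    """Write a labelled matrix (index kept, e.g. the bit-score matrix)."""
    df.to_csv(path, sep="\t", index=True, float_format=FLOAT_FORMAT)


def read_matrix_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"could not read matrix TSV: {exc}", path) from exc
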