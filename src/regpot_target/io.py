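"""Shared genomic coordinate types and readers/writers for the standard formats.

All coordinates are 0-based half-open (BED convention) throughout the
package; any 1-based display is presentation-layer only. Chromosome names
are matched by exact string equality everywhere — no "chr" normalization —
so that mismatched inputs surface as validation warnings rather than being
silently aliased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "TSSRecord",
    "DERecord",
    "SequencePair",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_tss_table",
    "write_tss_table",
    "read_de_table",
    "write_de_table",
    "read_fasta",
    "write_fasta",
]

GAP = "-"
_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open span ``[start, end)`` on a chromosome.

    The unit of ChIP-seq peaks, motif hits and conserved regions.
    ``start`` is 0-based inclusive, ``end`` 0-based exclusive.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None  # "+", "-" or None (unspecified)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TSSRecord:
    """One gene's transcription start site; the anchor for all distances.

    For minus-strand genes the annotated position is taken as given — the
    annotation supplier is responsible for strand-correct TSS.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"strand must be '+' or '-', got {self.strand!r} for {self.gene_id}"
            )


@dataclass(frozen=True)
class DERecord:
    """One gene's knockout-vs-control differential-expression summary.

    ``pvalue`` may be NaN (missing); such rows are retained but can never
    pass the threshold filter.
    """

    gene_id: str
    log2fc: float
    pvalue: float
    base_mean: float

    def __post_init__(self) -> None:
        if not math.isnan(self.pvalue) and not (0.0 < self.pvalue <= 1.0):
            raise ValueError(
                f"pvalue {self.pvalue} outside (0, 1] for {self.gene_id}"
            )
        if self.base_mean < 0:
            raise ValueError(f"negative base_mean for {self.gene_id}")

    @property
    def filterable(self) -> bool:
        return not math.isnan(self.pvalue)


@dataclass
class SequencePair:
    """Two homologous nucleotide sequences, optionally with a pairwise alignment.

    ``reference_seq`` plays the "mouse" role (coordinates of reported
    conserved regions), ``query_seq`` the "human" role. ``alignment`` is a
    pair of equal-length gapped rows; ungapping each row must reproduce the
    corresponding sequence.
    """

    reference_seq: str
    query_seq: str
    alignment: Optional[tuple[str, str]] = None
    reference_name: str = "reference"
    query_name: str = "query"

    def __post_init__(self) -> None:
        self.reference_seq = self.reference_seq.upper()
        self.query_seq = self.query_seq.upper()
        for label, seq in (("reference", self.reference_seq), ("query", self.query_seq)):
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(f"{label} sequence contains non-ACGTN symbols: {sorted(bad)}")
        if self.alignment is not None:
            ref_row, qry_row = (row.upper() for row in self.alignment)
            if len(ref_row) != len(qry_row):
                raise ValueError("alignment rows differ in length")
            if ref_row.replace(GAP, "") != self.reference_seq:
                raise ValueError("ungapped reference row does not match reference_seq")
            if qry_row.replace(GAP, "") != self.query_seq:
                raise ValueError("ungapped query row does not match query_seq")
            self.alignment = (ref_row, qry_row)


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into intervals, preserving input order.

    Raises :class:`ParseError` naming the offending line for non-integer
    coordinates or ``start >= end``.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else None
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED; round-trips coordinate-exactly through read_bed."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append(repr(iv.score) if iv.score is not None else ".")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# TSS and DE tables (TSV with header)

def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read a TSS annotation table (columns gene_id, chrom, tss, strand).

    One row per gene; duplicate gene ids are an error because every
    downstream distance computation assumes a unique TSS per gene.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    dups = df["gene_id"][df["gene_id"].duplicated()]
    if not dups.empty:
        raise ParseError(f"{path}: duplicate gene_id {dups.iloc[0]!r}")
    records = []
    for row in df.itertuples(index=False):
        try:
            records.append(TSSRecord(row.gene_id, row.chrom, int(row.tss), str(row.strand)))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return records


def write_tss_table(records: Iterable[TSSRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.chrom, r.tss, r.strand) for r in records],
        columns=["gene_id", "chrom", "tss", "strand"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> list[DERecord]:
    """Read a differential-expression table (gene_id, log2fc, pvalue, base_mean).

    Rows with a missing p value are retained (they are simply unfilterable);
    a p value outside (0, 1] is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "log2fc", "pvalue", "base_mean"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        pv = float(row.pvalue) if not pd.isna(row.pvalue) else math.nan
        try:
            records.append(DERecord(row.gene_id, float(row.log2fc), pv, float(row.base_mean)))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return records


def write_de_table(records: Iterable[DERecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.log2fc, r.pvalue, r.base_mean) for r in records],
        columns=["gene_id", "log2fc", "pvalue", "base_mean"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into a name -> uppercase-sequence mapping.

    Names are taken up to the first whitespace; an empty file or a duplicate
    name is an error.
    """
    mapping: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in mapping:
            raise ParseError(f"{path}: duplicate sequence name {record.id!r}")
        mapping[record.id] = str(record.seq).upper()
    if not mapping:
        raise ParseError(f"{path}: no FASTA records found")
    return mapping


def write_fasta(mapping: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in mapping.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
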