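"""Genome-wide scan for a degenerate IUPAC consensus motif.

The AP-1 family consensus used throughout is ``RATGASTCAT`` (R = A/G,
S = C/G). Matching is exact set membership per position — no position
weight matrix, no score threshold — which mirrors consensus-string motif
scanners. An ``N`` in the genome matches nothing, so assembly gaps never
generate hits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .io import GenomicInterval

__all__ = [
    "IUPAC_SETS",
    "MotifConsensus",
    "MotifHit",
    "iupac_match",
    "reverse_complement",
    "scan_sequence",
    "scan_genome",
    "dedupe_hit_intervals",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifConsensus:
    """A degenerate consensus pattern over IUPAC nucleotide codes."""

    pattern: str
    name: str = "motif"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        bad = set(self.pattern) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"invalid IUPAC codes in pattern: {sorted(bad)}")
        if len(self.pattern) < 4:
            raise ValueError("consensus pattern must be at least 4 bases")

    def __len__(self) -> int:
        return len(self.pattern)

    def reverse_complement(self) -> str:
        return reverse_complement(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in forward genomic coordinates.

    ``matched_seq`` is the genomic substring read on the hit strand, so it
    always matches the consensus under IUPAC expansion.
    """

    interval: GenomicInterval
    strand: str
    matched_seq: str


def iupac_match(code: str, base: str) -> bool:
    """True iff concrete ``base`` is in IUPAC ``code``'s expansion set."""
    try:
        allowed = IUPAC_SETS[code.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {code!r}") from None
    if base.upper() not in "ACGT":
        raise ValueError(f"base must be one of A,C,G,T, got {base!r}")
    return base.upper() in allowed


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _allowed_lookup(pattern: str) -> np.ndarray:
    """(len(pattern), 256) boolean table: row j allows byte b at position j.

    Genome ``N`` (or any byte outside ACGT) is allowed nowhere, including at
    pattern position N.
    """
    table = np.zeros((len(pattern), 256), dtype=bool)
    for j, code in enumerate(pattern):
        for base in IUPAC_SETS[code]:
            table[j, ord(base)] = True
    return table


def _scan_one_strand(encoded: np.ndarray, pattern: str) -> np.ndarray:
    """Start offsets where ``pattern`` matches the byte-encoded sequence."""
    L, m = encoded.size, len(pattern)
    if L < m:
        return np.empty(0, dtype=np.intp)
    table = _allowed_lookup(pattern)
    ok = table[0][encoded[: L - m + 1]]
    for j in range(1, m):
        ok &= table[j][encoded[j : L - m + 1 + j]]
    return np.flatnonzero(ok)


def scan_sequence(
    seq: str,
    motif: MotifConsensus,
    both_strands: bool = True,
    chrom: str = "",
) -> list[MotifHit]:
    """Test every window of ``len(motif)`` at every offset of ``seq``.

    Minus-strand hits are found by scanning the forward sequence with the
    reverse-complement consensus; they are reported in forward coordinates
    with ``strand="-"`` and ``matched_seq`` read 5'->3' on the minus strand.
    Hits are sorted by start, then strand (+ before -). A sequence shorter
    than the motif yields an empty list.
    """
    seq = seq.upper()
    m = len(motif)
    encoded = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    hits: list[MotifHit] = []
    for start in _scan_one_strand(encoded, motif.pattern):
        s = int(start)
        hits.append(
            MotifHit(
                GenomicInterval(chrom, s, s + m, name=motif.name, strand="+"),
                "+",
                seq[s : s + m],
            )
        )
    if both_strands:
        for start in _scan_one_strand(encoded, motif.reverse_complement()):
            s = int(start)
            hits.append(
                MotifHit(
                    GenomicInterval(chrom, s, s + m, name=motif.name, strand="-"),
                    "-",
                    reverse_complement(seq[s : s + m]),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def scan_genome(
    genome: Mapping[str, str], motif: MotifConsensus, both_strands: bool = True
) -> list[MotifHit]:
    """Scan every chromosome; results concatenated in lexicographic chromosome order."""
    hits: list[MotifHit] = []
    for chrom in sorted(genome):
        hits.extend(scan_sequence(genome[chrom], motif, both_strands=both_strands, chrom=chrom))
    return hits


def dedupe_hit_intervals(hits: Iterable[MotifHit]) -> list[GenomicInterval]:
    """Collapse hits sharing identical coordinates (e.g. both strands) to one interval.

    Regulatory-potential scoring counts genomic elements, not strands, so a
    palindromic-overlap double report must contribute once.
    """
    seen: set[tuple[str, int, int]] = set()
    out: list[GenomicInterval] = []
    for h in hits:
        key = (h.interval.chrom, h.interval.start, h.interval.end)
        if key not in seen:
            seen.add(key)
            out.append(GenomicInterval(h.interval.chrom, h.interval.start, h.interval.end, name=h.interval.name))
    return out
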