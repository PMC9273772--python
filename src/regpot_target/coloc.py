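"""Reciprocal-overlap colocalization of multiple factors' peak sets.

Two intervals overlap *reciprocally* at fraction f when their intersection
covers at least f of BOTH intervals (boundary inclusive). A reference-set
peak is *colocalized* when every other set contains at least one peak
passing the reciprocal test against it — the rule used to call composite
binding sites shared by a factor trio (e.g. an AP-1 dimer with IRF4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .io import GenomicInterval, TSSRecord
from .rp import anchor_point
from .targets import TargetCall

__all__ = [
    "OverlapPair",
    "ColocGroup",
    "reciprocal_overlap",
    "colocalized_peaks",
    "fraction_of_genes_with_colocalized_peak",
]


@dataclass(frozen=True)
class OverlapPair:
    """A passing reciprocal overlap between two intervals."""

    interval_a: GenomicInterval
    interval_b: GenomicInterval
    overlap_bp: int
    frac_a: float
    frac_b: float


@dataclass(frozen=True)
class ColocGroup:
    """A colocalized reference peak with one witness peak per other set."""

    reference: GenomicInterval
    witnesses: tuple[GenomicInterval, ...]


def reciprocal_overlap(
    a: GenomicInterval, b: GenomicInterval, min_frac: float = 0.5
) -> Optional[OverlapPair]:
    """The overlap pair iff the intersection covers >= min_frac of both intervals.

    Zero-length intersections (abutting intervals) are not overlaps.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    if a.chrom != b.chrom:
        return None
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return None
    frac_a = ov / len(a)
    frac_b = ov / len(b)
    if frac_a >= min_frac and frac_b >= min_frac:
        return OverlapPair(a, b, ov, frac_a, frac_b)
    return None


def _build_trees(peaks: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    return trees


def colocalized_peaks(
    sets: Sequence[Sequence[GenomicInterval]], min_frac: float = 0.5
) -> list[ColocGroup]:
    """Reference peaks (first set) with a reciprocal-overlap witness in every other set.

    For each other set the witness recorded is the first passing peak in
    coordinate order, so the result is deterministic and the group count
    counts reference peaks, not combinatorial matches. Groups are returned
    in reference coordinate order.
    """
    if len(sets) < 2:
        raise ValueError("colocalization requires at least 2 peak sets")
    other_trees = [_build_trees(s) for s in sets[1:]]
    groups: list[ColocGroup] = []
    for ref in sorted(sets[0], key=lambda p: (p.chrom, p.start, p.end)):
        witnesses: list[GenomicInterval] = []
        for trees in other_trees:
            tree = trees.get(ref.chrom)
            if tree is None:
                break
            passing = [
                iv.data
                for iv in tree.overlap(ref.start, ref.end)
                if reciprocal_overlap(ref, iv.data, min_frac) is not None
            ]
            if not passing:
                break
            passing.sort(key=lambda p: (p.start, p.end, p.name or ""))
            witnesses.append(passing[0])
        else:
            groups.append(ColocGroup(ref, tuple(witnesses)))
    return groups


def fraction_of_genes_with_colocalized_peak(
    calls: Sequence[TargetCall],
    genes: Sequence[TSSRecord],
    groups: Sequence[ColocGroup],
    window_kb: float = 100.0,
) -> Optional[float]:
    """Fraction of direct-target genes with a colocalized peak near their TSS.

    A direct target counts when at least one group's reference-peak midpoint
    lies within window_kb of its TSS. Returns None when there are no direct
    targets.
    """
    direct = {c.gene_id for c in calls if c.is_direct}
    if not direct:
        return None
    window_bp = window_kb * 1000.0
    anchors_by_chrom: dict[str, list[int]] = {}
    for g in groups:
        anchors_by_chrom.setdefault(g.reference.chrom, []).append(anchor_point(g.reference))
    n_with = 0
    for gene in genes:
        if gene.gene_id not in direct:
            continue
        anchors = anchors_by_chrom.get(gene.chrom, [])
        if any(abs(a - gene.tss) <= window_bp for a in anchors):
            n_with += 1
    return n_with / len(direct)
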