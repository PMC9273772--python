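"""Evolutionarily conserved region (ECR) detection by sliding-window identity.

Two homologous sequences are compared through a pairwise alignment; a
fixed-length window (default 200 bp of the *reference* sequence) qualifies
when at least ``min_identity`` (default 75%) of its reference positions are
aligned to an identical base in the query. Overlapping or abutting
qualifying windows are merged into maximal ECRs, numbered ECR1..ECRn in
coordinate order. Gap columns and N count as mismatches, a conservative
choice for assembly gaps and indels.

Identity here is alignment-column identity over the reference window —
the standard desk-scale reading of "percent similarity" between aligned
homologous loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .coloc import ColocGroup
from .io import GAP, GenomicInterval, SequencePair

__all__ = [
    "ECRConfig",
    "ECR",
    "window_identity",
    "find_ecrs",
    "align_pair",
    "intersect_ecrs_with_peaks",
    "read_sequence_pair",
    "write_sequence_pair",
]

MAX_ALIGN_LEN = 200_000


@dataclass(frozen=True)
class ECRConfig:
    """Window length, identity cutoff and TSS flank for ECR search."""

    window_bp: int = 200
    min_identity: float = 0.75
    flank_kb: float = 50.0

    def __post_init__(self) -> None:
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class ECR:
    """A maximal run of qualifying windows, in reference coordinates.

    ``identity`` is the best single-window identity inside the region;
    ``n_windows`` the number of qualifying windows merged.
    """

    interval: GenomicInterval
    identity: float
    n_windows: int


def _reference_match_profile(pair: SequencePair) -> np.ndarray:
    """Per-reference-position indicator: 1 where the alignment column carries
    identical non-gap, non-N bases in both rows.

    Query-insertion columns (reference gap) sit between reference positions
    and can never match, so dropping them loses nothing.
    """
    if pair.alignment is None:
        raise ValueError("pair has no alignment; call align_pair first")
    ref_row, qry_row = pair.alignment
    ref_len = len(pair.reference_seq)
    profile = np.zeros(ref_len, dtype=np.int64)
    i = 0
    for rc, qc in zip(ref_row, qry_row):
        if rc == GAP:
            continue
        if qc != GAP and rc == qc and rc != "N":
            profile[i] = 1
        i += 1
    return profile


def window_identity(pair: SequencePair, ref_start: int, window_bp: int) -> float:
    """Identity of one window: matching columns / window_bp.

    ``ref_start`` is an ungapped reference coordinate; the window must lie
    within the reference sequence.
    """
    if ref_start < 0 or ref_start + window_bp > len(pair.reference_seq):
        raise ValueError(
            f"window [{ref_start}, {ref_start + window_bp}) extends outside "
            f"reference of length {len(pair.reference_seq)}"
        )
    profile = _reference_match_profile(pair)
    return int(profile[ref_start : ref_start + window_bp].sum()) / window_bp


def find_ecrs(
    pair: SequencePair,
    config: ECRConfig = ECRConfig(),
    tss: Optional[int] = None,
    chrom: str = "reference",
) -> list[ECR]:
    """Slide the window by 1 bp over the reference and merge qualifying windows.

    When ``tss`` is given the search is restricted to
    [tss - flank_kb*1000, tss + flank_kb*1000), clipped to the sequence. A
    reference shorter than the window yields an empty list. ECRs are named
    ECR1..ECRn in coordinate order; each carries its best window identity.
    """
    if pair.alignment is None:
        pair = align_pair(pair)
    L = len(pair.reference_seq)
    w = config.window_bp
    lo, hi = 0, L
    if tss is not None:
        flank = int(config.flank_kb * 1000)
        lo, hi = max(0, tss - flank), min(L, tss + flank)
    if hi - lo < w:
        return []
    profile = _reference_match_profile(pair)
    # windowed match counts via cumulative sum; starts in [lo, hi - w]
    csum = np.concatenate(([0], np.cumsum(profile)))
    starts = np.arange(lo, hi - w + 1)
    counts = csum[starts + w] - csum[starts]
    # integer threshold: need counts/w >= min_identity (0.75*200 = 150 exact)
    threshold = math.ceil(config.min_identity * w - 1e-9)
    qualifying = starts[counts >= threshold]
    if qualifying.size == 0:
        return []
    q_counts = counts[counts >= threshold]

    ecrs: list[ECR] = []
    run_start = 0
    for i in range(1, qualifying.size + 1):
        # windows overlap or abut while consecutive starts are <= w apart
        if i == qualifying.size or qualifying[i] - qualifying[i - 1] > w:
            s = int(qualifying[run_start])
            e = int(qualifying[i - 1]) + w
            best = int(q_counts[run_start:i].max()) / w
            ecrs.append(
                ECR(
                    GenomicInterval(chrom, s, e, name=f"ECR{len(ecrs) + 1}"),
                    best,
                    i - run_start,
                )
            )
            run_start = i
    return ecrs


def align_pair(
    pair: SequencePair,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> SequencePair:
    """Global pairwise alignment of the two sequences (desk-scale).

    Affine-gap Needleman-Wunsch via Biopython's PairwiseAligner; the first
    optimal alignment is taken, which makes tie-breaking deterministic.
    Sequences longer than 200 kb are refused — supply a precomputed
    alignment for genome-scale input.
    """
    if not pair.reference_seq or not pair.query_seq:
        raise ValueError("cannot align an empty sequence")
    if len(pair.reference_seq) > MAX_ALIGN_LEN or len(pair.query_seq) > MAX_ALIGN_LEN:
        raise ValueError(
            f"sequences exceed {MAX_ALIGN_LEN} bp; supply a precomputed alignment"
        )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    alignment = aligner.align(pair.reference_seq, pair.query_seq)[0]
    ref_row, qry_row = str(alignment[0]), str(alignment[1])
    return SequencePair(
        pair.reference_seq,
        pair.query_seq,
        alignment=(ref_row, qry_row),
        reference_name=pair.reference_name,
        query_name=pair.query_name,
    )


def read_sequence_pair(path: str | Path, aligned: bool = False) -> SequencePair:
    """Read a 2-record FASTA as a sequence pair (first record = reference).

    With ``aligned=True`` the records are treated as gapped alignment rows;
    the underlying sequences are their ungapped forms.
    """
    from .io import read_fasta

    mapping = read_fasta(path)
    if len(mapping) != 2:
        raise ValueError(f"{path}: expected exactly 2 FASTA records, got {len(mapping)}")
    (ref_name, ref_row), (qry_name, qry_row) = mapping.items()
    if aligned:
        return SequencePair(
            ref_row.replace(GAP, ""),
            qry_row.replace(GAP, ""),
            alignment=(ref_row, qry_row),
            reference_name=ref_name,
            query_name=qry_name,
        )
    return SequencePair(ref_row, qry_row, reference_name=ref_name, query_name=qry_name)


def write_sequence_pair(pair: SequencePair, path: str | Path) -> None:
    """Write the pair as 2-record FASTA; gapped rows when an alignment is attached."""
    from .io import write_fasta

    if pair.alignment is not None:
        rows = {pair.reference_name: pair.alignment[0], pair.query_name: pair.alignment[1]}
    else:
        rows = {pair.reference_name: pair.reference_seq, pair.query_name: pair.query_seq}
    write_fasta(rows, path)


def intersect_ecrs_with_peaks(
    ecrs: Sequence[ECR],
    groups: Sequence[ColocGroup],
    proximity_bp: int = 1000,
) -> list[tuple[ECR, ColocGroup]]:
    """Pair each ECR with colocalization groups whose reference peak is near it.

    Distance 0 means overlap; a pair is reported when the gap between the
    group's reference peak and the ECR interval is <= proximity_bp. Both
    coordinate sets must live in the same reference frame (chromosome names
    compared exactly).
    """
    pairs: list[tuple[ECR, ColocGroup]] = []
    for ecr in ecrs:
        for grp in groups:
            ref = grp.reference
            if ref.chrom != ecr.interval.chrom:
                continue
            gap = max(ecr.interval.start - ref.end, ref.start - ecr.interval.end, 0)
            if gap <= proximity_bp:
                pairs.append((ecr, grp))
    return pairs
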