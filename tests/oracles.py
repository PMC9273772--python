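"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal method available
(regex expansion, all-pairs loops, per-position window counting) without
touching the package's optimized code paths, so agreement is evidence the
implementation is right rather than self-consistent.
"""

from __future__ import annotations

import math
import re

# Independent IUPAC expansion table (do not import the package's).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMP.get(b, "N") for b in reversed(seq))


def regex_for(pattern: str) -> re.Pattern:
    return re.compile("(?=(" + "".join(f"[{IUPAC[c]}]" for c in pattern) + "))")


def regex_scan(seq: str, pattern: str) -> set[tuple[int, str]]:
    """Both-strand hit set {(start, strand)} by regex over the IUPAC expansion."""
    hits = {(m.start(), "+") for m in regex_for(pattern).finditer(seq)}
    rc = "".join(IUPAC_COMP[c] for c in reversed(pattern))
    hits |= {(m.start(), "-") for m in regex_for(rc).finditer(seq)}
    return hits


# complement of IUPAC codes for building the reverse-complement pattern
IUPAC_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}


def brute_rp(genes, intervals, window_bp=100_000.0, c0=0.5, c1=4.0):
    """All-pairs RP scores: {gene_id: rp} by direct looping."""
    out = {}
    for g in genes:
        deltas = []
        for iv in intervals:
            if iv.chrom != g.chrom:
                continue
            anchor = (iv.start + iv.end) // 2
            d = abs(anchor - g.tss)
            if d <= window_bp:
                deltas.append(d / window_bp)
        deltas.sort()
        total = 0.0
        for d in deltas:
            total += math.exp(-(c0 + c1 * d))
        out[g.gene_id] = total
    return out


def brute_reciprocal(a, b, min_frac):
    if a.chrom != b.chrom:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    return ov / (a.end - a.start) >= min_frac and ov / (b.end - b.start) >= min_frac


def brute_coloc(sets, min_frac):
    """Reference peaks colocalized with every other set, by all-pairs loops."""
    ref_hits = []
    for p in sets[0]:
        if all(any(brute_reciprocal(p, q, min_frac) for q in other) for other in sets[1:]):
            ref_hits.append((p.chrom, p.start, p.end))
    return sorted(ref_hits)


def brute_window_matches(ref_row: str, qry_row: str) -> list[int]:
    """Per-reference-position match indicators from gapped alignment rows."""
    out = []
    for rc, qc in zip(ref_row, qry_row):
        if rc == "-":
            continue
        out.append(1 if (qc != "-" and rc == qc and rc != "N") else 0)
    return out


def brute_ecrs(ref_row: str, qry_row: str, window: int, min_identity: float):
    """Merged conserved regions by per-position window counting.

    Returns a list of (start, end, best_identity) in reference coordinates.
    """
    matches = brute_window_matches(ref_row, qry_row)
    L = len(matches)
    if L < window:
        return []
    qual = []
    for s in range(L - window + 1):
        m = sum(matches[s : s + window])
        if m / window >= min_identity - 1e-12:
            qual.append((s, m / window))
    regions = []
    for s, ident in qual:
        if regions and s <= regions[-1][1]:
            prev = regions[-1]
            regions[-1] = (prev[0], max(prev[1], s + window), max(prev[2], ident))
        else:
            regions.append((s, s + window, ident))
    return regions
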