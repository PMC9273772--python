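"""Threshold-based DE filtering and BETA-style direct-target calling.

A gene is a *direct target* of the factor when it is differentially
expressed upon factor knockout (|log2FC| > 0.5, p < 0.05, base mean > 100,
all strict) AND has non-zero regulatory potential from the factor's binding
sites — the "non-zero score" criterion of binding-and-expression target
(BETA) analysis. The rank-product beta score (fractional RP rank times
fractional DE rank, both in (0,1], smaller = stronger) orders the calls but
does not gate them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .io import DERecord
from .rp import RPResult

__all__ = [
    "DEThresholds",
    "TargetCall",
    "classify_de",
    "fractional_rank",
    "call_targets",
    "summarize_direct_fraction",
]


@dataclass(frozen=True)
class DEThresholds:
    """Strict cutoffs applied to a precomputed DE table.

    Defaults follow the usual knockout screen convention:
    |log2FC| > 0.5, raw p < 0.05, base mean > 100. Raw p values drive the
    filter by default; set ``use_padj`` when the table's pvalue column
    carries adjusted p values instead.
    """

    lfc_cut: float = 0.5
    p_cut: float = 0.05
    base_mean_cut: float = 100.0
    use_padj: bool = False

    def __post_init__(self) -> None:
        if self.lfc_cut <= 0 or self.p_cut <= 0 or self.base_mean_cut <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class TargetCall:
    """Per-gene verdict combining DE status and regulatory potential."""

    gene_id: str
    de_direction: str  # "up", "down" or "none"
    rp: float
    rp_rank: float
    de_rank: Optional[float]
    beta_score: Optional[float]
    is_direct: bool


def classify_de(record: DERecord, thresholds: DEThresholds = DEThresholds()) -> str:
    """Classify one gene as "up", "down" or "none" under strict cutoffs.

    All three comparisons are strict, so values exactly at a cutoff
    (log2fc = +-0.5, p = 0.05, base mean = 100) are excluded. A missing
    p value makes the gene unfilterable ("none").
    """
    if math.isnan(record.pvalue):
        return "none"
    if not (record.pvalue < thresholds.p_cut and record.base_mean > thresholds.base_mean_cut):
        return "none"
    if record.log2fc > thresholds.lfc_cut:
        return "up"
    if record.log2fc < -thresholds.lfc_cut:
        return "down"
    return "none"


def fractional_rank(values: Sequence[float], ascending: bool = True) -> list[float]:
    """Fractional ranks in (0, 1]: sorted position / n, ties share the mean.

    With ``ascending=True`` the smallest value gets the smallest rank.
    """
    if len(values) == 0:
        raise ValueError("cannot rank an empty list")
    arr = np.asarray(values, dtype=float)
    ranks = rankdata(arr if ascending else -arr, method="average")
    return list(ranks / len(arr))


def call_targets(
    rp_results: Sequence[RPResult],
    de_records: Sequence[DERecord],
    thresholds: DEThresholds = DEThresholds(),
) -> list[TargetCall]:
    """Join RP scores with DE records on gene_id and call direct targets.

    The gene universe is the union: genes in the DE table without an RP
    entry get rp = 0 (they can never be direct); genes with RP but no DE
    record get de_direction "none". RP ranks are computed over all genes by
    rp descending; DE ranks over threshold-passing genes by p value
    ascending. Output is sorted by beta score ascending (strongest calls
    first), non-direct genes after, then gene_id.
    """
    rp_by_gene = {r.gene_id: r.rp for r in rp_results}
    de_by_gene = {r.gene_id: r for r in de_records}
    if len(rp_by_gene) != len(rp_results):
        raise ValueError("duplicate gene_id in rp_results")
    if len(de_by_gene) != len(de_records):
        raise ValueError("duplicate gene_id in de_records")
    if not set(rp_by_gene) & set(de_by_gene):
        raise ValueError("gene universes of RP and DE inputs do not intersect")

    gene_ids = sorted(set(rp_by_gene) | set(de_by_gene))
    rp_vals = [rp_by_gene.get(g, 0.0) for g in gene_ids]
    rp_ranks = fractional_rank(rp_vals, ascending=False)

    directions = {
        g: classify_de(de_by_gene[g], thresholds) if g in de_by_gene else "none"
        for g in gene_ids
    }
    de_passing = [g for g in gene_ids if directions[g] != "none"]
    de_ranks: dict[str, float] = {}
    if de_passing:
        ranks = fractional_rank([de_by_gene[g].pvalue for g in de_passing], ascending=True)
        de_ranks = dict(zip(de_passing, ranks))

    calls = []
    for g, rp_val, rp_rank in zip(gene_ids, rp_vals, rp_ranks):
        direction = directions[g]
        is_direct = direction != "none" and rp_val > 0
        de_rank = de_ranks.get(g)
        beta = rp_rank * de_rank if is_direct else None
        calls.append(TargetCall(g, direction, rp_val, rp_rank, de_rank, beta, is_direct))
    calls.sort(key=lambda c: (c.beta_score is None, c.beta_score, c.gene_id))
    return calls


def summarize_direct_fraction(calls: Sequence[TargetCall]) -> Optional[float]:
    """Fraction of DE genes called direct; None when no gene passed the DE filter."""
    if not calls:
        raise ValueError("calls must be non-empty")
    n_de = sum(1 for c in calls if c.de_direction != "none")
    if n_de == 0:
        return None
    return sum(1 for c in calls if c.is_direct) / n_de
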