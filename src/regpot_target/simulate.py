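"""Synthetic study generator with recorded ground truth.

Emulates the statistical structure of a factor-knockout integration study:
a random genome with planted AP-1 consensus occurrences, three factors'
peak sets with a controllable colocalization fraction, a gene/TSS
annotation, a differential-expression table in which planted direct
targets carry both strong expression changes and non-zero regulatory
potential, and a two-species homologous sequence pair with planted
high-identity blocks. Every quantity downstream modules are meant to
recover is recorded in a :class:`SyntheticTruth`.

A single integer master seed drives everything: each generator derives an
independent stream as ``default_rng([seed, stream_index])`` with a fixed
stream index per component, so one seed reproduces the full dataset
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import (
    DERecord,
    GenomicInterval,
    SequencePair,
    TSSRecord,
    write_bed,
    write_de_table,
    write_fasta,
    write_tss_table,
)
from .motifs import IUPAC_SETS, MotifConsensus
from .rp import RPConfig, RPResult, rp_score_all
from .targets import DEThresholds, classify_de

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_genome",
    "generate_genes",
    "generate_peaks",
    "generate_de_table",
    "generate_sequence_pair",
    "generate_dataset",
]

AP1_MOTIF = MotifConsensus("RATGASTCAT", name="AP1")

_STREAMS = {"genome": 0, "genes": 1, "peaks": 2, "de": 3, "pair": 4}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic dataset.

    Defaults are sized so a laptop-scale run exercises every stage with
    informative structure: peak-to-TSS distances follow an 80/20 mixture
    (80% within +-20 kb of a gene TSS, 20% uniform within +-100 kb) so
    regulatory-potential scores spread over their range rather than
    degenerating; planted direct targets have mean |log2FC| 1.5 against the
    0.5 filter cutoff, with sd-0.3 noise and a 5% background false-DE layer
    as the default noise regime.
    """

    n_chroms: int = 4
    chrom_length_bp: int = 25_000_000
    n_genes: int = 1000
    n_peaks_per_factor: int = 2000
    bound_gene_fraction: float = 0.6
    coloc_fraction: float = 0.6
    n_direct_targets: int = 50
    de_effect_size: float = 1.5
    de_noise_sd: float = 0.3
    background_de_rate: float = 0.05
    n_motif_plants: int = 60
    pair_length_bp: int = 20_000
    n_conserved_blocks: int = 5
    core_frac: float = 0.8         # fraction of peaks in the +-core_kb mixture component
    core_kb: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coloc_fraction", "background_de_rate", "core_frac", "bound_gene_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_chroms", "chrom_length_bp", "n_genes", "n_peaks_per_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_direct_targets > self.n_genes:
            raise ValueError("n_direct_targets cannot exceed n_genes")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass
class SyntheticTruth:
    """Everything the generators planted, for comparison against recovery."""

    planted_motif_sites: list[GenomicInterval] = field(default_factory=list)
    planted_direct_targets: list[tuple[str, str]] = field(default_factory=list)
    colocalized_peak_triples: list[tuple[GenomicInterval, GenomicInterval, GenomicInterval]] = field(
        default_factory=list
    )
    planted_conserved_blocks: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        def iv(x: GenomicInterval) -> dict:
            return {"chrom": x.chrom, "start": x.start, "end": x.end}

        payload = {
            "seed": self.seed,
            "planted_motif_sites": [iv(x) for x in self.planted_motif_sites],
            "planted_direct_targets": [list(t) for t in self.planted_direct_targets],
            "colocalized_peak_triples": [
                [iv(a), iv(b), iv(c)] for a, b, c in self.colocalized_peak_triples
            ],
            "planted_conserved_blocks": [
                [iv(a), ident] for a, ident in self.planted_conserved_blocks
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)

        def iv(x: dict) -> GenomicInterval:
            return GenomicInterval(x["chrom"], x["start"], x["end"])

        return cls(
            planted_motif_sites=[iv(x) for x in d["planted_motif_sites"]],
            planted_direct_targets=[tuple(t) for t in d["planted_direct_targets"]],
            colocalized_peak_triples=[
                (iv(a), iv(b), iv(c)) for a, b, c in d["colocalized_peak_triples"]
            ],
            planted_conserved_blocks=[
                (iv(a), ident) for a, ident in d["planted_conserved_blocks"]
            ],
            seed=d["seed"],
        )


def _chrom_names(config: SimulationConfig) -> list[str]:
    width = max(2, len(str(config.n_chroms)))
    return [f"chr{i + 1:0{width}d}" for i in range(config.n_chroms)]


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def generate_genome(
    config: SimulationConfig, motif: MotifConsensus = AP1_MOTIF
) -> tuple[dict[str, str], list[GenomicInterval]]:
    """Uniform-random genome with planted, non-overlapping motif instances.

    Degenerate motif positions are sampled from their IUPAC expansion sets,
    so every planted instance matches the consensus. The plant list (forward
    strand) is the ground truth a genome scan must recover.
    """
    rng = config.rng("genome")
    names = _chrom_names(config)
    m = len(motif)
    capacity = config.n_chroms * (config.chrom_length_bp // (2 * m))
    if config.n_motif_plants > capacity:
        raise ValueError(
            f"cannot plant {config.n_motif_plants} motifs: capacity ~{capacity}"
        )
    arrays = {name: _random_seq(rng, config.chrom_length_bp) for name in names}
    plants: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    for i in range(config.n_motif_plants):
        chrom = names[i % config.n_chroms]
        while True:
            start = int(rng.integers(0, config.chrom_length_bp - m))
            if all(start + m <= s or start >= e for s, e in occupied[chrom]):
                break
        occupied[chrom].append((start, start + m))
        instance = "".join(
            sorted(IUPAC_SETS[code])[rng.integers(0, len(IUPAC_SETS[code]))]
            for code in motif.pattern
        )
        arrays[chrom][start : start + m] = np.frombuffer(instance.encode(), dtype=np.uint8)
        plants.append(GenomicInterval(chrom, start, start + m, name=f"plant{i}"))
    genome = {name: arrays[name].tobytes().decode("ascii") for name in names}
    plants.sort(key=lambda p: (p.chrom, p.start))
    return genome, plants


def generate_genes(config: SimulationConfig) -> list[TSSRecord]:
    """Gene annotation with TSS uniform per chromosome and unique gene ids."""
    rng = config.rng("genes")
    names = _chrom_names(config)
    genes: list[TSSRecord] = []
    for i in range(config.n_genes):
        chrom = names[i % config.n_chroms]
        tss = int(rng.integers(0, config.chrom_length_bp))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(TSSRecord(f"g{i:05d}", chrom, tss, strand))
    return genes


def _place_peak(
    rng: np.random.Generator, gene: TSSRecord, config: SimulationConfig, name: str
) -> GenomicInterval:
    if rng.random() < config.core_frac:
        half = config.core_kb * 1000
    else:
        half = 100_000
    offset = int(rng.integers(-int(half), int(half) + 1))
    width = int(rng.integers(200, 801))
    center = min(max(gene.tss + offset, width // 2 + 1), config.chrom_length_bp - width)
    start = center - width // 2
    return GenomicInterval(gene.chrom, start, start + width, name=name)


def generate_peaks(
    config: SimulationConfig, genes: Sequence[TSSRecord]
) -> tuple[
    list[GenomicInterval],
    list[GenomicInterval],
    list[GenomicInterval],
    list[tuple[GenomicInterval, GenomicInterval, GenomicInterval]],
]:
    """Three factors' peak sets with a planted colocalization fraction.

    Peaks are anchored only on a ``bound_gene_fraction`` subset of genes so
    that genes outside any bound neighborhood carry zero regulatory
    potential, as in a real factor's binding landscape. Reference-factor
    peaks are placed by the TSS-distance mixture; a ``coloc_fraction``
    subset gets witness peaks in the other two sets with the same width and
    a jitter of at most width/4, guaranteeing >=75% (hence >=50%)
    reciprocal overlap. Remaining peaks in factors 2 and 3 are placed
    independently (on the same bound-gene subset).
    """
    rng = config.rng("peaks")
    n_bound = max(1, int(round(config.bound_gene_fraction * len(genes))))
    bound_idx = rng.choice(len(genes), size=n_bound, replace=False)
    bound = [genes[int(i)] for i in np.sort(bound_idx)]
    ref: list[GenomicInterval] = []
    for i in range(config.n_peaks_per_factor):
        gene = bound[int(rng.integers(0, len(bound)))]
        ref.append(_place_peak(rng, gene, config, f"ref_pk{i}"))
    n_coloc = int(round(config.coloc_fraction * config.n_peaks_per_factor))
    coloc_idx = set(
        rng.choice(config.n_peaks_per_factor, size=n_coloc, replace=False).tolist()
    )
    set2: list[GenomicInterval] = []
    set3: list[GenomicInterval] = []
    triples = []
    for i, p in enumerate(ref):
        if i in coloc_idx:
            w = len(p)
            witnesses = []
            for label, out in (("f2", set2), ("f3", set3)):
                shift = int(rng.integers(-(w // 4), w // 4 + 1))
                start = max(0, p.start + shift)
                iv = GenomicInterval(p.chrom, start, start + w, name=f"{label}_{p.name}")
                out.append(iv)
                witnesses.append(iv)
            triples.append((p, witnesses[0], witnesses[1]))
    n_indep = config.n_peaks_per_factor - n_coloc
    for label, out in (("f2", set2), ("f3", set3)):
        for i in range(n_indep):
            gene = bound[int(rng.integers(0, len(bound)))]
            out.append(_place_peak(rng, gene, config, f"{label}_pk{i}"))
    return ref, set2, set3, triples


def generate_de_table(
    config: SimulationConfig,
    rp_results: Sequence[RPResult],
    thresholds: DEThresholds = DEThresholds(),
) -> tuple[list[DERecord], list[tuple[str, str]]]:
    """DE table with planted direct targets and a controlled false-DE layer.

    Planted targets are drawn from genes with rp > 0; their log2FC is
    ``+-(de_effect_size + N(0, de_noise_sd))`` with p ~ U(0, 0.01) and base
    mean ~ U(200, 2000), so they pass the filter unless noise pushes the
    fold change under the cutoff. A ``background_de_rate`` fraction of the
    remaining genes is forced past the thresholds irrespective of rp (the
    false-positive layer); every other background gene is drawn from the
    null and redrawn if it would pass the filter by chance, so the planted
    rate is exactly the false-DE rate.
    """
    rng = config.rng("de")
    eligible = [r.gene_id for r in rp_results if r.rp > 0]
    if len(eligible) < config.n_direct_targets:
        raise ValueError(
            f"only {len(eligible)} genes have rp > 0; "
            f"cannot plant {config.n_direct_targets} direct targets"
        )
    planted_ids = rng.choice(eligible, size=config.n_direct_targets, replace=False)
    planted: dict[str, str] = {}
    for gid in planted_ids:
        planted[str(gid)] = "up" if rng.random() < 0.5 else "down"
    background = [r.gene_id for r in rp_results if r.gene_id not in planted]
    n_false = int(round(config.background_de_rate * len(background)))
    forced = set(
        str(g) for g in rng.choice(background, size=n_false, replace=False)
    ) if n_false else set()

    records: list[DERecord] = []
    for r in rp_results:
        gid = r.gene_id
        if gid in planted:
            sign = 1.0 if planted[gid] == "up" else -1.0
            noise = rng.normal(0.0, config.de_noise_sd) if config.de_noise_sd > 0 else 0.0
            lfc = sign * (config.de_effect_size + noise)
            p = float(rng.uniform(1e-12, 0.01))
            bm = float(rng.uniform(200, 2000))
        elif gid in forced:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc = sign * float(rng.uniform(thresholds.lfc_cut + 0.1, 1.5))
            p = float(rng.uniform(1e-12, thresholds.p_cut * 0.98))
            bm = float(rng.uniform(thresholds.base_mean_cut * 1.5, 1500))
        else:
            while True:
                lfc = float(rng.normal(0.0, 0.2))
                p = float(rng.uniform(1e-12, 1.0))
                bm = float(rng.uniform(20, 500))
                if classify_de(DERecord(gid, lfc, p, bm), thresholds) == "none":
                    break
        records.append(DERecord(gid, float(lfc), p, bm))
    truth = sorted(planted.items())
    return records, truth


def generate_sequence_pair(
    config: SimulationConfig, window_bp: int = 200
) -> tuple[SequencePair, list[tuple[GenomicInterval, float]]]:
    """Homologous pair with planted conserved blocks in divergent background.

    The query is a copy of the reference with per-base substitution rate
    0.6 outside planted blocks (background identity ~40%, far below any
    usual cutoff) and rate (1 - identity) inside each block, identities
    drawn from {0.75, 0.80, ..., 1.0}. Blocks are at least ``window_bp``
    long and non-overlapping; the (gapless) alignment is attached.
    """
    rng = config.rng("pair")
    L = config.pair_length_bp
    n = config.n_conserved_blocks
    if n * (window_bp * 3) > L:
        raise ValueError("pair_length_bp too small for requested blocks")
    ref = _random_seq(rng, L)
    slot = L // max(n, 1)
    blocks: list[tuple[GenomicInterval, float]] = []
    rate = np.full(L, 0.6)
    identities = np.arange(0.75, 1.0001, 0.05)
    for b in range(n):
        length = int(rng.integers(window_bp, min(2 * window_bp, slot // 2) + 1))
        start = b * slot + int(rng.integers(0, slot - length))
        ident = float(identities[rng.integers(0, len(identities))])
        rate[start : start + length] = 1.0 - ident
        blocks.append((GenomicInterval("reference", start, start + length), round(ident, 2)))
    sub = rng.random(L) < rate
    shift = rng.integers(1, 4, size=int(sub.sum()))
    codes = np.searchsorted(_BASES, ref)  # ACGT are sorted bytes
    query_codes = codes.copy()
    query_codes[sub] = (codes[sub] + shift) % 4
    qry = _BASES[query_codes]
    ref_s = ref.tobytes().decode("ascii")
    qry_s = qry.tobytes().decode("ascii")
    pair = SequencePair(ref_s, qry_s, alignment=(ref_s, qry_s))
    return pair, blocks


def generate_dataset(
    config: SimulationConfig,
    outdir: str | Path,
    rp_config: RPConfig = RPConfig(),
    thresholds: DEThresholds = DEThresholds(),
) -> tuple[SyntheticTruth, dict[str, Path]]:
    """Generate and write the full synthetic bundle; returns truth and file paths.

    Writes genome.fa, junb.bed, batf.bed, irf4.bed, tss.tsv, de.tsv,
    pair.fa (aligned 2-record FASTA) and truth.json into ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, plants = generate_genome(config)
    genes = generate_genes(config)
    ref_peaks, peaks2, peaks3, triples = generate_peaks(config, genes)
    rp_results = rp_score_all(genes, ref_peaks, rp_config)
    de_records, planted_targets = generate_de_table(config, rp_results, thresholds)
    pair, blocks = generate_sequence_pair(config)

    paths = {
        "genome": outdir / "genome.fa",
        "junb": outdir / "junb.bed",
        "batf": outdir / "batf.bed",
        "irf4": outdir / "irf4.bed",
        "tss": outdir / "tss.tsv",
        "de": outdir / "de.tsv",
        "pair": outdir / "pair.fa",
        "truth": outdir / "truth.json",
    }
    write_fasta(genome, paths["genome"])
    write_bed(ref_peaks, paths["junb"])
    write_bed(peaks2, paths["batf"])
    write_bed(peaks3, paths["irf4"])
    write_tss_table(genes, paths["tss"])
    write_de_table(de_records, paths["de"])
    assert pair.alignment is not None
    write_fasta(
        {pair.reference_name: pair.alignment[0], pair.query_name: pair.alignment[1]},
        paths["pair"],
    )
    truth = SyntheticTruth(
        planted_motif_sites=plants,
        planted_direct_targets=planted_targets,
        colocalized_peak_triples=triples,
        planted_conserved_blocks=blocks,
        seed=config.seed,
    )
    truth.to_json(paths["truth"])
    return truth, paths
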