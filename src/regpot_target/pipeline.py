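"""End-to-end orchestration: scan -> RP -> target call -> colocalization -> ECR.

Every intermediate is persisted in its standard format (BED/TSV) so each
stage can be re-run and audited independently; the run report records the
package version, a hash of the semantic configuration, input checksums and
per-stage counts. Given identical inputs and configuration, all BED/TSV
outputs are byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .coloc import ColocGroup, colocalized_peaks, fraction_of_genes_with_colocalized_peak
from .ecr import ECRConfig, find_ecrs, intersect_ecrs_with_peaks, read_sequence_pair
from .io import (
    GenomicInterval,
    ParseError,
    read_bed,
    read_de_table,
    read_fasta,
    read_tss_table,
    write_bed,
)
from .motifs import MotifConsensus, dedupe_hit_intervals, scan_genome
from .rp import RPConfig, RPResult, dedupe_intervals, rp_score_all
from .simulate import SyntheticTruth
from .targets import DEThresholds, TargetCall, call_targets, summarize_direct_fraction

logger = logging.getLogger("regpot_target")

__all__ = ["PipelineConfig", "PipelineError", "ValidationReport", "validate_inputs", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


@dataclass
class PipelineConfig:
    """Inputs, outputs and parameters of one pipeline run."""

    peaks: list[str]                 # >=1 BED paths; first is the reference factor
    tss: str
    de: str
    outdir: str
    genome: Optional[str] = None     # enables the motif scan stage
    motif: str = "RATGASTCAT"
    pair: Optional[str] = None       # enables the ECR stage
    pair_aligned: bool = False
    ecr_tss: Optional[int] = None
    truth: Optional[str] = None      # synthetic truth.json for recall/precision
    rp: RPConfig = field(default_factory=RPConfig)
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    min_frac: float = 0.5
    ecr: ECRConfig = field(default_factory=ECRConfig)
    proximity_bp: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, sub in (("rp", RPConfig), ("thresholds", DEThresholds), ("ecr", ECRConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def semantic_dict(self) -> dict:
        """Fields that affect results (paths and log level excluded)."""
        return {
            "motif": self.motif,
            "pair_aligned": self.pair_aligned,
            "ecr_tss": self.ecr_tss,
            "rp": asdict(self.rp),
            "thresholds": asdict(self.thresholds),
            "min_frac": self.min_frac,
            "ecr": asdict(self.ecr),
            "proximity_bp": self.proximity_bp,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Check existence and format of every input before any stage executes.

    Chromosome-name mismatches across inputs are warnings (exact-string
    matching means such peaks simply never pair with any gene); malformed
    files are fatal.
    """
    report = ValidationReport()
    chrom_sets: dict[str, set[str]] = {}
    for label, path in [("peaks[reference]", config.peaks[0] if config.peaks else None)] + [
        (f"peaks[{i}]", p) for i, p in enumerate(config.peaks[1:], start=1)
    ]:
        if path is None:
            report.errors.append("no peak files configured")
            continue
        if not Path(path).exists():
            report.errors.append(f"{label}: file not found: {path}")
            continue
        try:
            ivs = read_bed(path)
            chrom_sets[label] = {iv.chrom for iv in ivs}
        except ParseError as exc:
            report.errors.append(f"{label}: {exc}")
    for label, path, reader in (
        ("tss", config.tss, read_tss_table),
        ("de", config.de, read_de_table),
    ):
        if not Path(path).exists():
            report.errors.append(f"{label}: file not found: {path}")
            continue
        try:
            records = reader(path)
            if label == "tss":
                chrom_sets["tss"] = {r.chrom for r in records}
        except ParseError as exc:
            report.errors.append(f"{label}: {exc}")
    if config.genome is not None:
        if not Path(config.genome).exists():
            report.errors.append(f"genome: file not found: {config.genome}")
        else:
            try:
                chrom_sets["genome"] = set(read_fasta(config.genome))
            except ParseError as exc:
                report.errors.append(f"genome: {exc}")
    if config.pair is not None and not Path(config.pair).exists():
        report.errors.append(f"pair: file not found: {config.pair}")
    try:
        MotifConsensus(config.motif)
    except ValueError as exc:
        report.errors.append(f"motif: {exc}")
    if "tss" in chrom_sets:
        for label, names in chrom_sets.items():
            if label == "tss":
                continue
            only_here = sorted(names - chrom_sets["tss"])
            only_tss = sorted(chrom_sets["tss"] - names)
            if only_here or only_tss:
                report.warnings.append(
                    f"chromosome names differ between {label} and tss: "
                    f"only in {label}: {only_here}; only in tss: {only_tss}"
                )
    return report


def _write_rp_tsv(results: Sequence[RPResult], path: Path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.k, repr(r.rp)) for r in results],
        columns=["gene_id", "k", "rp"],
    )
    df.to_csv(path, sep="\t", index=False)


def _write_targets_tsv(calls: Sequence[TargetCall], path: Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            (
                c.gene_id,
                c.de_direction,
                repr(c.rp),
                repr(c.rp_rank),
                repr(c.de_rank) if c.de_rank is not None else "NA",
                repr(c.beta_score) if c.beta_score is not None else "NA",
                int(c.is_direct),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "de_direction", "rp", "rp_rank", "de_rank", "beta_score", "is_direct"],
    )
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns (and writes) the run report.

    Stages: motif scan (if a genome is given), RP scoring of peaks and of
    deduplicated motif hits, target calling on the combined peak+motif
    site set, multi-factor colocalization (if >=2 peak sets), the
    direct-target colocalization fraction, and ECR detection plus ECR-peak
    proximity pairing (if a sequence pair is given). Any stage error aborts
    with the stage name.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    validation = validate_inputs(config)
    for w in validation.warnings:
        logger.warning("validation: %s", w)
    if not validation.ok:
        raise PipelineError("validation failed: " + "; ".join(validation.errors))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.semantic_dict(),
        "inputs": {},
        "stages": {},
        "warnings": validation.warnings,
    }
    for label, path in [(f"peaks[{i}]", p) for i, p in enumerate(config.peaks)] + [
        ("tss", config.tss),
        ("de", config.de),
    ] + ([("genome", config.genome)] if config.genome else []) + (
        [("pair", config.pair)] if config.pair else []
    ):
        report["inputs"][label] = {"path": str(path), "sha256": _sha256(path)}

    def stage(name: str):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    def done(name: str, t0: float, **counts) -> None:
        dt = time.perf_counter() - t0
        report["stages"][name] = {"seconds": round(dt, 3), **counts}
        logger.info("stage %s done in %.2fs: %s", name, dt, counts)

    try:
        t0 = stage("load")
        peak_sets = [read_bed(p) for p in config.peaks]
        genes = read_tss_table(config.tss)
        de_records = read_de_table(config.de)
        done("load", t0, peaks=[len(s) for s in peak_sets], genes=len(genes), de=len(de_records))
    except (ParseError, OSError) as exc:
        raise PipelineError(f"stage load: {exc}") from exc

    motif_sites: list[GenomicInterval] = []
    if config.genome is not None:
        try:
            t0 = stage("scan")
            genome = read_fasta(config.genome)
            hits = scan_genome(genome, MotifConsensus(config.motif))
            write_bed(
                [
                    GenomicInterval(
                        h.interval.chrom, h.interval.start, h.interval.end,
                        name=h.interval.name, score=1.0, strand=h.strand,
                    )
                    for h in hits
                ],
                outdir / "motif_hits.bed",
            )
            motif_sites = dedupe_hit_intervals(hits)
            done("scan", t0, hits=len(hits), unique_sites=len(motif_sites))
        except (ParseError, ValueError, OSError) as exc:
            raise PipelineError(f"stage scan: {exc}") from exc

    try:
        t0 = stage("rp")
        rp_peaks = rp_score_all(genes, peak_sets[0], config.rp)
        _write_rp_tsv(rp_peaks, outdir / "rp_peaks.tsv")
        combined_sites = dedupe_intervals(list(peak_sets[0]) + motif_sites)
        if motif_sites:
            rp_motifs = rp_score_all(genes, motif_sites, config.rp)
            _write_rp_tsv(rp_motifs, outdir / "rp_motifs.tsv")
        rp_combined = rp_score_all(genes, combined_sites, config.rp)
        _write_rp_tsv(rp_combined, outdir / "rp_combined.tsv")
        done(
            "rp", t0,
            genes=len(rp_peaks),
            sites=len(combined_sites),
            genes_with_peak_rp=sum(1 for r in rp_peaks if r.rp > 0),
        )
    except ValueError as exc:
        raise PipelineError(f"stage rp: {exc}") from exc

    # target calls are driven by the reference factor's binding (peak RP);
    # motif and combined RP are reported alongside for inspection
    try:
        t0 = stage("call")
        calls = call_targets(rp_peaks, de_records, config.thresholds)
        _write_targets_tsv(calls, outdir / "targets.tsv")
        n_de = sum(1 for c in calls if c.de_direction != "none")
        n_direct = sum(1 for c in calls if c.is_direct)
        direct_fraction = summarize_direct_fraction(calls)
        done("call", t0, de_genes=n_de, direct_targets=n_direct)
    except ValueError as exc:
        raise PipelineError(f"stage call: {exc}") from exc
    report["direct_fraction"] = direct_fraction

    groups: list[ColocGroup] = []
    coloc_fraction = None
    if len(peak_sets) >= 2:
        try:
            t0 = stage("coloc")
            groups = colocalized_peaks(peak_sets, config.min_frac)
            write_bed([g.reference for g in groups], outdir / "coloc.bed")
            wit_rows = []
            for g in groups:
                for j, w in enumerate(g.witnesses, start=2):
                    wit_rows.append(
                        (g.reference.chrom, g.reference.start, g.reference.end,
                         f"set{j}", w.start, w.end)
                    )
            pd.DataFrame(
                wit_rows,
                columns=["chrom", "ref_start", "ref_end", "witness_set", "wit_start", "wit_end"],
            ).to_csv(outdir / "coloc_witnesses.tsv", sep="\t", index=False)
            coloc_fraction = fraction_of_genes_with_colocalized_peak(
                calls, genes, groups, config.rp.window_kb
            )
            done("coloc", t0, groups=len(groups))
        except ValueError as exc:
            raise PipelineError(f"stage coloc: {exc}") from exc
    report["coloc_fraction_of_direct_targets"] = coloc_fraction

    if config.pair is not None:
        try:
            t0 = stage("ecr")
            pair = read_sequence_pair(config.pair, aligned=config.pair_aligned)
            ecrs = find_ecrs(pair, config.ecr, tss=config.ecr_tss, chrom=pair.reference_name)
            write_bed(
                [
                    GenomicInterval(
                        e.interval.chrom, e.interval.start, e.interval.end,
                        name=e.interval.name, score=float(round(e.identity * 1000)),
                    )
                    for e in ecrs
                ],
                outdir / "ecrs.bed",
            )
            ecr_pairs = intersect_ecrs_with_peaks(ecrs, groups, config.proximity_bp)
            pd.DataFrame(
                [
                    (e.interval.name, e.interval.start, e.interval.end,
                     g.reference.chrom, g.reference.start, g.reference.end)
                    for e, g in ecr_pairs
                ],
                columns=["ecr", "ecr_start", "ecr_end", "peak_chrom", "peak_start", "peak_end"],
            ).to_csv(outdir / "ecr_peak_pairs.tsv", sep="\t", index=False)
            done("ecr", t0, ecrs=len(ecrs), ecr_peak_pairs=len(ecr_pairs))
        except ValueError as exc:
            raise PipelineError(f"stage ecr: {exc}") from exc

    if config.truth is not None:
        truth = SyntheticTruth.from_json(config.truth)
        planted = {gid for gid, _ in truth.planted_direct_targets}
        called = {c.gene_id for c in calls if c.is_direct}
        tp = len(planted & called)
        report["recall"] = tp / len(planted) if planted else None
        report["precision"] = tp / len(called) if called else None

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
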