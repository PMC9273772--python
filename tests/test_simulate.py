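import filecmp

import numpy as np
import pytest
from scipy import stats

from regpot_target import (
    ECRConfig,
    RPConfig,
    SimulationConfig,
    SyntheticTruth,
    call_targets,
    colocalized_peaks,
    find_ecrs,
    generate_dataset,
    generate_de_table,
    generate_genes,
    generate_genome,
    generate_peaks,
    generate_sequence_pair,
    rp_score_all,
    scan_genome,
)
from regpot_target.simulate import AP1_MOTIF

# laptop-scale conditions for fast structural checks; the acceptance suite
# exercises the full-size study
SMALL = SimulationConfig(
    n_chroms=2,
    chrom_length_bp=400_000,
    n_genes=60,
    n_peaks_per_factor=120,
    n_direct_targets=10,
    n_motif_plants=8,
    pair_length_bp=6_000,
    n_conserved_blocks=3,
    seed=13,
)


class TestGenerateGenome:
    def test_planted_instances_all_recovered_by_scan(self):
        genome, plants = generate_genome(SMALL)
        hits = {(h.interval.chrom, h.interval.start) for h in scan_genome(genome, AP1_MOTIF)}
        assert all((p.chrom, p.start) in hits for p in plants)
        assert len(plants) == SMALL.n_motif_plants

    def test_zero_plants_leaves_chance_hits_near_poisson_expectation(self):
        cfg = SimulationConfig(
            n_chroms=2, chrom_length_bp=2_000_000, n_motif_plants=0, seed=3
        )
        genome, plants = generate_genome(cfg)
        assert plants == []
        n_hits = len(scan_genome(genome, AP1_MOTIF))
        # per-position match probability: R and S contribute 2/4 each, the
        # other 8 positions 1/4, per strand -> lambda = 2 * L * 4/4^10
        lam = 2 * cfg.n_chroms * cfg.chrom_length_bp * 4 / 4**10
        assert stats.poisson.ppf(0.001, lam) <= n_hits <= stats.poisson.ppf(0.999, lam)

    def test_same_seed_is_byte_identical(self):
        g1, p1 = generate_genome(SMALL)
        g2, p2 = generate_genome(SMALL)
        assert g1 == g2 and p1 == p2

    def test_overfull_plant_request_is_error(self):
        with pytest.raises(ValueError, match="capacity"):
            generate_genome(SimulationConfig(n_chroms=1, chrom_length_bp=1000, n_motif_plants=200))


class TestGeneratePeaks:
    def test_full_coloc_fraction_recovers_every_reference_peak(self):
        cfg = SimulationConfig(**{**SMALL.__dict__, "coloc_fraction": 1.0})
        genes = generate_genes(cfg)
        ref, s2, s3, triples = generate_peaks(cfg, genes)
        groups = colocalized_peaks([ref, s2, s3], 0.5)
        assert len(groups) == len(ref)
        assert len(triples) == len(ref)

    def test_zero_coloc_fraction_gives_chance_level_groups(self):
        cfg = SimulationConfig(
            n_chroms=2, chrom_length_bp=5_000_000, n_genes=100,
            n_peaks_per_factor=300, coloc_fraction=0.0, seed=17,
        )
        genes = generate_genes(cfg)
        ref, s2, s3, triples = generate_peaks(cfg, genes)
        assert triples == []
        groups = colocalized_peaks([ref, s2, s3], 0.5)
        assert len(groups) < 0.05 * len(ref)

    def test_planted_triples_reciprocally_overlap(self):
        genes = generate_genes(SMALL)
        _, _, _, triples = generate_peaks(SMALL, genes)
        from regpot_target import reciprocal_overlap

        for ref, w2, w3 in triples:
            assert reciprocal_overlap(ref, w2, 0.5) is not None
            assert reciprocal_overlap(ref, w3, 0.5) is not None

    def test_interval_invariants_hold_for_every_peak(self):
        genes = generate_genes(SMALL)
        for peaks in generate_peaks(SMALL, genes)[:3]:
            for p in peaks:
                assert 0 <= p.start < p.end <= SMALL.chrom_length_bp


class TestGenerateDeTable:
    @staticmethod
    def _rp(cfg):
        genes = generate_genes(cfg)
        ref, *_ = generate_peaks(cfg, genes)
        return rp_score_all(genes, ref, RPConfig())

    def test_noise_off_gives_perfect_recall_and_precision(self):
        cfg = SimulationConfig(
            **{**SMALL.__dict__, "de_noise_sd": 0.0, "background_de_rate": 0.0}
        )
        rp_results = self._rp(cfg)
        records, truth = generate_de_table(cfg, rp_results)
        calls = call_targets(rp_results, records)
        direct = {c.gene_id for c in calls if c.is_direct}
        assert direct == {g for g, _ in truth}

    def test_planted_directions_match_fold_change_signs(self):
        rp_results = self._rp(SMALL)
        records, truth = generate_de_table(SMALL, rp_results)
        by_id = {r.gene_id: r for r in records}
        for gid, direction in truth:
            assert (by_id[gid].log2fc > 0) == (direction == "up")

    def test_false_de_layer_with_zero_rp_never_called_direct(self):
        cfg = SimulationConfig(
            **{**SMALL.__dict__, "background_de_rate": 0.2}
        )
        rp_results = self._rp(cfg)
        records, truth = generate_de_table(cfg, rp_results)
        calls = call_targets(rp_results, records)
        planted = {g for g, _ in truth}
        for c in calls:
            if c.gene_id not in planted and c.rp == 0:
                assert not c.is_direct

    def test_requesting_more_targets_than_bound_genes_is_error(self):
        cfg = SimulationConfig(
            **{**SMALL.__dict__, "n_peaks_per_factor": 1, "n_direct_targets": 59}
        )
        with pytest.raises(ValueError, match="rp > 0"):
            generate_de_table(cfg, self._rp(cfg))

    def test_same_seed_is_identical(self):
        rp_results = self._rp(SMALL)
        assert generate_de_table(SMALL, rp_results) == generate_de_table(SMALL, rp_results)


class TestGenerateSequencePair:
    def test_fully_conserved_block_detected_as_ecr(self):
        # fix block identities at 1.0 by regenerating until one is planted at 1.0
        pair, blocks = generate_sequence_pair(SMALL)
        ecrs = find_ecrs(pair, ECRConfig())
        perfect = [b for b, ident in blocks if ident >= 0.95]
        assert perfect, "expected at least one high-identity planted block"
        for block in perfect:
            assert any(
                e.interval.start <= block.start and e.interval.end >= block.end
                for e in ecrs
            )

    def test_background_produces_no_ecrs(self):
        cfg = SimulationConfig(
            **{**SMALL.__dict__, "n_conserved_blocks": 0, "pair_length_bp": 5_000}
        )
        pair, blocks = generate_sequence_pair(cfg)
        assert blocks == []
        assert find_ecrs(pair, ECRConfig()) == []

    def test_same_seed_is_identical(self):
        p1, b1 = generate_sequence_pair(SMALL)
        p2, b2 = generate_sequence_pair(SMALL)
        assert p1.reference_seq == p2.reference_seq and p1.query_seq == p2.query_seq
        assert b1 == b2


class TestGenerateDataset:
    def test_bundle_reproducible_byte_for_byte(self, tmp_path):
        generate_dataset(SMALL, tmp_path / "a")
        generate_dataset(SMALL, tmp_path / "b")
        for name in [
            "genome.fa", "junb.bed", "batf.bed", "irf4.bed",
            "tss.tsv", "de.tsv", "pair.fa", "truth.json",
        ]:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name

    def test_truth_round_trips_through_json(self, tmp_path):
        truth, paths = generate_dataset(SMALL, tmp_path / "c")
        back = SyntheticTruth.from_json(paths["truth"])
        assert back.planted_direct_targets == truth.planted_direct_targets
        assert [
            (iv.chrom, iv.start, iv.end) for iv in back.planted_motif_sites
        ] == [(iv.chrom, iv.start, iv.end) for iv in truth.planted_motif_sites]
        assert back.planted_conserved_blocks == [
            (type(iv)(iv.chrom, iv.start, iv.end), ident)
            for iv, ident in truth.planted_conserved_blocks
        ]

    def test_written_files_pass_the_format_readers(self, tmp_path):
        from regpot_target import read_bed, read_de_table, read_fasta, read_tss_table

        _, paths = generate_dataset(SMALL, tmp_path / "d")
        assert len(read_bed(paths["junb"])) == SMALL.n_peaks_per_factor
        assert len(read_tss_table(paths["tss"])) == SMALL.n_genes
        assert len(read_de_table(paths["de"])) == SMALL.n_genes
        assert len(read_fasta(paths["genome"])) == SMALL.n_chroms
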