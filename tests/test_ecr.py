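import numpy as np
import pytest

from oracles import brute_ecrs
from regpot_target import (
    ColocGroup,
    ECRConfig,
    GenomicInterval,
    SequencePair,
    align_pair,
    find_ecrs,
    intersect_ecrs_with_peaks,
    read_sequence_pair,
    window_identity,
    write_sequence_pair,
)

BASES = np.array(list("ACGT"))


def random_seq(rng, n):
    return "".join(rng.choice(BASES, size=n))


def mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def gapless(ref, qry):
    return SequencePair(ref, qry, alignment=(ref, qry))


class TestWindowIdentity:
    def test_identical_sequences_are_fully_identical(self, rng):
        s = random_seq(rng, 300)
        assert window_identity(gapless(s, s), 40, 200) == 1.0

    def test_counts_mismatching_columns(self, rng):
        s = random_seq(rng, 200)
        q = list(s)
        flipped = rng.choice(200, size=50, replace=False)
        for i in flipped:
            q[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[i]]
        assert window_identity(gapless(s, "".join(q)), 0, 200) == 0.75

    def test_gap_columns_count_as_mismatches(self):
        ref = "A" * 200
        qry = "A" * 190
        aln = ("A" * 200, "A" * 95 + "-" * 10 + "A" * 95)
        pair = SequencePair(ref, qry, alignment=aln)
        assert window_identity(pair, 0, 200) == pytest.approx(190 / 200)

    def test_window_past_reference_end_is_error(self):
        pair = gapless("ACGT" * 10, "ACGT" * 10)
        with pytest.raises(ValueError):
            window_identity(pair, 30, 200)


class TestFindEcrs:
    def test_identical_pair_yields_one_full_coverage_ecr(self, rng):
        s = random_seq(rng, 1000)
        ecrs = find_ecrs(gapless(s, s), ECRConfig())
        assert len(ecrs) == 1
        e = ecrs[0]
        assert (e.interval.start, e.interval.end) == (0, 1000)
        assert e.identity == 1.0 and e.interval.name == "ECR1"

    def test_planted_identical_block_in_divergent_background(self):
        rng = np.random.default_rng(5)
        ref = random_seq(rng, 2000)
        qry = mutate(rng, ref, 0.75)  # background ~25% identity
        qry = qry[:900] + ref[900:1200] + qry[1200:]  # plant 300-bp 100% block
        ecrs = find_ecrs(gapless(ref, qry), ECRConfig())
        assert len(ecrs) == 1
        e = ecrs[0]
        assert e.interval.start <= 900 and e.interval.end >= 1200

    def test_block_just_below_threshold_yields_nothing(self):
        rng = np.random.default_rng(6)
        ref = random_seq(rng, 1000)
        qry = mutate(rng, ref, 0.75)
        # plant a 200-bp block with exactly 148/200 matches (0.74 < 0.75)
        block = list(ref[400:600])
        bad = rng.choice(200, size=52, replace=False)
        for i in bad:
            block[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[block[i]]
        qry = qry[:400] + "".join(block) + qry[600:]
        # guard against chance qualifying windows in the mutated background
        ecrs = find_ecrs(gapless(ref, qry), ECRConfig())
        assert all(not (e.interval.start <= 400 and e.interval.end >= 600) for e in ecrs)
        assert ecrs == []

    def test_exact_threshold_block_qualifies(self):
        """A 200-bp window with exactly 150 matching columns reaches 0.75."""
        ref = "A" * 200
        qry = "A" * 150 + "C" * 50
        ecrs = find_ecrs(gapless(ref, qry), ECRConfig())
        assert len(ecrs) == 1 and ecrs[0].identity == 0.75

    def test_one_fewer_match_fails(self):
        ref = "A" * 200
        qry = "A" * 149 + "C" * 51
        assert find_ecrs(gapless(ref, qry), ECRConfig()) == []

    def test_reference_shorter_than_window_is_empty(self):
        assert find_ecrs(gapless("ACGT" * 10, "ACGT" * 10), ECRConfig()) == []

    def test_tss_flank_restricts_search(self, rng):
        s = random_seq(rng, 10_000)
        cfg = ECRConfig(flank_kb=1.0)
        ecrs = find_ecrs(gapless(s, s), cfg, tss=5000)
        assert len(ecrs) == 1
        assert (ecrs[0].interval.start, ecrs[0].interval.end) == (4000, 6000)

    def test_lowering_identity_never_reduces_coverage(self):
        rng = np.random.default_rng(7)
        ref = random_seq(rng, 3000)
        qry = mutate(rng, ref, 0.2)
        cover = []
        for ident in (0.95, 0.85, 0.75, 0.65):
            ecrs = find_ecrs(gapless(ref, qry), ECRConfig(min_identity=ident))
            cover.append(sum(len(e.interval) for e in ecrs))
        assert cover == sorted(cover)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_window_scan(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_seq(rng, 1200)
        qry = mutate(rng, ref, rng.uniform(0.1, 0.3))
        pair = gapless(ref, qry)
        ecrs = find_ecrs(pair, ECRConfig())
        expected = brute_ecrs(ref, qry, 200, 0.75)
        assert [(e.interval.start, e.interval.end) for e in ecrs] == [
            (s, t) for s, t, _ in expected
        ]
        assert [e.identity for e in ecrs] == pytest.approx([i for _, _, i in expected])


class TestAlignPair:
    def test_identical_sequences_align_gapless(self):
        pair = align_pair(SequencePair("ACGTACGT", "ACGTACGT"))
        assert pair.alignment == ("ACGTACGT", "ACGTACGT")

    def test_single_deletion_opens_one_gap(self):
        pair = align_pair(SequencePair("ACGT", "ACT"))
        ref_row, qry_row = pair.alignment
        assert ref_row.replace("-", "") == "ACGT"
        assert qry_row.count("-") == 1 and ref_row.count("-") == 0

    def test_empty_query_is_error(self):
        with pytest.raises(ValueError):
            align_pair(SequencePair("ACGT", ""))

    def test_oversized_input_refused(self):
        with pytest.raises(ValueError, match="precomputed"):
            align_pair(SequencePair("A" * 200_001, "ACGT"))

    def test_deterministic(self, rng):
        a, b = random_seq(rng, 300), random_seq(rng, 280)
        assert align_pair(SequencePair(a, b)).alignment == align_pair(SequencePair(a, b)).alignment


class TestIntersectEcrsWithPeaks:
    @staticmethod
    def _ecr(start, end, chrom="reference"):
        from regpot_target.ecr import ECR

        return ECR(GenomicInterval(chrom, start, end), 0.9, 1)

    @staticmethod
    def _group(start, end, chrom="reference"):
        return ColocGroup(GenomicInterval(chrom, start, end), ())

    def test_peak_inside_ecr_pairs_at_any_proximity(self):
        pairs = intersect_ecrs_with_peaks([self._ecr(100, 400)], [self._group(200, 300)], 0)
        assert len(pairs) == 1

    def test_distant_peak_unpaired(self):
        pairs = intersect_ecrs_with_peaks(
            [self._ecr(0, 200)], [self._group(10_200, 10_400)], 1000
        )
        assert pairs == []

    def test_three_planted_adjacent_peaks_among_many_ecrs(self):
        ecrs = [self._ecr(i * 5000, i * 5000 + 300) for i in range(20)]
        near = [self._group(i * 5000 + 500, i * 5000 + 700) for i in (3, 5, 19)]
        pairs = intersect_ecrs_with_peaks(ecrs, near, 1000)
        assert sorted(e.interval.start // 5000 for e, _ in pairs) == [3, 5, 19]


class TestPairIo:
    def test_round_trip_unaligned_and_aligned(self, tmp_path, rng):
        ref, qry = random_seq(rng, 100), random_seq(rng, 90)
        pair = align_pair(SequencePair(ref, qry, reference_name="m", query_name="h"))
        p = tmp_path / "pair.fa"
        write_sequence_pair(pair, p)
        back = read_sequence_pair(p, aligned=True)
        assert back.alignment == pair.alignment
        assert back.reference_seq == ref and back.query_seq == qry

    def test_wrong_record_count_is_error(self, tmp_path):
        p = tmp_path / "one.fa"
        p.write_text(">a\nACGT\n")
        with pytest.raises(ValueError):
            read_sequence_pair(p)
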