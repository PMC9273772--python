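import numpy as np
import pytest

from regpot_target import GenomicInterval, TSSRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_intervals(rng, n, chrom="chr1", max_pos=1_000_000, min_len=50, max_len=1000):
    starts = rng.integers(0, max_pos, size=n)
    lengths = rng.integers(min_len, max_len, size=n)
    return [
        GenomicInterval(chrom, int(s), int(s + l))
        for s, l in zip(starts, lengths)
    ]


def random_genes(rng, n, chrom="chr1", max_pos=1_000_000):
    return [
        TSSRecord(f"g{i:04d}", chrom, int(t), "+" if rng.random() < 0.5 else "-")
        for i, t in enumerate(rng.integers(0, max_pos, size=n))
    ]
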