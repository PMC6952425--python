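import numpy as np
import pandas as pd
import pytest

from polprof import GeneModel, GeneModelSet, ReadSet, SimulationConfig


@pytest.fixture
def toy_genes():
    """Hand-placed genes on a 10 kb chromosome, both strands."""
    return GeneModelSet(
        [
            GeneModel("gp", "chr1", 2000, 5000, "+"),
            GeneModel("gm", "chr1", 6000, 9000, "-"),
        ],
        {"chr1": 10_000},
    )


@pytest.fixture
def small_config():
    """Down-scaled simulation for fast unit tests."""
    return SimulationConfig(
        n_chroms=1,
        chrom_length=80_000,
        n_genes=12,
        depth=20_000,
        seed=0,
    )


def make_reads(records, chrom_sizes, total_mapped=0):
    """records: iterable of (chrom, start, end, strand)."""
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "strand"])
    return ReadSet(df, dict(chrom_sizes), total_mapped)


def uniform_reads(chrom, size, read_len, step, strand="+"):
    """Regularly spaced reads tiling a chromosome."""
    starts = np.arange(0, size - read_len, step)
    return make_reads(
        [(chrom, int(s), int(s + read_len), strand) for s in starts], {chrom: size}
    )


def pileup_bin_counts(reads: ReadSet, chrom, bin_starts, bin_ends):
    """Brute-force oracle: for each bin, count fragments overlapping it by
    direct per-fragment interval comparison."""
    recs = reads.data[reads.data["chrom"] == chrom]
    out = np.zeros(len(bin_starts), dtype=int)
    for s, e in zip(recs["start"], recs["end"]):
        for j, (bs, be) in enumerate(zip(bin_starts, bin_ends)):
            if s < be and e > bs:
                out[j] += 1
    return out
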