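"""Promoter-proximal pausing index from a normalized IP/input ratio track.

The pausing index of a gene is the ratio of its mean normalized Pol II
density in a pausing region to the mean over the gene body (the elongating
region).  Two pausing-region definitions are computed side by side: a
*relaxed* region spanning -500..+500 around the TSS (capturing promoter
and pause-site polymerase) and a *stringent* region covering only
TSS..+500.  The gene body runs from +500 to the TES.  Set-level indices are
arithmetic means of per-gene ratios over the usable genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import extend_reads, _count_overlaps
from .models import GeneModelSet, ReadSet

__all__ = [
    "PausingRegions",
    "RatioTrack",
    "PausingResult",
    "normalized_ratio_track",
    "pausing_indices",
]


@dataclass(frozen=True)
class PausingRegions:
    """Transcription-direction relative region bounds (bp from the TSS)."""

    relaxed: tuple[int, int] = (-500, 500)
    stringent: tuple[int, int] = (0, 500)
    body_start: int = 500  # body runs [body_start, gene length)


@dataclass
class RatioTrack:
    """Genome-wide binned (RPKM_ip + eps) / (RPKM_input + eps) ratio."""

    values: dict[str, np.ndarray]
    bin_size: int
    chrom_sizes: dict[str, int]
    pseudocount: float

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        """Overlap-length-weighted mean of the track over ``[start, end)``.

        The region is clipped to the chromosome; regions that clip to
        nothing return NaN.
        """
        size = self.chrom_sizes[chrom]
        start, end = max(start, 0), min(end, size)
        if start >= end:
            return float("nan")
        b = self.bin_size
        first, last = start // b, (end - 1) // b
        vals = self.values[chrom][first : last + 1]
        edges = np.arange(first, last + 2) * b
        lo = np.maximum(edges[:-1], start)
        hi = np.minimum(edges[1:], end)
        weights = (hi - lo).astype(float)
        return float(np.sum(vals * weights) / np.sum(weights))

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, vals in self.values.items():
                size = self.chrom_sizes[chrom]
                for i, v in enumerate(vals):
                    s = i * self.bin_size
                    fh.write(f"{chrom}\t{s}\t{min(s + self.bin_size, size)}\t{v:.6g}\n")


def normalized_ratio_track(
    ip: ReadSet,
    input: ReadSet,
    bin_size: int = 60,
    extend: int | None = 200,
    pseudocount: float = 1.0,
) -> RatioTrack:
    """Per-bin RPKM ratio of IP over input across the genome.

    RPKM here is ``count x 10^9 / (bin_bp x total_mapped)``, counting a
    fragment into every bin it overlaps.  ``extend`` replaces each read by a
    fixed-size fragment from its 5' end first (pass ``None`` if the reads
    are already fragments).
    """
    if ip.chrom_sizes != input.chrom_sizes:
        raise ValueError("ip and input live on different genomes")
    if ip.total_mapped <= 0 or input.total_mapped <= 0:
        raise ValueError("zero mapped reads")
    if extend is not None:
        ip = extend_reads(ip, extend)
        input = extend_reads(input, extend)
    ip_idx, in_idx = ip.sorted_index(), input.sorted_index()
    values: dict[str, np.ndarray] = {}
    for chrom, size in ip.chrom_sizes.items():
        n_bins = -(-size // bin_size)
        bs = np.arange(n_bins, dtype=np.int64) * bin_size
        be = np.minimum(bs + bin_size, size)
        widths = (be - bs).astype(float)
        rpkm_ip = _count_overlaps(ip_idx, chrom, bs, be) * 1e9 / (widths * ip.total_mapped)
        rpkm_in = _count_overlaps(in_idx, chrom, bs, be) * 1e9 / (widths * input.total_mapped)
        values[chrom] = (rpkm_ip + pseudocount) / (rpkm_in + pseudocount)
    return RatioTrack(values, bin_size, dict(ip.chrom_sizes), pseudocount)


@dataclass
class PausingResult:
    """Per-gene and set-level pausing indices."""

    per_gene: pd.DataFrame
    set_relaxed: float
    set_stringent: float
    n_used: int
    exclusions: dict[str, int] = field(default_factory=dict)
    regions: PausingRegions = field(default_factory=PausingRegions)


def pausing_indices(
    track: RatioTrack,
    genes: GeneModelSet,
    gene_set: Sequence[str] | None = None,
    regions: PausingRegions = PausingRegions(),
    min_gene_length: int | None = None,
) -> PausingResult:
    """Compute relaxed and stringent pausing indices per gene and per set.

    Region means are overlap-length weighted over the track bins (regions
    need not align to the bin grid).  Genes too short to contain one
    complete body bin (length <= body_start + bin_size by default) are
    excluded and counted per reason.  The set value is the arithmetic mean
    of per-gene ratios over usable genes.
    """
    if min_gene_length is None:
        min_gene_length = regions.body_start + track.bin_size
    subset = genes if gene_set is None else genes.subset(list(gene_set))
    if len(subset) == 0:
        raise ValueError("empty gene set")

    rows = []
    exclusions: dict[str, int] = {}
    for g in subset:
        row = {"gene_id": g.gene_id, "relaxed": np.nan, "stringent": np.nan,
               "body_mean": np.nan, "usable": False, "exclusion_reason": ""}
        if g.length <= min_gene_length:
            row["exclusion_reason"] = "body_too_short"
        else:
            means = {}
            for name, (a, b) in (
                ("relaxed", regions.relaxed),
                ("stringent", regions.stringent),
                ("body", (regions.body_start, g.length)),
            ):
                s, e = g.rel_interval_to_genomic(a, b)
                means[name] = track.region_mean(g.chrom, s, e)
            if not all(np.isfinite(v) for v in means.values()):
                row["exclusion_reason"] = "region_outside_chromosome"
            elif means["body"] <= 0:
                row["exclusion_reason"] = "body_mean_zero"
            else:
                row.update(
                    relaxed=means["relaxed"] / means["body"],
                    stringent=means["stringent"] / means["body"],
                    body_mean=means["body"],
                    usable=True,
                )
        if not row["usable"]:
            exclusions[row["exclusion_reason"]] = exclusions.get(row["exclusion_reason"], 0) + 1
        rows.append(row)

    per_gene = pd.DataFrame(rows)
    used = per_gene[per_gene["usable"]]
    if used.empty:
        raise ValueError(f"no usable genes; exclusions: {exclusions}")
    return PausingResult(
        per_gene,
        set_relaxed=float(used["relaxed"].mean()),
        set_stringent=float(used["stringent"].mean()),
        n_used=len(used),
        exclusions=exclusions,
        regions=regions,
    )
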