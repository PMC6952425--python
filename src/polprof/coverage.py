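"""Binned read densities and fold enrichment over input around anchors.

The engine converts extended fragments into RPKM-style bin densities
(reads · kb⁻¹ · million-mapped⁻¹, i.e. ``count × 10⁹ / (bin_bp × total)``)
in fixed windows around the TSS, the TES or peak summits, or in
length-scaled bins across gene bodies, and then forms per-bin IP/input
ratios.  A fragment increments every bin it overlaps (coverage semantics);
bins that fall off a chromosome end are kept but flagged missing and
excluded pairwise from any aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .models import GeneModelSet, ReadSet

__all__ = [
    "AnchorSpec",
    "DensityProfile",
    "EnrichmentProfile",
    "extend_reads",
    "bin_density",
    "fold_enrichment",
]

AnchorKind = Literal["tss", "tes", "summit", "genebody"]


@dataclass(frozen=True)
class AnchorSpec:
    """Where and how to bin.

    ``flank``/``bin_size`` drive fixed-width windows around point anchors;
    ``n_body_bins`` drives length-scaled gene-body profiles (1%-of-gene bins
    at the default 100).
    """

    kind: AnchorKind = "tss"
    flank: int = 600
    bin_size: int = 60
    n_body_bins: int = 100

    def __post_init__(self) -> None:
        if self.kind in ("tss", "tes", "summit"):
            if self.flank <= 0 or self.bin_size <= 0:
                raise ValueError("flank and bin_size must be positive")
            if self.flank % self.bin_size:
                raise ValueError("flank must be divisible by bin_size")
        elif self.n_body_bins < 1:
            raise ValueError("n_body_bins must be >= 1")

    @property
    def bin_labels(self) -> np.ndarray:
        """Left edges of the bins in transcription-direction bp (or bin index
        for gene-body mode)."""
        if self.kind == "genebody":
            return np.arange(self.n_body_bins)
        return np.arange(-self.flank, self.flank, self.bin_size)


@dataclass
class DensityProfile:
    """Per-gene binned normalized densities around an anchor.

    ``values`` is genes x bins; missing (off-chromosome) bins are NaN.
    """

    values: np.ndarray
    bin_labels: np.ndarray
    gene_ids: list[str]
    library: str
    spec: AnchorSpec
    bin_widths: np.ndarray | None = None  # per-gene width, gene-body mode only

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.gene_ids), len(self.bin_labels)):
            raise ValueError("values shape does not match gene_ids x bin_labels")
        if np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("densities must be non-negative")

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset(self, gene_ids: Sequence[str]) -> "DensityProfile":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return replace(self, values=self.values[idx], gene_ids=list(gene_ids))


def extend_reads(reads: ReadSet, length: int) -> ReadSet:
    """Replace each read by the ``length``-bp interval starting at its 5' end.

    Extension follows the read strand and is clipped at chromosome bounds;
    ``total_mapped`` is unchanged.
    """
    if length <= 0:
        raise ValueError("extension length must be positive")
    df = reads.data.copy()
    start = df["start"].to_numpy(dtype=np.int64)
    end = df["end"].to_numpy(dtype=np.int64)
    minus = (df["strand"] == "-").to_numpy()
    new_start = np.where(minus, end - length, start)
    new_end = np.where(minus, end, start + length)
    sizes = df["chrom"].map(reads.chrom_sizes).to_numpy(dtype=np.int64)
    df["start"] = np.clip(new_start, 0, sizes)
    df["end"] = np.clip(new_end, 0, sizes)
    df = df[df["start"] < df["end"]].reset_index(drop=True)
    return ReadSet(df, reads.chrom_sizes, reads.total_mapped, fragment_length=length)


def _count_overlaps(
    index: dict[str, tuple[np.ndarray, np.ndarray]],
    chrom: str,
    bin_starts: np.ndarray,
    bin_ends: np.ndarray,
) -> np.ndarray:
    """Fragments overlapping each half-open bin: start < bin_end and end > bin_start."""
    if chrom not in index:
        return np.zeros(len(bin_starts), dtype=np.int64)
    starts, ends = index[chrom]
    return np.searchsorted(starts, bin_ends, side="left") - np.searchsorted(
        ends, bin_starts, side="right"
    )


def _window_bins(anchor: int, strand: str, spec: AnchorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Genomic (start, end) arrays of the window bins, in transcription order."""
    labels = spec.bin_labels
    if strand == "+":
        bs = anchor + labels
        return bs, bs + spec.bin_size
    # minus strand: relative [l, l+b) covers genomic [anchor-l-b+1, anchor-l+1)
    bs = anchor - labels - spec.bin_size + 1
    return bs, bs + spec.bin_size


def bin_density(
    reads: ReadSet,
    genes: GeneModelSet | pd.DataFrame,
    spec: AnchorSpec,
    library: str = "ip",
) -> DensityProfile:
    """Compute per-gene binned densities around the anchors ``spec`` names.

    ``genes`` is a :class:`GeneModelSet` for tss/tes/genebody anchors, or a
    summit table (as from :func:`polprof.io.read_summits`) for summit
    anchors.  Reads are expected to be already extended to fragment size.
    """
    if reads.total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    index = reads.sorted_index()
    scale = 1e9 / reads.total_mapped

    if spec.kind == "summit":
        if isinstance(genes, GeneModelSet):
            raise TypeError("summit anchors require a summit table")
        names = genes["name"].tolist()
        anchors = [
            (str(r.chrom), int(r.summit), str(r.strand)) for r in genes.itertuples(index=False)
        ]
        chrom_sizes = reads.chrom_sizes
    else:
        if not isinstance(genes, GeneModelSet):
            raise TypeError(f"{spec.kind} anchors require a GeneModelSet")
        names = genes.ids
        chrom_sizes = genes.chrom_sizes
        if spec.kind == "tss":
            anchors = [(g.chrom, g.tss, g.strand) for g in genes]
        elif spec.kind == "tes":
            anchors = [(g.chrom, g.tes, g.strand) for g in genes]
        else:  # genebody
            return _genebody_density(reads, genes, spec, library, scale)

    labels = spec.bin_labels
    values = np.full((len(names), len(labels)), np.nan)
    for i, (chrom, anchor, strand) in enumerate(anchors):
        size = chrom_sizes[chrom]
        bs, be = _window_bins(anchor, strand, spec)
        inside = (bs >= 0) & (be <= size)
        counts = _count_overlaps(index, chrom, bs[inside], be[inside])
        row = np.full(len(labels), np.nan)
        row[inside] = counts * scale / spec.bin_size
        values[i] = row
    return DensityProfile(values, labels, list(names), library, spec)


def _genebody_density(
    reads: ReadSet, genes: GeneModelSet, spec: AnchorSpec, library: str, scale: float
) -> DensityProfile:
    index = reads.sorted_index()
    n_bins = spec.n_body_bins
    values = np.full((len(genes), n_bins), np.nan)
    widths = np.zeros(len(genes))
    for i, g in enumerate(genes):
        edges = np.floor(g.start + np.arange(n_bins + 1) * g.length / n_bins).astype(np.int64)
        bs, be = edges[:-1], edges[1:]
        ok = bs < be
        counts = _count_overlaps(index, g.chrom, bs[ok], be[ok])
        row = np.full(n_bins, np.nan)
        row[ok] = counts * scale / (be[ok] - bs[ok])
        if g.strand == "-":
            row = row[::-1]
        values[i] = row
        widths[i] = g.length / n_bins
    return DensityProfile(values, spec.bin_labels, genes.ids, library, spec, bin_widths=widths)


@dataclass
class EnrichmentProfile:
    """Per-bin fold enrichment of an IP library over its matched input.

    The default ``set_mean`` aggregation divides the gene-set mean IP density
    of every bin (plus pseudocount) by the matching input mean; ``per_gene``
    forms the gene-wise ratio first.  Bins missing in either library are
    excluded pairwise.
    """

    ip: DensityProfile
    input: DensityProfile
    pseudocount: float = 1.0
    aggregate: Literal["set_mean", "per_gene"] = "set_mean"

    def __post_init__(self) -> None:
        if self.ip.values.shape != self.input.values.shape:
            dim = "genes" if len(self.ip.gene_ids) != len(self.input.gene_ids) else "bins"
            raise ValueError(f"ip and input profiles differ in dimension: {dim}")
        if self.ip.gene_ids != self.input.gene_ids:
            raise ValueError("ip and input profiles cover different genes")
        if not np.array_equal(self.ip.bin_labels, self.input.bin_labels):
            raise ValueError("ip and input profiles have different bin labels")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @property
    def bin_labels(self) -> np.ndarray:
        return self.ip.bin_labels

    @property
    def gene_ids(self) -> list[str]:
        return self.ip.gene_ids

    def _rows(self, gene_set: Sequence[str] | None) -> tuple[np.ndarray, np.ndarray]:
        if gene_set is None:
            ip, inp = self.ip.values, self.input.values
        else:
            idx = [self.gene_ids.index(g) for g in gene_set]
            ip, inp = self.ip.values[idx], self.input.values[idx]
        missing = np.isnan(ip) | np.isnan(inp)
        return np.where(missing, np.nan, ip), np.where(missing, np.nan, inp)

    def per_gene_matrix(self, gene_set: Sequence[str] | None = None) -> np.ndarray:
        """Gene-wise (IP + eps) / (input + eps) ratio matrix."""
        ip, inp = self._rows(gene_set)
        with np.errstate(invalid="ignore", divide="ignore"):
            return (ip + self.pseudocount) / (inp + self.pseudocount)

    def values(self, gene_set: Sequence[str] | None = None) -> np.ndarray:
        """Set-level per-bin fold enrichment under the configured aggregation."""
        ip, inp = self._rows(gene_set)
        with np.errstate(invalid="ignore", divide="ignore"):
            if self.aggregate == "set_mean":
                return (np.nanmean(ip, axis=0) + self.pseudocount) / (
                    np.nanmean(inp, axis=0) + self.pseudocount
                )
            return np.nanmean(self.per_gene_matrix(gene_set), axis=0)

    def to_frame(self, gene_set: Sequence[str] | None = None) -> pd.DataFrame:
        ip, inp = self._rows(gene_set)
        return pd.DataFrame(
            {
                "bin_label": self.bin_labels,
                "ip_density": np.nanmean(ip, axis=0),
                "input_density": np.nanmean(inp, axis=0),
                "enrichment": self.values(gene_set),
            }
        )


def fold_enrichment(
    ip: DensityProfile,
    input: DensityProfile,
    pseudocount: float = 1.0,
    aggregate: Literal["set_mean", "per_gene"] = "set_mean",
) -> EnrichmentProfile:
    """Form the per-bin fold-enrichment-over-input profile for matched IP and
    input density profiles."""
    return EnrichmentProfile(ip, input, pseudocount, aggregate)
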