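"""Core genomic containers: gene models and aligned-read sets.

Coordinate conventions used throughout the package:

* All internal coordinates are 0-based, half-open ``[start, end)`` (BED
  native; GFF3 is converted on read).
* The TSS of a plus-strand gene is ``start``; of a minus-strand gene it is
  ``end - 1``.  The TES (last transcribed base) of a plus-strand gene is
  ``end - 1``; of a minus-strand gene it is ``start``.
* "Downstream" and all anchor-relative coordinates are in transcription
  direction: relative position ``r`` of genomic base ``g`` is ``g - tss``
  for plus-strand genes and ``tss - g`` for minus-strand genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["GeneModel", "GeneModelSet", "ReadSet"]


@dataclass(frozen=True)
class GeneModel:
    """A single gene interval with strand-aware anchors."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start site."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Genomic position of the last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    def to_genomic(self, rel: int) -> int:
        """Map a transcription-direction relative position to genomic."""
        return self.tss + rel if self.strand == "+" else self.tss - rel

    def rel_interval_to_genomic(self, a: int, b: int) -> tuple[int, int]:
        """Map the relative half-open interval ``[a, b)`` to a genomic one.

        For minus-strand genes the genomic interval is reversed:
        relative ``[a, b)`` covers genomic ``[tss - b + 1, tss - a + 1)``.
        """
        if a >= b:
            raise ValueError("empty relative interval")
        if self.strand == "+":
            return self.tss + a, self.tss + b
        return self.tss - b + 1, self.tss - a + 1


class GeneModelSet:
    """An ordered collection of gene models on a genome.

    Parameters
    ----------
    genes
        Iterable of :class:`GeneModel`.
    chrom_sizes
        Mapping chromosome name -> length in bp.
    """

    def __init__(self, genes: Iterable[GeneModel], chrom_sizes: Mapping[str, int]):
        self.genes: list[GeneModel] = list(genes)
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids")
        self._by_id = {g.gene_id: g for g in self.genes}
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    @property
    def ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def subset(self, gene_ids: Sequence[str]) -> "GeneModelSet":
        missing = [i for i in gene_ids if i not in self._by_id]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return GeneModelSet([self._by_id[i] for i in gene_ids], self.chrom_sizes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
            }
        )

    def mirrored(self) -> "GeneModelSet":
        """Reflect every gene through its chromosome (used by symmetry checks)."""
        out = []
        for g in self.genes:
            n = self.chrom_sizes[g.chrom]
            out.append(
                GeneModel(
                    g.gene_id,
                    g.chrom,
                    n - g.end,
                    n - g.start,
                    "-" if g.strand == "+" else "+",
                )
            )
        return GeneModelSet(out, self.chrom_sizes)


@dataclass
class ReadSet:
    """Aligned single-end reads (or extended fragments).

    ``data`` holds one record per read with columns ``chrom``, ``start``,
    ``end`` (0-based half-open) and ``strand``.  ``total_mapped`` is the
    library size used for density normalization; it defaults to the record
    count and is carried unchanged through read extension so that
    duplicating a library leaves densities invariant.
    """

    data: pd.DataFrame
    chrom_sizes: dict[str, int]
    total_mapped: int = 0
    fragment_length: int | None = None

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "strand"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"read table must have columns {sorted(required)}")
        if len(self.data) and (self.data["start"] >= self.data["end"]).any():
            raise ValueError("reads must satisfy start < end")
        if self.total_mapped == 0:
            self.total_mapped = len(self.data)
        if self.total_mapped < len(self.data):
            raise ValueError("total_mapped cannot be below the record count")
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.data)

    def sorted_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome ``(sorted starts, sorted ends)`` for overlap counting."""
        if self._index is None:
            idx = {}
            for chrom, grp in self.data.groupby("chrom", sort=False):
                starts = np.sort(grp["start"].to_numpy(dtype=np.int64))
                ends = np.sort(grp["end"].to_numpy(dtype=np.int64))
                idx[str(chrom)] = (starts, ends)
            self._index = idx
        return self._index

    def concat(self, other: "ReadSet") -> "ReadSet":
        if self.chrom_sizes != other.chrom_sizes:
            raise ValueError("read sets live on different genomes")
        return ReadSet(
            pd.concat([self.data, other.data], ignore_index=True),
            self.chrom_sizes,
            self.total_mapped + other.total_mapped,
            self.fragment_length,
        )

    def mirrored(self) -> "ReadSet":
        """Reflect every read through its chromosome, flipping strand."""
        df = self.data.copy()
        sizes = df["chrom"].map(self.chrom_sizes).to_numpy(dtype=np.int64)
        start = sizes - df["end"].to_numpy(dtype=np.int64)
        end = sizes - df["start"].to_numpy(dtype=np.int64)
        df["start"], df["end"] = start, end
        df["strand"] = np.where(df["strand"] == "+", "-", "+")
        return ReadSet(df, self.chrom_sizes, self.total_mapped, self.fragment_length)
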