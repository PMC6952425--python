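"""Readers and writers for the standard formats the pipeline touches.

Gene models travel as BED12 or GFF3, reads as coordinate-sorted SAM or
6-column BED, sequence as FASTA, and all tables as tab-separated text with a
header.  BED is consumed natively (0-based half-open); GFF3 starts are
shifted by -1 on read.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd
import pysam
from Bio import SeqIO

from .models import GeneModel, GeneModelSet, ReadSet

__all__ = [
    "read_bed12",
    "write_bed12",
    "read_gff3",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "read_sam",
    "write_sam",
    "read_bed_reads",
    "write_bed_reads",
    "read_summits",
]


# ---------------------------------------------------------------------------
# gene models


def write_bed12(genes: GeneModelSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            block = f"{g.length},"
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t1\t{block}\t0,\n"
            )


def read_bed12(path: str | os.PathLike, chrom_sizes: Mapping[str, int]) -> GeneModelSet:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError("BED gene file needs at least 6 columns")
            genes.append(GeneModel(f[3], f[0], int(f[1]), int(f[2]), f[5]))
    return GeneModelSet(genes, chrom_sizes)


def write_gff3(genes: GeneModelSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in genes.chrom_sizes.items():
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tpolprof\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_gff3(path: str | os.PathLike, chrom_sizes: Mapping[str, int] | None = None) -> GeneModelSet:
    genes = []
    sizes: dict[str, int] = dict(chrom_sizes or {})
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()[:4]
                sizes.setdefault(chrom, int(end))
                continue
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gene_id = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
            genes.append(GeneModel(gene_id, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    if not sizes:
        raise ValueError("no chromosome sizes: provide chrom_sizes or ##sequence-region lines")
    return GeneModelSet(genes, sizes)


def read_summits(path: str | os.PathLike) -> pd.DataFrame:
    """Read a peak BED with an optional summit-offset column.

    Columns used: chrom, start, end, name, [score], [strand], [summit offset
    relative to start].  Without an offset column the summit is the interval
    midpoint; without a strand column the plus strand is assumed.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else f"peak{i}"
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
            summit = start + int(f[6]) if len(f) > 6 else (start + end) // 2
            rows.append((name, chrom, start, end, strand, summit))
    return pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "strand", "summit"])


# ---------------------------------------------------------------------------
# sequence


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# reads


def write_sam(reads: ReadSet, path: str | os.PathLike) -> None:
    """Write reads as a coordinate-sorted SAM file (sequence omitted)."""
    chroms = list(reads.chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(reads.chrom_sizes[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    df = reads.data.sort_values(["chrom", "start"], kind="mergesort")
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, row in enumerate(df.itertuples(index=False)):
            a = pysam.AlignedSegment()
            a.query_name = f"read{i}"
            a.flag = 16 if row.strand == "-" else 0
            a.reference_id = tid[row.chrom]
            a.reference_start = int(row.start)
            a.mapping_quality = 255
            a.cigartuples = [(0, int(row.end) - int(row.start))]
            out.write(a)


def read_sam(path: str | os.PathLike) -> ReadSet:
    chroms, starts, ends, strands = [], [], [], []
    with pysam.AlignmentFile(str(path), "r") as fh:
        sizes = {sq["SN"]: sq["LN"] for sq in fh.header.to_dict()["SQ"]}
        for a in fh:
            if a.is_unmapped:
                continue
            chroms.append(a.reference_name)
            starts.append(a.reference_start)
            ends.append(a.reference_end)
            strands.append("-" if a.is_reverse else "+")
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "strand": strands})
    return ReadSet(df, sizes)


def write_bed_reads(reads: ReadSet, path: str | os.PathLike) -> None:
    df = reads.data.sort_values(["chrom", "start"], kind="mergesort")
    with open(path, "w") as fh:
        for i, row in enumerate(df.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tread{i}\t0\t{row.strand}\n")


def read_bed_reads(path: str | os.PathLike, chrom_sizes: Mapping[str, int]) -> ReadSet:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        comment="#",
    )
    return ReadSet(df, dict(chrom_sizes))
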