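"""Regulated gene sets, suppression fractions, overlap and motif statistics.

Gene sets are cut from a differential-expression table at an FDR threshold;
"suppression" of a mutant-induced expression change by an RNAi is scored
either as a significant change in the opposing direction under the RNAi
(within-mutant contrast, the default) or as attenuation of the fold change
versus wild type.  Set overlaps are tested with the one-sided upper-tail
hypergeometric distribution, computed in log space.  Promoter motif
enrichment scans an IUPAC consensus over a TSS-relative window on the sense
strand and applies the same hypergeometric test to hit counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .models import GeneModelSet
from .simulate import IUPAC, revcomp

__all__ = [
    "classify_regulated",
    "suppression_fraction",
    "GeneSetOverlap",
    "overlap_test",
    "MotifSpec",
    "MotifEnrichment",
    "scan_consensus",
    "motif_enrichment",
]


def _require(table: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"expression table lacks contrast columns: {missing}")


def classify_regulated(
    table: pd.DataFrame,
    fdr: float = 0.05,
    mutant_contrast: str = "mutant_vs_wt",
    rnai_contrasts: Sequence[str] = (),
) -> dict[str, set[str]]:
    """Build regulated gene sets from a differential-expression table.

    Expects per-contrast columns ``log2fc_<contrast>`` and ``q_<contrast>``.
    Returns ``up_in_mutant``/``down_in_mutant`` from the mutant contrast and,
    per RNAi contrast, ``activated_by_<X>`` (significantly lower under the
    knockdown, i.e. genes the factor activates) and ``repressed_by_<X>``.
    """
    _require(table, [f"log2fc_{mutant_contrast}", f"q_{mutant_contrast}"])
    ids = table["gene_id"]
    q = table[f"q_{mutant_contrast}"]
    fc = table[f"log2fc_{mutant_contrast}"]
    sets = {
        "up_in_mutant": set(ids[(q < fdr) & (fc > 0)]),
        "down_in_mutant": set(ids[(q < fdr) & (fc < 0)]),
    }
    for rnai in rnai_contrasts:
        _require(table, [f"log2fc_{rnai}", f"q_{rnai}"])
        qx, fx = table[f"q_{rnai}"], table[f"log2fc_{rnai}"]
        sets[f"activated_by_{rnai}"] = set(ids[(qx < fdr) & (fx < 0)])
        sets[f"repressed_by_{rnai}"] = set(ids[(qx < fdr) & (fx > 0)])
    return sets


def suppression_fraction(
    mutant_set: Iterable[str],
    table: pd.DataFrame,
    rnai_contrast: str,
    direction: Literal["up", "down"] = "up",
    fdr: float = 0.05,
    mode: Literal["opposing_significant", "attenuated"] = "opposing_significant",
    mutant_contrast: str = "mutant_vs_wt",
    rnai_vs_wt_contrast: str | None = None,
    attenuation_threshold: float = 0.5,
) -> float:
    """Fraction of a mutant-regulated set whose change the RNAi suppresses.

    ``opposing_significant``: significant change in the opposing direction
    under the RNAi-vs-control contrast within the mutant.  ``attenuated``:
    |log2FC vs wild type under the RNAi| below ``attenuation_threshold``
    times the original mutant fold change (requires the
    ``rnai_vs_wt_contrast`` columns).
    """
    mutant_set = set(mutant_set)
    if not mutant_set:
        raise ValueError("empty mutant set")
    sub = table[table["gene_id"].isin(mutant_set)]
    if mode == "opposing_significant":
        _require(sub, [f"log2fc_{rnai_contrast}", f"q_{rnai_contrast}"])
        q, fc = sub[f"q_{rnai_contrast}"], sub[f"log2fc_{rnai_contrast}"]
        opposing = fc < 0 if direction == "up" else fc > 0
        suppressed = (q < fdr) & opposing
    elif mode == "attenuated":
        if rnai_vs_wt_contrast is None:
            raise ValueError("attenuated mode needs rnai_vs_wt_contrast")
        _require(sub, [f"log2fc_{rnai_vs_wt_contrast}", f"log2fc_{mutant_contrast}"])
        suppressed = sub[f"log2fc_{rnai_vs_wt_contrast}"].abs() < (
            attenuation_threshold * sub[f"log2fc_{mutant_contrast}"].abs()
        )
    else:
        raise ValueError(f"unknown mode '{mode}'")
    return float(suppressed.sum() / len(sub))


@dataclass(frozen=True)
class GeneSetOverlap:
    """Hypergeometric overlap test result."""

    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    p: float


def _hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), summed in log space."""
    if k <= 0:
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    support = np.arange(k, hi + 1)
    return float(min(1.0, np.exp(logsumexp(stats.hypergeom.logpmf(support, N, K, n)))))


def overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> GeneSetOverlap:
    """One-sided enrichment test for the overlap of two gene sets.

    p = P[X >= |A ∩ B|] with X ~ Hypergeometric(N=|universe|, K=|A|, n=|B|);
    exact, log-space summation.  Sets must be subsets of the universe.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    stray = sorted((a | b) - u)
    if stray:
        raise ValueError(f"ids outside the universe: {stray[:5]}")
    k = len(a & b)
    return GeneSetOverlap(len(a), len(b), k, len(u), _hypergeom_upper_tail(k, len(u), len(a), len(b)))


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC consensus and where to look for it.

    ``window`` is TSS-relative in transcription direction, half-open; the
    scan runs on the sense strand only unless ``both_orientations``.
    Defaults follow common core-promoter practice: TATA = TATAWAWR in
    [-100, 0), Inr = YYANWYY in [-5, +5).
    """

    name: str
    consensus: str
    window: tuple[int, int]
    both_orientations: bool = False

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("empty consensus")
        bad = [c for c in self.consensus.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"non-IUPAC symbols in consensus: {bad}")


TATA_SPEC = MotifSpec("TATA", "TATAWAWR", (-100, 0))
INR_SPEC = MotifSpec("Inr", "YYANWYY", (-5, 5))


def scan_consensus(seq: str, consensus: str) -> bool:
    """True if the IUPAC consensus matches anywhere in ``seq``."""
    seq = seq.upper()
    cons = consensus.upper()
    m, n = len(cons), len(seq)
    allowed = [set(IUPAC[c]) for c in cons]
    for i in range(n - m + 1):
        if all(seq[i + j] in allowed[j] for j in range(m)):
            return True
    return False


@dataclass(frozen=True)
class MotifEnrichment:
    """Motif hit counts in a gene set versus its background."""

    motif: MotifSpec
    set_hits: int
    set_n: int
    background_hits: int
    background_n: int
    p: float
    n_skipped: int = 0


def _promoter_seq(gene, seqs: Mapping[str, str], window: tuple[int, int]) -> str | None:
    s, e = gene.rel_interval_to_genomic(*window)
    if s < 0 or e > len(seqs[gene.chrom]):
        return None
    sub = seqs[gene.chrom][s:e]
    return sub if gene.strand == "+" else revcomp(sub)


def motif_enrichment(
    seqs: Mapping[str, str],
    genes: GeneModelSet,
    gene_set: Iterable[str],
    background_set: Iterable[str],
    motif: MotifSpec = TATA_SPEC,
) -> MotifEnrichment:
    """Test whether a promoter motif is enriched in a gene set.

    A gene is a hit if the consensus matches anywhere in its window on the
    sense strand (optionally either orientation).  The p-value is the
    upper-tail hypergeometric probability of the set's hit count given the
    hits in set ∪ background.  Genes whose window falls off the sequence
    are skipped and counted.
    """
    gene_set = list(dict.fromkeys(gene_set))
    background_set = [g for g in dict.fromkeys(background_set) if g not in set(gene_set)]
    skipped = 0

    def hits(ids: list[str]) -> tuple[int, int]:
        nonlocal skipped
        h = n = 0
        for gid in ids:
            seq = _promoter_seq(genes[gid], seqs, motif.window)
            if seq is None:
                skipped += 1
                continue
            n += 1
            found = scan_consensus(seq, motif.consensus)
            if not found and motif.both_orientations:
                found = scan_consensus(revcomp(seq), motif.consensus)
            h += int(found)
        return h, n

    set_hits, set_n = hits(gene_set)
    bg_hits, bg_n = hits(background_set)
    N = set_n + bg_n
    K = set_hits + bg_hits
    p = _hypergeom_upper_tail(set_hits, N, K, set_n) if set_n else 1.0
    return MotifEnrichment(motif, set_hits, set_n, bg_hits, bg_n, p, skipped)
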