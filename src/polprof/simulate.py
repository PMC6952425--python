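"""Synthetic testbed: toy genomes, Pol II occupancy reads and omics tables.

The read simulator embodies a compositional model of Pol II occupancy over a
gene: a *recruitment* component upstream of the TSS (polymerase engaged at
the promoter but not yet cleared), a promoter-proximal *pause* peak near
+50, uniform *body* coverage from elongating polymerase, and a *tes*
component at the transcription end that can be shifted downstream to mimic
delayed termination.  Designated gene classes carry condition-specific
multipliers on these components, so effects such as a recruitment defect in
a perturbed condition are planted with known ground truth and can be
recovered by the downstream profiling and statistics.

Fragment 5' starts are drawn from the resulting mixture (Gaussian components
truncated at ±4 sd, in strand-aware gene coordinates) plus a genome-wide
uniform background; input libraries are background only.  Total fragments
per library follow a multinomial over the mixture weights, so library depth
is exact up to reads clipped away at chromosome ends.

Every stochastic operation draws from its own generator derived from
``(seed, operation name)``, so regenerating one output never perturbs
another.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .models import GeneModel, GeneModelSet, ReadSet
from .phospho import PhosphoTable

__all__ = [
    "Amplitudes",
    "GeneClassSpec",
    "SimulationConfig",
    "generate_genome",
    "simulate_reads",
    "expected_bin_counts",
    "simulate_de_table",
    "simulate_phospho_table",
]

COMPONENTS = ("recruitment", "pause", "body", "tes")
_BASES = np.array(list("ACGT"))

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _rng(seed: int, *names: str) -> np.random.Generator:
    """Operation-local generator derived from the global seed and a label."""
    keys = [seed] + [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(keys)


@dataclass(frozen=True)
class Amplitudes:
    """Expected signal fragments per gene, per occupancy component (at
    multiplier 1; actual counts are rescaled with everything else so that the
    library totals the configured depth)."""

    recruitment: float = 30.0
    pause: float = 120.0
    body: float = 40.0
    tes: float = 20.0

    def __getitem__(self, component: str) -> float:
        return getattr(self, component)


@dataclass
class GeneClassSpec:
    """A designated gene class and the effects planted on it.

    ``multipliers`` maps condition -> component -> multiplier (components
    not listed default to 1).  ``tata_fraction`` of the class receives a
    planted TATA box; ``de_log2fc`` is the expression change planted in the
    mutant-vs-wt contrast (0 = not differentially expressed);
    ``suppressed_by`` maps an RNAi contrast name to the fraction of the
    class whose planted change reverses under that knockdown.
    """

    n_genes: int
    multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    tata_fraction: float = 0.0
    de_log2fc: float = 0.0
    suppressed_by: dict[str, float] = field(default_factory=dict)

    def multiplier(self, condition: str, component: str, class_name: str = "?") -> float:
        if condition not in self.multipliers:
            raise KeyError(
                f"gene class '{class_name}' defines no multipliers for condition '{condition}'"
            )
        m = self.multipliers[condition].get(component, 1.0)
        if m < 0:
            raise ValueError(f"negative multiplier for class '{class_name}'")
        return m


def _default_classes(n_genes: int) -> dict[str, GeneClassSpec]:
    # "coact": genes co-activated by the transcription factor and the
    # phosphatase, with a planted recruitment defect in the perturbed
    # condition B; "bulk": everything else, unchanged between conditions.
    # A quarter of the genes are co-activated (50 of 200 at the default size).
    if n_genes == 0:
        return {}
    n_coact = max(1, round(n_genes / 4))
    return {
        "coact": GeneClassSpec(
            n_genes=n_coact,
            multipliers={"A": {}, "B": {"recruitment": 0.5}},
            tata_fraction=0.8,
            de_log2fc=2.0,
            suppressed_by={"rnai": 0.4},
        ),
        "bulk": GeneClassSpec(
            n_genes=n_genes - n_coact, multipliers={"A": {}, "B": {}}, tata_fraction=0.1
        ),
    }


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic genome and libraries."""

    n_chroms: int = 2
    chrom_length: int = 600_000
    n_genes: int = 200
    min_gene_length: int = 2000
    max_gene_length: int = 4000
    gene_classes: dict[str, GeneClassSpec] | None = None
    amplitudes: Amplitudes = field(default_factory=Amplitudes)
    pause_center: int = 50
    upstream_center: int = -150
    peak_sd: float = 80.0
    tes_shift: dict[str, int] = field(default_factory=dict)
    background_rate: float = 20.0  # fragments per kb of genome
    depth: int = 200_000
    fragment_length: int = 200
    tata_consensus: str = "TATAWAWR"
    de_power: float = 0.9
    de_fdr: float = 0.05
    de_lfc_noise: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_classes is None:
            self.gene_classes = _default_classes(self.n_genes)
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if min(asdict(self.amplitudes).values()) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.min_gene_length <= self.pause_center + 500:
            raise ValueError("min_gene_length must exceed pause_center + 500")
        if self.max_gene_length < self.min_gene_length:
            raise ValueError("max_gene_length below min_gene_length")
        n_classified = sum(c.n_genes for c in self.gene_classes.values())
        if n_classified > self.n_genes:
            raise ValueError("gene class counts exceed n_genes")
        if n_classified < self.n_genes:
            # every gene needs exactly one class: grow/create the catch-all
            extra = self.n_genes - n_classified
            if "bulk" in self.gene_classes:
                self.gene_classes["bulk"].n_genes += extra
            else:
                conds = set()
                for c in self.gene_classes.values():
                    conds.update(c.multipliers)
                self.gene_classes["bulk"] = GeneClassSpec(
                    n_genes=extra, multipliers={c: {} for c in conds} or {"A": {}}
                )

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    @property
    def genome_length(self) -> int:
        return self.n_chroms * self.chrom_length

    @property
    def conditions(self) -> list[str]:
        conds: list[str] = []
        for c in self.gene_classes.values():
            for k in c.multipliers:
                if k not in conds:
                    conds.append(k)
        return conds

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["gene_classes"] = {
            k: GeneClassSpec(**v) for k, v in raw.get("gene_classes", {}).items()
        }
        if "amplitudes" in raw:
            raw["amplitudes"] = Amplitudes(**raw["amplitudes"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# genome generation


def _sample_iupac(consensus: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC[c.upper()])) for c in consensus)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_genome(
    config: SimulationConfig,
) -> tuple[GeneModelSet, dict[str, str], pd.DataFrame]:
    """Generate gene models, random sequence and the truth table.

    Genes are placed without overlap, separated by at least 1 kb, on both
    strands (~50% minus).  Genes flagged ``tata_planted`` carry a concrete
    realization of the configured TATA consensus on the sense strand at
    -30 ± 5 relative to the TSS.  The truth table records every planted
    property per gene.
    """
    rng = _rng(config.seed, "genome")
    sizes = config.chrom_sizes
    chroms = list(sizes)

    n = config.n_genes
    if n == 0:
        seqs = {
            c: "".join(rng.choice(_BASES, size=sizes[c])) for c in chroms
        }
        return GeneModelSet([], sizes), seqs, _empty_truth(config)

    lengths = rng.integers(config.min_gene_length, config.max_gene_length + 1, size=n)
    strands = rng.choice(["+", "-"], size=n)
    # round-robin assignment of genes to chromosomes, then left-to-right
    # placement with >=1 kb gaps and random extra slack
    per_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for i in range(n):
        per_chrom[chroms[i % len(chroms)]].append(i)

    genes: list[GeneModel] = []
    for chrom in chroms:
        idx = per_chrom[chrom]
        if not idx:
            continue
        total = int(lengths[idx].sum()) + 1000 * len(idx)
        slack = sizes[chrom] - total
        if slack < 0:
            raise ValueError(
                f"genome too small: need {total} bp on {chrom} ({sizes[chrom]} available); "
                "increase chrom_length or reduce n_genes"
            )
        extra = rng.multinomial(slack, np.full(len(idx) + 1, 1.0 / (len(idx) + 1)))
        pos = 0
        for j, i in enumerate(idx):
            pos += int(extra[j]) + 1000
            genes.append(GeneModel(f"g{i:04d}", chrom, pos, pos + int(lengths[i]), strands[i]))
            pos += int(lengths[i])

    genes.sort(key=lambda g: (g.chrom, g.start))
    gene_set = GeneModelSet(genes, sizes)

    # class labels in gene-id order
    class_names: list[str] = []
    for name, spec in config.gene_classes.items():
        class_names.extend([name] * spec.n_genes)
    order = rng.permutation(n)
    label_by_id = {f"g{i:04d}": class_names[k] for k, i in enumerate(order)}

    seq_arrays = {c: rng.choice(_BASES, size=sizes[c]) for c in chroms}

    truth_rows = []
    for g in gene_set:
        cls = label_by_id[g.gene_id]
        spec = config.gene_classes[cls]
        truth_rows.append({"gene_id": g.gene_id, "class_name": cls, "chrom": g.chrom,
                           "start": g.start, "end": g.end, "strand": g.strand,
                           "length": g.length})
    truth = pd.DataFrame(truth_rows)

    for cond in config.conditions:
        for comp in COMPONENTS:
            truth[f"mult_{cond}_{comp}"] = [
                config.gene_classes[r.class_name].multiplier(cond, comp, r.class_name)
                for r in truth.itertuples()
            ]

    # plant TATA boxes, class by class, on the sense strand at -30 +/- 5
    truth["tata_planted"] = False
    for name, spec in config.gene_classes.items():
        members = truth.index[truth["class_name"] == name].to_numpy()
        n_tata = int(round(spec.tata_fraction * len(members)))
        chosen = rng.choice(members, size=n_tata, replace=False) if n_tata else []
        for i in chosen:
            g = gene_set[truth.at[i, "gene_id"]]
            motif = _sample_iupac(config.tata_consensus, rng)
            offset = int(rng.integers(-5, 6))
            rel = -30 + offset
            if g.strand == "+":
                s = g.tss + rel
                seq_arrays[g.chrom][s : s + len(motif)] = list(motif)
            else:
                e = g.tss - rel + 1  # sense-strand [rel, rel+len) maps to genomic
                s = e - len(motif)
                seq_arrays[g.chrom][s:e] = list(revcomp(motif))
            truth.at[i, "tata_planted"] = True

    # plant DE effects and RNAi suppression flags
    truth["de_log2fc"] = [
        config.gene_classes[c].de_log2fc for c in truth["class_name"]
    ]
    rnai_names = sorted({r for c in config.gene_classes.values() for r in c.suppressed_by})
    for rnai in rnai_names:
        col = np.zeros(len(truth), dtype=bool)
        for name, spec in config.gene_classes.items():
            frac = spec.suppressed_by.get(rnai, 0.0)
            members = truth.index[
                (truth["class_name"] == name) & (truth["de_log2fc"] != 0)
            ].to_numpy()
            k = int(round(frac * len(members)))
            if k:
                col[rng.choice(members, size=k, replace=False)] = True
        truth[f"suppressed_by_{rnai}"] = col

    seqs = {c: "".join(a) for c, a in seq_arrays.items()}
    return gene_set, seqs, truth


def _empty_truth(config: SimulationConfig) -> pd.DataFrame:
    cols = ["gene_id", "class_name", "chrom", "start", "end", "strand", "length"]
    for cond in config.conditions:
        cols += [f"mult_{cond}_{c}" for c in COMPONENTS]
    cols += ["tata_planted", "de_log2fc"]
    return pd.DataFrame(columns=cols)


# ---------------------------------------------------------------------------
# read simulation


def _component_weights(
    genes: GeneModelSet, config: SimulationConfig, condition: str, truth: pd.DataFrame | None
) -> np.ndarray:
    """(n_genes, 4) mixture weights; uses the truth table when supplied so
    reads honor the exact planted multipliers."""
    if truth is not None:
        t = truth.set_index("gene_id").loc[genes.ids]
        w = np.stack(
            [t[f"mult_{condition}_{c}"].to_numpy() * config.amplitudes[c] for c in COMPONENTS],
            axis=1,
        )
        return w
    raise ValueError("truth table required to resolve gene classes")


def _mixture_probs(
    genes: GeneModelSet, config: SimulationConfig, condition: str, truth: pd.DataFrame | None
) -> np.ndarray:
    """Flat mixture probabilities: one entry per (gene, component) plus a
    final background entry.

    Probabilities are normalized against the *reference* composition (every
    multiplier at 1): a condition that suppresses a component hands that
    component's fragment share to nonspecific background instead of
    rescaling every other gene's coverage.  This keeps planted effects local
    — unaffected genes keep identical expected per-million densities across
    conditions — and the library depth exact.
    """
    w = _component_weights(genes, config, condition, truth)
    amps = np.array([config.amplitudes[c] for c in COMPONENTS])
    bg_weight = config.background_rate * config.genome_length / 1000.0
    ref_total = len(genes) * amps.sum() + bg_weight
    p_signal = w.ravel() / ref_total
    p_bg = 1.0 - p_signal.sum()
    if p_bg < 0:
        raise ValueError(
            "signal weights exceed the depth budget: lower amplitudes/multipliers "
            "or raise background_rate"
        )
    return np.concatenate([p_signal, [p_bg]])


def simulate_reads(
    genes: GeneModelSet,
    config: SimulationConfig,
    condition: str,
    library: str = "ip",
    truth: pd.DataFrame | None = None,
    seed: int | None = None,
) -> ReadSet:
    """Draw one sequencing library under the occupancy mixture model.

    ``library='ip'`` mixes the per-gene signal components with uniform
    background; ``library='input'`` is background only.  Reads are
    ``fragment_length`` long, 5'-anchored at the drawn start, on the gene
    strand (background reads get a random strand), clipped at chromosome
    bounds.
    """
    if library not in ("ip", "input"):
        raise ValueError("library must be 'ip' or 'input'")
    if condition not in config.conditions:
        raise KeyError(f"unknown condition '{condition}'")
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "reads", condition, library)
    flen = config.fragment_length
    sizes = config.chrom_sizes

    if library == "ip" and len(genes):
        probs = _mixture_probs(genes, config, condition, truth)
    else:
        probs = np.array([1.0])
    counts = rng.multinomial(config.depth, probs)

    chroms_out, starts5 = [], []
    strands_out: list[np.ndarray] = []

    shift = config.tes_shift.get(condition, 0)
    if library == "ip" and len(genes):
        per_gene = counts[:-1].reshape(len(genes), len(COMPONENTS))
        for gi, g in enumerate(genes):
            for ci, comp in enumerate(COMPONENTS):
                k = int(per_gene[gi, ci])
                if k == 0:
                    continue
                if comp == "body":
                    rel = rng.integers(500, g.length, size=k)
                else:
                    if comp == "recruitment":
                        center = config.upstream_center
                    elif comp == "pause":
                        center = config.pause_center
                    else:
                        center = (g.length - 1) + shift
                    rel = np.rint(
                        stats.truncnorm.rvs(
                            -4, 4, loc=center, scale=config.peak_sd, size=k, random_state=rng
                        )
                    ).astype(np.int64)
                pos = g.tss + rel if g.strand == "+" else g.tss - rel
                chroms_out.append(np.full(k, g.chrom, dtype=object))
                starts5.append(pos)
                strands_out.append(np.full(k, g.strand, dtype=object))

    n_bg = int(counts[-1])
    if n_bg:
        flat = rng.integers(0, config.genome_length, size=n_bg)
        chrom_idx = flat // config.chrom_length
        pos = flat % config.chrom_length
        names = np.array(list(sizes), dtype=object)
        chroms_out.append(names[chrom_idx])
        starts5.append(pos)
        strands_out.append(rng.choice(np.array(["+", "-"], dtype=object), size=n_bg))

    if chroms_out:
        chrom = np.concatenate(chroms_out)
        p5 = np.concatenate(starts5).astype(np.int64)
        strand = np.concatenate(strands_out)
    else:
        chrom = np.array([], dtype=object)
        p5 = np.array([], dtype=np.int64)
        strand = np.array([], dtype=object)

    minus = strand == "-"
    start = np.where(minus, p5 - flen + 1, p5)
    end = np.where(minus, p5 + 1, p5 + flen)
    lens = np.array([sizes[c] for c in chrom], dtype=np.int64) if len(chrom) else np.array([], dtype=np.int64)
    start = np.clip(start, 0, lens)
    end = np.clip(end, 0, lens)
    keep = start < end

    df = pd.DataFrame(
        {"chrom": chrom[keep], "start": start[keep], "end": end[keep], "strand": strand[keep]}
    )
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return ReadSet(df, sizes, fragment_length=flen)


# ---------------------------------------------------------------------------
# closed-form expectations (oracle for tests and monotonicity checks)


def expected_bin_counts(
    genes: GeneModelSet,
    config: SimulationConfig,
    condition: str,
    library: str,
    chrom: str,
    bin_starts: np.ndarray,
    bin_ends: np.ndarray,
    truth: pd.DataFrame | None = None,
) -> np.ndarray:
    """Expected number of fragments overlapping each genomic bin.

    Closed-form mixture expectation (continuous CDF approximation of the
    integer rounding), used as the independent oracle against empirical bin
    counts and for noise-free monotonicity checks.  Chromosome-edge clipping
    is ignored, so use away from chromosome ends.
    """
    flen = config.fragment_length
    bin_starts = np.asarray(bin_starts, dtype=np.int64)
    bin_ends = np.asarray(bin_ends, dtype=np.int64)
    out = np.zeros(len(bin_starts), dtype=float)

    if library == "ip" and len(genes):
        probs = _mixture_probs(genes, config, condition, truth)
        w = probs[:-1].reshape(len(genes), len(COMPONENTS)) * config.depth
        bg_count = probs[-1] * config.depth
    else:
        w = None
        bg_count = float(config.depth)

    # background: a fragment overlaps [s, e) iff its 5' start falls in a
    # window of (e - s) + flen - 1 positions, regardless of strand
    n_pos = (bin_ends - bin_starts) + flen - 1
    out += bg_count * n_pos / config.genome_length

    if w is None:
        return out

    shift = config.tes_shift.get(condition, 0)
    sd = config.peak_sd
    margin = flen + 4 * sd + abs(shift) + 1
    bmin, bmax = int(bin_starts.min()), int(bin_ends.max())
    for gi, g in enumerate(genes):
        if g.chrom != chrom:
            continue
        if g.end + margin <= bmin or g.start - margin >= bmax:
            continue
        # genomic window of 5' starts whose fragment overlaps each bin,
        # converted to transcription-direction relative coordinates
        if g.strand == "+":
            lo_r = (bin_starts - flen + 1 - g.tss).astype(float)
            hi_r = (bin_ends - g.tss).astype(float)
        else:
            lo_r = (g.tss - (bin_ends + flen - 1) + 1).astype(float)
            hi_r = (g.tss - bin_starts + 1).astype(float)
        for ci, comp in enumerate(COMPONENTS):
            weight = w[gi, ci]
            if weight == 0:
                continue
            if comp == "body":
                mass = np.clip(
                    np.minimum(hi_r, g.length) - np.maximum(lo_r, 500), 0.0, None
                ) / max(g.length - 500, 1)
            else:
                center = {
                    "recruitment": config.upstream_center,
                    "pause": config.pause_center,
                    "tes": (g.length - 1) + shift,
                }[comp]
                if hi_r.max() < center - 4 * sd - 1 or lo_r.min() > center + 4 * sd + 1:
                    continue
                upper = stats.truncnorm.cdf((hi_r - 0.5 - center) / sd, -4, 4)
                lower = stats.truncnorm.cdf((lo_r - 0.5 - center) / sd, -4, 4)
                mass = np.maximum(upper - lower, 0.0)
            out += weight * mass
    return out


# ---------------------------------------------------------------------------
# expression and phosphopeptide tables


def simulate_de_table(
    truth: pd.DataFrame, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Gene-level differential-expression table with planted effects.

    Contrasts: ``mutant_vs_wt`` plus one ``<rnai>_vs_control`` per RNAi named
    in the truth table.  Planted genes reach significance with probability
    ``config.de_power`` (q drawn below ``de_fdr``); everything else gets a
    uniform q.  Suppressed genes show a significant change of opposite sign
    under the RNAi.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "de_table")
    n = len(truth)
    lfc_true = truth["de_log2fc"].to_numpy(dtype=float)
    planted = lfc_true != 0

    out = pd.DataFrame({"gene_id": truth["gene_id"].to_numpy()})
    out["log2fc_mutant_vs_wt"] = lfc_true + rng.normal(0, config.de_lfc_noise, n)
    # keep the observed sign consistent with the planted direction
    out.loc[planted, "log2fc_mutant_vs_wt"] = np.sign(lfc_true[planted]) * np.abs(
        out.loc[planted, "log2fc_mutant_vs_wt"]
    )
    q = rng.uniform(0, 1, n)
    powered = planted & (rng.uniform(0, 1, n) < config.de_power)
    q[powered] = rng.uniform(0, config.de_fdr, powered.sum())
    q[planted & ~powered] = rng.uniform(config.de_fdr, 1, (planted & ~powered).sum())
    out["q_mutant_vs_wt"] = q

    rnai_cols = [c for c in truth.columns if c.startswith("suppressed_by_")]
    for col in rnai_cols:
        rnai = col[len("suppressed_by_") :]
        supp = truth[col].to_numpy(dtype=bool)
        lfc = rng.normal(0, config.de_lfc_noise, n)
        lfc[supp] = -lfc_true[supp] + rng.normal(0, config.de_lfc_noise, supp.sum())
        lfc[supp] = -np.sign(lfc_true[supp]) * np.abs(lfc[supp])
        qr = rng.uniform(0, 1, n)
        powered_r = supp & (rng.uniform(0, 1, n) < config.de_power)
        qr[powered_r] = rng.uniform(0, config.de_fdr, powered_r.sum())
        qr[supp & ~powered_r] = rng.uniform(config.de_fdr, 1, (supp & ~powered_r).sum())
        out[f"log2fc_{rnai}_vs_control"] = lfc
        out[f"q_{rnai}_vs_control"] = qr
    return out


def simulate_phospho_table(
    n_peptides: int = 2000,
    n_planted: int = 20,
    n_replicates: int = 3,
    effect_fold: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    flagship_protein: str = "SPT5L",
    flagship_fold: float | None = None,
) -> tuple[PhosphoTable, pd.DataFrame]:
    """Phosphopeptide intensity table with planted increases.

    Intensities are log-normal (log2 base ~ N(20, 2), replicate noise
    ``noise_sd`` on the log2 scale).  ``n_planted`` peptides gain
    ``log2(effect_fold)`` in the treatment replicates.  One flagship protein
    (two peptides, a stronger ``flagship_fold`` effect, defaulting to
    ``effect_fold**2``) mimics the top-ranked substrate: it carries both the
    reporter-screen and the co-purification evidence flags in the truth.

    Returns the table and a truth frame (one row per peptide) with
    ``planted``, protein-level ``reporter_hit`` and ``copurified`` columns.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if n_planted + 2 > n_peptides:
        raise ValueError("not enough peptides for the planted set")
    rng = _rng(seed, "phospho_table")
    if flagship_fold is None:
        flagship_fold = effect_fold**2

    pep_ids = [f"pep{i:05d}" for i in range(n_peptides)]
    # flagship protein owns the first two peptides; each remaining planted
    # peptide sits on its own protein; background peptides pair up 2/protein
    prot_ids = []
    for i in range(n_peptides):
        if i < 2:
            prot_ids.append(flagship_protein)
        elif i < 2 + n_planted:
            prot_ids.append(f"prot{i:05d}")
        else:
            prot_ids.append(f"prot{2 + n_planted + (i - 2 - n_planted) // 2:05d}")
    sites = [f"S{int(s)}" for s in rng.integers(1, 999, size=n_peptides)]

    base = rng.normal(20.0, 2.0, n_peptides)
    ctrl = base[:, None] + rng.normal(0, noise_sd, (n_peptides, n_replicates))
    trt = base[:, None] + rng.normal(0, noise_sd, (n_peptides, n_replicates))

    planted = np.zeros(n_peptides, dtype=bool)
    folds = np.ones(n_peptides)
    if effect_fold != 1.0:
        planted[: 2 + n_planted] = True
        folds[:2] = flagship_fold
        folds[2 : 2 + n_planted] = effect_fold
        trt += np.log2(folds)[:, None]

    data = {"peptide_id": pep_ids, "protein_id": prot_ids, "site": sites}
    ctrl_cols = [f"control_{r + 1}" for r in range(n_replicates)]
    trt_cols = [f"treatment_{r + 1}" for r in range(n_replicates)]
    for j, c in enumerate(ctrl_cols):
        data[c] = 2.0 ** ctrl[:, j]
    for j, c in enumerate(trt_cols):
        data[c] = 2.0 ** trt[:, j]
    table = PhosphoTable(pd.DataFrame(data), ctrl_cols, trt_cols)

    planted_prots = set(np.array(prot_ids)[planted])
    reporter = {flagship_protein}
    others = sorted(planted_prots - {flagship_protein})
    reporter.update(others[: len(others) // 2])
    bg_prots = sorted(set(prot_ids) - planted_prots)
    reporter.update(rng.choice(bg_prots, size=min(5, len(bg_prots)), replace=False))
    copurified = {flagship_protein} | set(others[:2])

    truth = pd.DataFrame(
        {
            "peptide_id": pep_ids,
            "protein_id": prot_ids,
            "planted": planted,
            "effect_fold": np.where(planted, folds, 1.0),
            "reporter_hit": [p in reporter for p in prot_ids],
            "copurified": [p in copurified for p in prot_ids],
        }
    )
    return table, truth
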