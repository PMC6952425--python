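"""End-to-end synthetic experiments and calibration runs.

These compose the simulator with the profiling and statistics stages into
the standard in-silico experiments: recruitment-defect recovery at the TSS,
pausing-index neutrality, termination-shift detection at the TES, and
empirical null calibration of the window test and the peptide test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .coverage import AnchorSpec, EnrichmentProfile, bin_density, fold_enrichment
from .metagene import compare_window, metagene
from .models import GeneModelSet
from .pausing import PausingResult, normalized_ratio_track, pausing_indices
from .phospho import differential_phospho, rank_candidates
from .simulate import SimulationConfig, generate_genome, simulate_phospho_table, simulate_reads

__all__ = [
    "chip_profile",
    "OccupancyExperiment",
    "run_occupancy_experiment",
    "tes_shift_experiment",
    "compare_window_null_rate",
    "phospho_null_rate",
    "phospho_recovery",
]


def chip_profile(
    genes: GeneModelSet,
    config: SimulationConfig,
    truth: pd.DataFrame,
    condition: str,
    anchor: AnchorSpec,
    seed: int,
    pseudocount: float = 1.0,
) -> EnrichmentProfile:
    """Simulate one IP + input library pair and profile it around the anchor."""
    ip = simulate_reads(genes, config, condition, "ip", truth, seed=seed)
    inp = simulate_reads(genes, config, condition, "input", truth, seed=seed)
    dip = bin_density(ip, genes, anchor, library="ip")
    din = bin_density(inp, genes, anchor, library="input")
    return fold_enrichment(dip, din, pseudocount=pseudocount)


@dataclass
class OccupancyExperiment:
    """One simulated two-condition Pol II ChIP experiment, profiled and
    tested on the perturbed gene class and on an unaffected control set."""

    genes: GeneModelSet
    truth: pd.DataFrame
    affected_set: list[str]
    control_set: list[str]
    p_affected: float
    p_control: float
    pausing_a: PausingResult
    pausing_b: PausingResult
    profile_a: EnrichmentProfile
    profile_b: EnrichmentProfile


def run_occupancy_experiment(
    config: SimulationConfig,
    seed: int,
    conditions: tuple[str, str] = ("A", "B"),
    affected_class: str = "coact",
    control_class: str = "bulk",
    control_size: int = 50,
    window: tuple[int, int] = (-600, 600),
) -> OccupancyExperiment:
    """Simulate both conditions, compare TSS windows, compute pausing indices."""
    cfg = replace(config, seed=seed)
    genes, _, truth = generate_genome(cfg)
    anchor = AnchorSpec("tss", flank=600, bin_size=60)
    affected = truth.loc[truth["class_name"] == affected_class, "gene_id"].tolist()
    control = truth.loc[truth["class_name"] == control_class, "gene_id"].tolist()[:control_size]

    prof = {}
    tracks = {}
    for i, cond in enumerate(conditions):
        ip = simulate_reads(genes, cfg, cond, "ip", truth, seed=seed)
        inp = simulate_reads(genes, cfg, cond, "input", truth, seed=seed)
        dip = bin_density(ip, genes, anchor, library="ip")
        din = bin_density(inp, genes, anchor, library="input")
        prof[cond] = fold_enrichment(dip, din)
        tracks[cond] = normalized_ratio_track(ip, inp, bin_size=60, extend=None)

    a, b = conditions
    p_aff = compare_window(prof[a], prof[b], affected, window).p
    p_ctl = compare_window(prof[a], prof[b], control, window).p
    paus_a = pausing_indices(tracks[a], genes, affected)
    paus_b = pausing_indices(tracks[b], genes, affected)
    return OccupancyExperiment(
        genes, truth, affected, control, p_aff, p_ctl, paus_a, paus_b, prof[a], prof[b]
    )


def tes_shift_experiment(
    config: SimulationConfig,
    seed: int,
    shift: int = 200,
    conditions: tuple[str, str] = ("A", "B"),
    gene_class: str = "coact",
) -> tuple[int, int]:
    """Measure how far the TES-anchored metagene peak moves under a planted
    downstream termination shift.

    Returns ``(peak_label_a, peak_label_b)`` — the bin left edges of the
    set-mean enrichment maxima in the two conditions.
    """
    cfg = replace(config, seed=seed, tes_shift={conditions[1]: shift})
    genes, _, truth = generate_genome(cfg)
    anchor = AnchorSpec("tes", flank=600, bin_size=60)
    gene_set = truth.loc[truth["class_name"] == gene_class, "gene_id"].tolist()
    peaks = []
    for cond in conditions:
        enr = chip_profile(genes, cfg, truth, cond, anchor, seed=seed)
        peaks.append(metagene(enr, gene_set).peak_label())
    return peaks[0], peaks[1]


def compare_window_null_rate(
    config: SimulationConfig,
    n_reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    gene_class: str = "coact",
    window: tuple[int, int] = (-600, 600),
    condition: str = "A",
) -> float:
    """Empirical type-I error of the window test under the simulation null.

    Each replicate draws two independent libraries of the *same* condition
    and runs the paired window test; the returned fraction of p < alpha
    measures how much the bin-as-observation assumption inflates (or not)
    the nominal level.
    """
    cfg = replace(config, seed=seed)
    genes, _, truth = generate_genome(cfg)
    anchor = AnchorSpec("tss", flank=600, bin_size=60)
    gene_set = truth.loc[truth["class_name"] == gene_class, "gene_id"].tolist()
    rej = 0
    for r in range(n_reps):
        e1 = chip_profile(genes, cfg, truth, condition, anchor, seed=seed + 2 * r + 1)
        e2 = chip_profile(genes, cfg, truth, condition, anchor, seed=seed + 2 * r + 2)
        if compare_window(e1, e2, gene_set, window).p < alpha:
            rej += 1
    return rej / n_reps


def phospho_null_rate(
    n_reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    n_peptides: int = 500,
    n_replicates: int = 3,
    noise_sd: float = 0.25,
) -> float:
    """Per-peptide raw-p rejection rate of the moderated test with no
    planted effects (should sit near the nominal alpha)."""
    rates = []
    for r in range(n_reps):
        table, _ = simulate_phospho_table(
            n_peptides=n_peptides,
            n_planted=0,
            n_replicates=n_replicates,
            effect_fold=1.0,
            noise_sd=noise_sd,
            seed=seed + r,
        )
        res = differential_phospho(table)
        rates.append(float((res.table["p"] < alpha).mean()))
    return float(np.mean(rates))


def phospho_recovery(
    seed: int,
    n_seeds: int = 20,
    n_peptides: int = 2000,
    n_planted: int = 20,
    n_replicates: int = 3,
    effect_fold: float = 2.0,
    noise_sd: float = 0.25,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Recall / empirical FDR of planted phosphopeptides and the rank of the
    flagship candidate, averaged over ``n_seeds`` simulations."""
    recalls, fdrs, top_ranked = [], [], []
    for s in range(n_seeds):
        table, truth = simulate_phospho_table(
            n_peptides=n_peptides,
            n_planted=n_planted,
            n_replicates=n_replicates,
            effect_fold=effect_fold,
            noise_sd=noise_sd,
            seed=seed + s,
        )
        res = differential_phospho(table, alpha=alpha)
        called = res.table["increased"].to_numpy()
        planted = truth["planted"].to_numpy()
        recalls.append(called[planted].mean() if planted.any() else 0.0)
        n_called = called.sum()
        fdrs.append((called & ~planted).sum() / n_called if n_called else 0.0)
        reporter = set(truth.loc[truth["reporter_hit"], "protein_id"])
        copur = set(truth.loc[truth["copurified"], "protein_id"])
        ranked = rank_candidates(res, reporter, copur)
        flagship = truth.loc[truth["effect_fold"].idxmax(), "protein_id"]
        top = (
            not ranked.empty
            and ranked.iloc[0]["protein_id"] == flagship
            and bool(ranked.iloc[0]["copurified"])
        )
        top_ranked.append(float(top))
    return {
        "recall": float(np.mean(recalls)),
        "fdr": float(np.mean(fdrs)),
        "top_candidate_rate": float(np.mean(top_ranked)),
    }
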