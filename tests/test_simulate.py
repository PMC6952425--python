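import numpy as np
import pytest
from scipy import stats

from polprof import (
    Amplitudes,
    GeneClassSpec,
    SimulationConfig,
    expected_bin_counts,
    generate_genome,
    simulate_de_table,
    simulate_phospho_table,
    simulate_reads,
)
from polprof.genesets import scan_consensus
from polprof.simulate import revcomp


class TestConfigValidation:
    def test_rejects_short_genes(self):
        with pytest.raises(ValueError, match="min_gene_length"):
            SimulationConfig(min_gene_length=500)

    def test_rejects_overfull_classes(self):
        with pytest.raises(ValueError, match="exceed"):
            SimulationConfig(
                n_genes=10, gene_classes={"a": GeneClassSpec(20, {"A": {}})}
            )

    def test_fills_catch_all_class(self):
        cfg = SimulationConfig(
            n_genes=30,
            chrom_length=200_000,
            gene_classes={"a": GeneClassSpec(10, {"A": {}})},
        )
        assert sum(c.n_genes for c in cfg.gene_classes.values()) == 30

    def test_yaml_roundtrip(self, tmp_path, small_config):
        path = tmp_path / "cfg.yaml"
        small_config.to_yaml(path)
        again = SimulationConfig.from_yaml(path)
        assert again == small_config


class TestGenerateGenome:
    def test_empty_genome(self):
        cfg = SimulationConfig(n_genes=0, n_chroms=1, chrom_length=5000, gene_classes={})
        genes, seqs, truth = generate_genome(cfg)
        assert len(genes) == 0
        assert len(seqs["chr1"]) == 5000
        assert truth.empty

    def test_placement_invariants(self):
        cfg = SimulationConfig(n_chroms=1, chrom_length=1_000_000, n_genes=100, seed=3)
        genes, seqs, truth = generate_genome(cfg)
        assert len(genes) == 100
        frame = genes.to_frame().sort_values("start")
        assert (frame["end"] - frame["start"] >= 2000).all()
        gaps = frame["start"].to_numpy()[1:] - frame["end"].to_numpy()[:-1]
        assert (gaps >= 1000).all()
        strands = frame["strand"].value_counts()
        assert strands.min() >= 25  # both strands well represented
        assert set(truth["class_name"]) == set(cfg.gene_classes)
        assert len(truth) == 100

    def test_too_small_genome_raises(self):
        cfg = SimulationConfig(n_chroms=1, chrom_length=30_000, n_genes=50)
        with pytest.raises(ValueError, match="genome too small"):
            generate_genome(cfg)

    def test_determinism(self, small_config):
        a = generate_genome(small_config)
        b = generate_genome(small_config)
        assert a[0].to_frame().equals(b[0].to_frame())
        assert a[1] == b[1]
        assert a[2].equals(b[2])

    def test_tata_planted_at_minus30(self, small_config):
        genes, seqs, truth = generate_genome(small_config)
        consensus = small_config.tata_consensus
        for row in truth.itertuples():
            g = genes[row.gene_id]
            s, e = g.rel_interval_to_genomic(-30 - 5, -30 + 5 + len(consensus))
            window = seqs[g.chrom][s:e]
            if g.strand == "-":
                window = revcomp(window)
            if row.tata_planted:
                assert scan_consensus(window, consensus), row.gene_id
        n_expected = sum(
            round(spec.tata_fraction * (truth["class_name"] == name).sum())
            for name, spec in small_config.gene_classes.items()
        )
        assert truth["tata_planted"].sum() == n_expected


class TestSimulateReads:
    def test_depth_conservation(self, small_config):
        genes, _, truth = generate_genome(small_config)
        for lib in ("ip", "input"):
            reads = simulate_reads(genes, small_config, "A", lib, truth)
            # only whole-read clipping at chromosome ends may lose records
            assert small_config.depth - 50 <= len(reads) <= small_config.depth

    def test_determinism(self, small_config):
        genes, _, truth = generate_genome(small_config)
        r1 = simulate_reads(genes, small_config, "A", "ip", truth)
        r2 = simulate_reads(genes, small_config, "A", "ip", truth)
        assert r1.data.equals(r2.data)

    def test_unknown_condition_named_in_error(self, small_config):
        genes, _, truth = generate_genome(small_config)
        with pytest.raises(KeyError, match="Z"):
            simulate_reads(genes, small_config, "Z", "ip", truth)

    def test_degenerate_mixture_is_uniform_background(self):
        cfg = SimulationConfig(
            n_chroms=1,
            chrom_length=100_000,
            n_genes=5,
            amplitudes=Amplitudes(0, 0, 0, 0),
            depth=50_000,
            seed=2,
        )
        genes, _, truth = generate_genome(cfg)
        reads = simulate_reads(genes, cfg, "A", "ip", truth)
        # coarse uniformity: chi-square over 20 position bins of 5' starts
        starts = np.where(
            reads.data["strand"] == "+", reads.data["start"], reads.data["end"] - 1
        )
        counts, _ = np.histogram(starts, bins=20, range=(0, 100_000))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_mixture_expectation_recruitment_halved(self):
        """Planted multiplier 0.5 halves the expected upstream-window reads;
        empirical counts stay within 3 sigma of the closed-form expectation."""
        cfg = SimulationConfig(seed=5)
        genes, _, truth = generate_genome(cfg)
        coact = truth[truth["class_name"] == "coact"]
        assert len(coact) >= 50
        sd = cfg.peak_sd
        window = {}
        for cond in ("A", "B"):
            reads = simulate_reads(genes, cfg, cond, "ip", truth)
            idx = reads.sorted_index()
            total = expected = 0.0
            for gid in coact["gene_id"]:
                g = genes[gid]
                lo, hi = g.rel_interval_to_genomic(
                    int(cfg.upstream_center - 2 * sd), int(cfg.upstream_center + 2 * sd)
                )
                starts, ends = idx[g.chrom]
                n = np.searchsorted(starts, hi, "left") - np.searchsorted(
                    ends, lo, "right"
                )
                total += n
                expected += expected_bin_counts(
                    genes, cfg, cond, "ip", g.chrom, np.array([lo]), np.array([hi]), truth
                )[0]
            window[cond] = (total, expected)
        for cond, (total, expected) in window.items():
            assert abs(total - expected) < 3 * np.sqrt(expected), cond
        # planted direction: B's upstream occupancy is clearly lower (the
        # drop is diluted by pause/background fragments sharing the window)
        assert window["B"][1] < 0.9 * window["A"][1]
        assert window["B"][0] < 0.9 * window["A"][0]

    def test_strand_symmetry(self):
        """Mirroring genes and strands mirrors the anchor-relative read-start
        distribution (chi-square homogeneity p > 0.01 at depth 1e5)."""
        cfg = SimulationConfig(
            n_chroms=1, chrom_length=400_000, n_genes=60, depth=100_000, seed=9
        )
        genes, _, truth = generate_genome(cfg)
        mirrored = genes.mirrored()
        truth_m = truth.copy()
        n = cfg.chrom_length
        truth_m["start"], truth_m["end"] = n - truth["end"], n - truth["start"]
        truth_m["strand"] = np.where(truth["strand"] == "+", "-", "+")

        def rel_hist(gene_set, reads):
            idx = {g.gene_id: g for g in gene_set}
            rel = []
            p5 = np.where(reads.data["strand"] == "+", reads.data["start"], reads.data["end"] - 1)
            # assign each read to the nearest gene TSS, transcription-direction
            for gid, g in idx.items():
                r = (p5 - g.tss) * (1 if g.strand == "+" else -1)
                rel.append(r[(r > -600) & (r < 600)])
            return np.histogram(np.concatenate(rel), bins=24, range=(-600, 600))[0]

        h1 = rel_hist(genes, simulate_reads(genes, cfg, "A", "ip", truth, seed=1))
        h2 = rel_hist(mirrored, simulate_reads(mirrored, cfg, "A", "ip", truth_m, seed=2))
        table = np.vstack([h1, h2])
        assert stats.chi2_contingency(table).pvalue > 0.01


class TestOmicsTables:
    def test_de_table_planted_effects(self, small_config):
        genes, _, truth = generate_genome(small_config)
        de = simulate_de_table(truth, small_config)
        merged = de.merge(truth[["gene_id", "de_log2fc"]], on="gene_id")
        planted = merged[merged["de_log2fc"] > 0]
        background = merged[merged["de_log2fc"] == 0]
        assert (np.sign(planted["log2fc_mutant_vs_wt"]) == 1).all()
        assert planted["q_mutant_vs_wt"].median() < background["q_mutant_vs_wt"].median()
        assert simulate_de_table(truth, small_config).equals(de)

    def test_phospho_no_effect_means_nothing_planted(self):
        _, truth = simulate_phospho_table(n_peptides=50, n_planted=5, effect_fold=1.0, seed=1)
        assert truth["planted"].sum() == 0

    def test_phospho_requires_replicates(self):
        with pytest.raises(ValueError, match="n_replicates"):
            simulate_phospho_table(n_peptides=10, n_replicates=1)

    def test_phospho_determinism(self):
        t1, tr1 = simulate_phospho_table(n_peptides=100, seed=4)
        t2, tr2 = simulate_phospho_table(n_peptides=100, seed=4)
        assert t1.data.equals(t2.data)
        assert tr1.equals(tr2)
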