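import itertools
import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polprof import (
    GeneModel,
    GeneModelSet,
    MotifSpec,
    classify_regulated,
    generate_genome,
    motif_enrichment,
    overlap_test,
    suppression_fraction,
)
from polprof.genesets import scan_consensus
from polprof.simulate import IUPAC, SimulationConfig


def _toy_table():
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(6)],
            "log2fc_mutant_vs_wt": [2.0, -1.5, 0.5, 3.0, -0.2, 1.0],
            "q_mutant_vs_wt": [0.01, 0.02, 0.5, 0.001, 0.04, 0.2],
            "log2fc_rnai": [-1.8, 1.2, 0.1, -0.5, 0.3, -2.0],
            "q_rnai": [0.01, 0.03, 0.9, 0.2, 0.01, 0.04],
        }
    )


class TestClassifyRegulated:
    def test_toy_table_exact_membership(self):
        sets = classify_regulated(_toy_table(), fdr=0.05, rnai_contrasts=["rnai"])
        assert sets["up_in_mutant"] == {"g0", "g3"}
        assert sets["down_in_mutant"] == {"g1", "g4"}
        assert sets["activated_by_rnai"] == {"g0", "g5"}
        assert sets["repressed_by_rnai"] == {"g1", "g4"}

    def test_all_insignificant_gives_empty_sets(self):
        table = _toy_table()
        table["q_mutant_vs_wt"] = 1.0
        sets = classify_regulated(table)
        assert sets["up_in_mutant"] == set() and sets["down_in_mutant"] == set()

    def test_missing_contrast_named(self):
        with pytest.raises(KeyError, match="q_nope"):
            classify_regulated(_toy_table(), rnai_contrasts=["nope"])

    def test_recovers_planted_classes(self):
        from polprof import simulate_de_table

        cfg = SimulationConfig(seed=8)
        genes, _, truth = generate_genome(cfg)
        de = simulate_de_table(truth, cfg)
        sets = classify_regulated(de, fdr=0.05)
        planted = set(truth.loc[truth["de_log2fc"] > 0, "gene_id"])
        recovered = sets["up_in_mutant"] & planted
        assert len(recovered) >= 0.8 * len(planted)  # configured power 0.9
        false_calls = sets["up_in_mutant"] - planted
        assert len(false_calls) <= 0.10 * (len(truth) - len(planted))


class TestSuppressionFraction:
    def test_no_rnai_effect_gives_zero(self):
        table = _toy_table()
        table["q_rnai"] = 1.0
        assert suppression_fraction({"g0", "g3"}, table, "rnai") == 0.0

    def test_full_reversal_gives_one(self):
        table = _toy_table()
        table.loc[table["gene_id"].isin(["g0", "g3"]), "q_rnai"] = 0.001
        table.loc[table["gene_id"].isin(["g0", "g3"]), "log2fc_rnai"] = -1.0
        assert suppression_fraction({"g0", "g3"}, table, "rnai") == 1.0

    def test_complement_identity(self):
        table = _toy_table()
        frac = suppression_fraction({"g0", "g3"}, table, "rnai")
        q, fc = table["q_rnai"], table["log2fc_rnai"]
        sub = table["gene_id"].isin({"g0", "g3"})
        unsuppressed = (~((q < 0.05) & (fc < 0)) & sub).sum() / sub.sum()
        assert frac == pytest.approx(1.0 - unsuppressed)

    def test_recovers_planted_reversal_fraction(self):
        from polprof import simulate_de_table

        fracs = []
        for seed in range(5):
            cfg = SimulationConfig(seed=20 + seed)
            _, _, truth = generate_genome(cfg)
            de = simulate_de_table(truth, cfg)
            planted_up = set(truth.loc[truth["de_log2fc"] > 0, "gene_id"])
            fracs.append(
                suppression_fraction(planted_up, de, "rnai_vs_control", direction="up")
            )
        # 40% of the class carries a reversal, recovered at power 0.9
        assert np.mean(fracs) == pytest.approx(0.4 * 0.9, abs=0.07)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            suppression_fraction(set(), _toy_table(), "rnai")


class TestOverlapTest:
    def test_disjoint_sets_give_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        res = overlap_test({"g0", "g1"}, {"g2", "g3"}, universe)
        assert res.p == 1.0

    def test_hand_computed_case(self):
        # N=10, |A|=4, |B|=5, overlap=4: p = C(4,4) C(6,1) / C(10,5) = 6/252
        universe = [f"g{i}" for i in range(10)]
        a = universe[:4]
        b = universe[:4] + [universe[9]]
        res = overlap_test(a, b, universe)
        assert res.p == pytest.approx(6 / 252, rel=1e-12)

    def test_symmetry_and_monotonicity(self):
        universe = [f"g{i}" for i in range(12)]
        a = set(universe[:5])
        b = set(universe[3:9])
        assert overlap_test(a, b, universe).p == pytest.approx(
            overlap_test(b, a, universe).p, rel=1e-12
        )
        # p non-increasing as overlap grows at fixed margins
        p_prev = 1.1
        for k in range(0, 6):
            bk = set(universe[:k]) | set(universe[5 : 5 + (5 - k)])
            p = overlap_test(a, bk, universe).p
            assert p <= p_prev + 1e-12
            p_prev = p

    def test_enumeration_oracle_small_universes(self):
        """Exact equality with full enumeration over all draws, for a grid of
        configurations with universe size <= 8 (exhaustive in k)."""
        for N in (1, 2, 5, 8):
            universe = list(range(N))
            for K in range(N + 1):
                a = set(universe[:K])
                for n in range(N + 1):
                    counts = {}
                    for comb in itertools.combinations(universe, n):
                        k = len(a & set(comb))
                        counts[k] = counts.get(k, 0) + 1
                    total = sum(counts.values())
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        b = set(universe[:k]) | set(universe[K : K + n - k])
                        assert len(b) == n and len(a & b) == k
                        want = sum(v for kk, v in counts.items() if kk >= k) / total
                        got = overlap_test(
                            [str(x) for x in a], [str(x) for x in b], [str(x) for x in universe]
                        ).p
                        assert got == pytest.approx(want, rel=1e-12), (N, K, n, k)

    def test_ids_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="x9"):
            overlap_test({"g1", "x9"}, {"g1"}, {"g1", "g2"})


class TestMotifs:
    def test_hand_written_promoter_hit(self):
        # 30 bp upstream window carrying TATAAAAG at -30
        seq = "C" * 70 + "TATAAAAG" + "C" * 22 + "A" * 100
        genes = GeneModelSet([GeneModel("g", "chr1", 100, 180, "+")], {"chr1": len(seq)})
        spec = MotifSpec("TATA", "TATAWAWR", (-100, 0))
        res = motif_enrichment({"chr1": seq}, genes, ["g"], [], spec)
        assert res.set_hits == 1

    def test_minus_strand_promoter_extraction(self):
        # minus-strand gene: promoter is genomically right of the TSS,
        # motif planted as reverse complement on the genome
        motif = "TATAAAAG"
        left = "C" * 150
        promoter = "G" * 20 + "TATAAAAG"[::-1].translate(str.maketrans("ACGT", "TGCA")) + "G" * 72
        seq = left + promoter + "C" * 100
        genes = GeneModelSet([GeneModel("g", "chr1", 50, 150, "-")], {"chr1": len(seq)})
        res = motif_enrichment(
            {"chr1": seq}, genes, ["g"], [], MotifSpec("TATA", motif, (-100, 0))
        )
        assert res.set_hits == 1

    def test_saturated_background_gives_p_one(self):
        seq = "A" * 400
        genes = GeneModelSet(
            [
                GeneModel("g1", "chr1", 150, 250, "+"),
                GeneModel("g2", "chr1", 260, 390, "+"),
            ],
            {"chr1": 400},
        )
        res = motif_enrichment(
            {"chr1": seq}, genes, ["g1"], ["g2"], MotifSpec("polyA", "A", (-50, 0))
        )
        assert res.set_hits == 1 and res.background_hits == 1
        assert res.p == 1.0

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=40))
    def test_scanner_agrees_with_regex_oracle(self, seq):
        consensus = "TATAWAWR"
        pattern = re.compile("".join(f"[{IUPAC[c]}]" for c in consensus))
        assert scan_consensus(seq, consensus) == bool(pattern.search(seq))

    def test_window_off_sequence_is_skipped(self):
        genes = GeneModelSet([GeneModel("g", "chr1", 10, 200, "+")], {"chr1": 300})
        res = motif_enrichment(
            {"chr1": "A" * 300}, genes, ["g"], [], MotifSpec("m", "A", (-100, 0))
        )
        assert res.n_skipped == 1 and res.set_n == 0 and res.p == 1.0

    def test_planted_tata_enrichment_recovered(self):
        """80% planted in the co-activated class vs 10% background yields a
        strongly significant hypergeometric enrichment."""
        cfg = SimulationConfig(seed=17)
        genes, seqs, truth = generate_genome(cfg)
        coact = truth.loc[truth["class_name"] == "coact", "gene_id"].tolist()
        bulk = truth.loc[truth["class_name"] == "bulk", "gene_id"].tolist()
        res = motif_enrichment(seqs, genes, coact, bulk)
        assert res.set_hits >= 0.7 * res.set_n
        assert res.p < 1e-3
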