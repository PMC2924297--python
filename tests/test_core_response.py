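import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

import synechonet as sn
from synechonet.errors import UndefinedAgreementError

from conftest import state_frame


class TestRegulationFrequency:
    def test_all_zero_row_has_fraction_zero(self):
        m = state_frame(["g1"], [f"e{i}" for i in range(68)], np.zeros((1, 68)))
        [rf] = sn.regulation_frequency(m)
        assert rf.fraction == 0.0

    def test_fraction_arithmetic(self):
        row = np.zeros(68)
        row[:35] = 1
        m = state_frame(["g1"], [f"e{i}" for i in range(68)], row.reshape(1, -1))
        [rf] = sn.regulation_frequency(m)
        assert rf.n_regulated == 35 and rf.n_observed == 68
        assert rf.fraction == pytest.approx(35 / 68)

    def test_missing_cells_excluded_from_denominator(self):
        row = np.full(68, np.nan)
        row[:10] = 1
        row[10:20] = 0
        m = state_frame(["g1"], [f"e{i}" for i in range(68)], row.reshape(1, -1))
        [rf] = sn.regulation_frequency(m)
        assert (rf.n_regulated, rf.n_observed, rf.fraction) == (10, 20, 0.5)

    def test_unobserved_gene_reported_with_undefined_fraction(self):
        m = state_frame(["g1"], ["e1"], [[np.nan]])
        [rf] = sn.regulation_frequency(m)
        assert rf.n_observed == 0 and rf.fraction is None


class TestIdentifyCtr:
    def test_strict_majority_rule(self):
        rows = np.zeros((2, 68))
        rows[0, :35] = 1  # 35/68 > 0.5
        rows[1, :34] = 1  # 34/68 == 0.5, excluded under strict ">"
        m = state_frame(["in", "out"], [f"e{i}" for i in range(68)], rows)
        assert sn.identify_ctr(m) == ["in"]
        assert sn.identify_ctr(m, strict=False) == ["in", "out"]

    def test_threshold_one_strict_is_empty(self):
        m = state_frame(["g"], ["e1", "e2"], [[1, 1]])
        assert sn.identify_ctr(m, threshold=1.0, strict=True) == []

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        m = state_frame(
            [f"g{i}" for i in range(30)],
            [f"e{j}" for j in range(20)],
            rng.choice((-1, 0, 1), size=(30, 20)),
        )
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            cur = set(sn.identify_ctr(m, threshold=thr))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_recovers_planted_core_genes(self, default_dataset, default_gene_states):
        _, ledger = default_dataset
        ctr = set(sn.identify_ctr(default_gene_states))
        core = ledger.planted_core_genes
        others = set(default_gene_states.rows) - core
        sensitivity = len(ctr & core) / len(core)
        specificity = 1 - len(ctr & others) / len(others)
        assert sensitivity >= 0.95
        assert specificity >= 0.95


class TestSummarizeCtr:
    @pytest.mark.parametrize(
        "n, total, percent", [(399, 3264, 12), (0, 3264, 0), (3264, 3264, 100)]
    )
    def test_rounded_percent(self, n, total, percent):
        s = sn.summarize_ctr(n, total)
        assert (s.n_ctr, s.percent) == (n, percent)

    def test_accepts_gene_collections(self):
        assert sn.summarize_ctr(["a", "b", "c"], 10).percent == 30


class TestAgreement:
    def test_identical_profiles_agree_fully(self):
        p = list(np.resize([1, -1, 0], 68))
        agr, n = sn.agreement(p, p)
        assert (agr, n) == (1.0, 68)

    def test_negation_without_zeros_agrees_nowhere(self):
        p = list(np.resize([1, -1], 68))
        agr, _ = sn.agreement(p, [-v for v in p])
        assert agr == 0.0

    def test_sixty_percent_cutoff_arithmetic(self):
        a = [1] * 68
        b = [1] * 41 + [0] * 27
        agr, n = sn.agreement(a, b)
        assert n == 68
        assert agr == pytest.approx(41 / 68)
        assert agr > 0.6

    def test_symmetric_bounded_and_hamming_complement(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            a = rng.choice([-1, 0, 1, None], 30).tolist()
            b = rng.choice([-1, 0, 1, None], 30).tolist()
            try:
                agr_ab, n = sn.agreement(a, b)
            except UndefinedAgreementError:
                continue
            agr_ba, _ = sn.agreement(b, a)
            assert agr_ab == agr_ba
            assert 0 <= agr_ab <= 1
            hamming = sum(
                1 for x, y in zip(a, b) if x is not None and y is not None and x != y
            )
            assert agr_ab == pytest.approx(1 - hamming / n)

    def test_no_overlap_is_undefined(self):
        with pytest.raises(UndefinedAgreementError):
            sn.agreement([1, None], [None, 1])


class TestCoregulationNetwork:
    def test_cutoff_one_keeps_only_perfect_matches(self):
        rows = np.array([[1, -1, 0, 1], [1, -1, 0, 1], [1, -1, 0, -1]])
        m = state_frame(["r", "t1", "t2"], list("abcd"), rows)
        edges = sn.coregulation_network(m, ["r"], ["t1", "t2"], cutoff=1.0)
        assert [] == edges  # strict ">" excludes even perfect agreement at cutoff 1
        edges = sn.coregulation_network(m, ["r"], ["t1", "t2"], cutoff=0.99)
        assert [(e.regulator, e.target) for e in edges] == [("r", "t1")]

    def test_empty_regulator_set_gives_no_edges(self):
        m = state_frame(["g1"], ["e1"], [[1]])
        assert sn.coregulation_network(m, [], ["g1"]) == []

    def test_missing_regulator_is_an_error(self):
        m = state_frame(["g1"], ["e1"], [[1]])
        with pytest.raises(KeyError, match="ghost"):
            sn.coregulation_network(m, ["ghost"], ["g1"])

    def test_planted_edges_recovered_with_few_decoy_false_positives(
        self, default_dataset, default_gene_states
    ):
        _, ledger = default_dataset
        regs = sorted({r for r, _, _ in ledger.regulator_pairs})
        tgts = sorted({t for _, t, _ in ledger.regulator_pairs})
        planted = {(r, t) for r, t, _ in ledger.regulator_pairs}
        ctr = set(sn.identify_ctr(default_gene_states))
        decoys = sorted(
            set(default_gene_states.rows)
            - ledger.planted_core_genes - ctr - set(regs) - set(tgts)
        )[:500]
        edges = sn.coregulation_network(default_gene_states, regs, tgts + decoys)
        found = {(e.regulator, e.target) for e in edges}
        assert planted <= found
        false_edges = {e for e in found if e[1] in set(decoys)}
        assert len(false_edges) / (len(regs) * len(decoys)) <= 0.05

    def test_fewer_experiments_never_increase_n_compared(self, default_gene_states):
        m = default_gene_states
        sub = sn.DiscreteStateMatrix(m.frame[m.columns[:20]].copy())
        regs, tgts = m.rows[:3], m.rows[3:13]
        full = {(e.regulator, e.target): e.n_compared
                for e in sn.coregulation_network(m, regs, tgts, cutoff=0.0)}
        part = {(e.regulator, e.target): e.n_compared
                for e in sn.coregulation_network(sub, regs, tgts, cutoff=0.0)}
        for k in part:
            assert part[k] <= full.get(k, np.inf)


class TestGreedyRegulatorCover:
    def test_greedy_cover_prefers_largest_gain_then_lexicographic(self):
        edges = [
            sn.CoregulationEdge("rB", t, 0.8, 10) for t in ("t1", "t2", "t3")
        ] + [
            sn.CoregulationEdge("rA", t, 0.8, 10) for t in ("t1", "t2", "t3")
        ] + [sn.CoregulationEdge("rC", "t4", 0.8, 10)]
        chosen, frac = sn.greedy_regulator_cover(edges, ["t1", "t2", "t3", "t4"], coverage=1.0)
        assert chosen == ["rA", "rC"]
        assert frac == 1.0


class TestScanConsensus:
    def test_exact_hit_with_n_wildcard(self):
        hits = sn.scan_consensus([("g1", "GGTTATAATCATTATAAGG")])
        assert hits == [sn.MotifHit("g1", 2, "TTATAATCATTATAA")]

    def test_no_match_gives_empty_list(self):
        assert sn.scan_consensus([("g1", "ACGT" * 10)]) == []

    def test_default_consensus_is_its_own_reverse_complement(self):
        # brute-force: every concrete realization of the consensus has a
        # reverse complement matching the consensus too
        from itertools import product

        from synechonet.core_response import IUPAC, PERR_CONSENSUS

        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for letters in product(*(IUPAC[c] for c in PERR_CONSENSUS)):
            word = "".join(letters)
            rc = "".join(comp[c] for c in reversed(word))
            assert all(r in IUPAC[c] for r, c in zip(rc, PERR_CONSENSUS))

    def test_reverse_complemented_sequence_has_same_hit_count(self):
        seq = "AAAATTATAATCATTATAAGGGGTACT"
        rc = str(Seq(seq).reverse_complement())
        assert len(sn.scan_consensus([("f", seq)])) == len(sn.scan_consensus([("r", rc)]))

    def test_both_strand_scan_finds_non_palindromic_motif_on_reverse(self):
        motif = "ACGTACGTAC"
        seq = "TTTT" + str(Seq(motif).reverse_complement()) + "TTTT"
        assert sn.scan_consensus([("g", seq)], motif) == []
        hits = sn.scan_consensus([("g", seq)], motif, both_strands=True)
        assert len(hits) == 1 and hits[0].strand == "-" and hits[0].offset == 4

    def test_accepts_seqrecords_and_rejects_bad_characters(self):
        rec = SeqRecord(Seq("GGTTATAATCATTATAAGG"), id="g1")
        assert len(sn.scan_consensus([rec])) == 1
        with pytest.raises(ValueError, match="non-nucleotide"):
            sn.scan_consensus([("g1", "ACGU")])
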