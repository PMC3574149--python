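"""NG86 counting, the per-codon selection test, and rate diagnostics."""

import itertools
import math

import numpy as np
import pytest

from cardcoal import (
    LocusAlignment,
    branch_length_to_outgroup,
    codon_site_test,
    fixed_aa_changes,
    island_mainland_ratio,
    lineage_dnds,
    ng86_codon_differences,
    ng86_pairwise,
    ng86_site_counts,
    p_distance,
    relative_rate,
)
from cardcoal.codes import get_code, sense_codons
from cardcoal.dnds import UndefinedCorrectionError
from cardcoal.io import read_newick
from helpers import ng86_pathway_oracle, ng86_sites_oracle, patristic_oracle


class TestSiteCounts:
    def test_phenylalanine_third_position(self):
        s, n = ng86_site_counts("TTT", "standard")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_fourfold_degenerate_alanine(self):
        s, _ = ng86_site_counts("GCT", "standard")
        assert s == pytest.approx(1.0)

    @pytest.mark.parametrize("code", ["standard", "vertebrate-mitochondrial"])
    def test_conservation_and_oracle_all_codons(self, code):
        for codon in sense_codons(code):
            s, n = ng86_site_counts(codon, code)
            assert s + n == pytest.approx(3.0)
            so, no = ng86_sites_oracle(codon, code)
            assert s == pytest.approx(so) and n == pytest.approx(no)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_counts("TAA", "standard")
        # AGA is a stop only in the vertebrate mitochondrial code
        ng86_site_counts("AGA", "standard")
        with pytest.raises(ValueError):
            ng86_site_counts("AGA", "vertebrate-mitochondrial")


class TestPairwise:
    def test_single_synonymous_difference(self):
        rec = ng86_pairwise("TTTGCTAAA", "TTCGCTAAA", "standard")
        assert rec.s_diffs == pytest.approx(1.0)
        assert rec.n_diffs == pytest.approx(0.0)
        assert rec.dn == 0.0
        s_total = sum(ng86_site_counts(c, "standard")[0]
                      for c in ("TTT", "GCT", "AAA")) / 1.0
        s_avg = (s_total + sum(ng86_site_counts(c, "standard")[0]
                               for c in ("TTC", "GCT", "AAA"))) / 2
        assert rec.ds == pytest.approx(
            -0.75 * math.log(1 - 4 / 3 * (1 / s_avg)))

    def test_identical_sequences_flagged_ratio(self):
        rec = ng86_pairwise("ATGGCT", "ATGGCT", "standard")
        assert rec.dn == rec.ds == 0.0
        assert not rec.defined and math.isnan(rec.ratio)

    def test_two_path_ambiguity_matches_oracle(self):
        # TTA (Leu) -> CTG (Leu): ambiguous order, oracle averages pathways
        sd, nd = ng86_pathway_oracle("TTA", "CTG", "standard")
        assert ng86_codon_differences("TTA", "CTG", "standard") == \
            pytest.approx((sd, nd))

    def test_random_pairs_match_oracle(self, rng):
        for code in ("standard", "vertebrate-mitochondrial"):
            senses = sense_codons(code)
            for _ in range(150):
                c1, c2 = (senses[int(i)] for i in
                          rng.integers(0, len(senses), size=2))
                sd, nd = ng86_pathway_oracle(c1, c2, code)
                got = ng86_codon_differences(c1, c2, code)
                assert got == pytest.approx((sd, nd), abs=1e-12)

    def test_ambiguous_codons_pairwise_deleted(self):
        rec = ng86_pairwise("TTTNNNGCTGGG", "TTCAAAGCTGGG", "standard")
        assert rec.n_codons == 3  # ambiguous middle codon dropped

    def test_saturated_proportion_rejected(self):
        with pytest.raises(UndefinedCorrectionError):
            ng86_pairwise("GCT" * 10, "GCA" * 10, "standard")

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            ng86_pairwise("ACGT", "ACGA", "standard")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_pairwise("TAAGCT", "TACGCT", "standard")

    def test_loose_agreement_with_biopython(self, rng):
        """Independent-route sanity check; conventions differ in stop-codon
        handling, so only loose agreement is expected."""
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        senses = sense_codons("standard")
        s1 = [senses[int(i)] for i in rng.integers(0, 61, size=60)]
        s2 = [c if rng.random() < 0.88 else senses[int(rng.integers(0, 61))]
              for c in s1]
        mine = ng86_pairwise("".join(s1), "".join(s2), "standard")
        dn, ds = cal_dn_ds(CodonSeq("".join(s1)), CodonSeq("".join(s2)),
                           method="NG86")
        assert mine.dn == pytest.approx(dn, abs=0.03)
        assert mine.ds == pytest.approx(ds, abs=0.03)


def _codon_aln(seqs, ids=None, code="standard"):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return LocusAlignment(ids=ids, seqs=list(seqs), genetic_code=code)


class TestLineageDnds:
    def test_identical_to_outgroup_undefined(self):
        aln = _codon_aln(["ATGGCT"] * 3, ids=["out", "a", "b"])
        res = lineage_dnds(aln, {"g": ["a", "b"]}, "out")
        assert math.isnan(res.group_median["g"])

    def test_group_medians_and_overall(self):
        # one group with a synonymous diff only, one with both kinds
        aln = _codon_aln(
            ["TTTGCTAAAACT", "TTCGCTAAAACT", "TTTGCTAAAACT",
             "TTCGCTAGAACT"],
            ids=["out", "g1a", "g1b", "g2a"])
        res = lineage_dnds(aln, {"g1": ["g1a", "g1b"], "g2": ["g2a"]}, "out")
        assert res.group_median["g1"] == 0.0  # only synonymous change
        assert res.group_median["g2"] > 0.0
        assert res.overall_median == pytest.approx(
            np.median([res.group_median["g1"], res.group_median["g2"]]))

    def test_empty_group_rejected(self):
        aln = _codon_aln(["ATGGCT"] * 2, ids=["out", "a"])
        with pytest.raises(ValueError, match="no haplotypes"):
            lineage_dnds(aln, {"g": []}, "out")


class TestIslandMainlandRatio:
    def test_values(self):
        assert island_mainland_ratio(0.1, 0.1) == 1.0
        assert island_mainland_ratio(0.2, 0.1) == pytest.approx(2.0)

    def test_zero_mainland_rejected(self):
        with pytest.raises(ValueError):
            island_mainland_ratio(0.2, 0.0)


class TestCodonSiteTest:
    def test_invariant_alignment(self):
        aln = _codon_aln(["ATGGCT"] * 4)
        res = codon_site_test(aln)
        assert (res.table["stat"] == 0).all()
        assert (res.table["p"] == 1.0).all()

    def test_synonymous_changes_give_negative_statistic(self):
        # third-position fourfold changes only
        aln = _codon_aln(["GCTATG", "GCAATG", "GCCATG", "GCGATG"])
        tree = read_newick("((s0:1,s1:1):1,(s2:1,s3:1):1);")
        res = codon_site_test(aln, guide_tree=tree)
        assert res.table.loc[0, "stat"] < 0
        assert res.table.loc[1, "stat"] == 0

    def test_nonsynonymous_excess_positive_statistic(self):
        aln = _codon_aln(["ATGAAA", "ATGAGA", "ATGACA", "ATGATA"])
        tree = read_newick("((s0:1,s1:1):1,(s2:1,s3:1):1);")
        res = codon_site_test(aln, guide_tree=tree)
        assert res.table.loc[1, "stat"] > 0
        assert 0 < res.table.loc[1, "p"] <= 1


class TestFixedAaChanges:
    def test_toy_example(self):
        aln = _codon_aln(["ATGGAT", "ATGGAT", "ATGAAT", "ATGAAT"],
                         ids=["f1", "f2", "o1", "o2"])
        n, pos = fixed_aa_changes(aln, ["f1", "f2"])
        assert n == 1 and pos == [2]  # Asp vs Asn at codon 2

    def test_identical_sequences(self):
        aln = _codon_aln(["ATGGAT"] * 4)
        n, _ = fixed_aa_changes(aln, ["s0", "s1"])
        assert n == 0

    def test_polymorphic_focal_site_not_counted(self):
        aln = _codon_aln(["ATGGAT", "ATGAAT", "ATGCAT", "ATGCAT"],
                         ids=["f1", "f2", "o1", "o2"])
        n, _ = fixed_aa_changes(aln, ["f1", "f2"])
        assert n == 0

    def test_synonymous_recoding_and_order_invariance(self):
        a = _codon_aln(["ATGGAT", "ATGGAT", "ATGAAT", "ATGAAT"],
                       ids=["f1", "f2", "o1", "o2"])
        # GAT -> GAC is synonymous (both Asp); order shuffled
        b = _codon_aln(["ATGAAT", "ATGGAC", "ATGGAT", "ATGAAT"],
                       ids=["o1", "f1", "f2", "o2"])
        assert fixed_aa_changes(a, ["f1", "f2"])[0] == \
            fixed_aa_changes(b, ["f1", "f2"])[0] == 1

    def test_sister_only_restriction(self):
        aln = _codon_aln(["ATGGAT", "ATGAAT", "ATGGAT"],
                         ids=["f1", "sis", "far"])
        assert fixed_aa_changes(aln, ["f1"])[0] == 0  # 'far' shares Asp
        assert fixed_aa_changes(aln, ["f1"], others=["sis"])[0] == 1


class TestDistancesAndRates:
    def test_p_distance(self):
        assert p_distance("ACGT", "ACGT") == 0.0
        assert p_distance("ACGT", "ACGA") == 0.25
        assert p_distance("ACNT", "ACGA") == pytest.approx(1 / 3)
        with pytest.raises(ValueError):
            p_distance("NNN", "ACG")
        with pytest.raises(ValueError):
            p_distance("AC", "ACG")

    def test_relative_rate_definitional(self):
        out = "A" * 1000
        # ingroup at p-distance 0.100 for cyt b; 0.050 and 0.123 for loci
        cytb = LocusAlignment(ids=["out", "x"],
                              seqs=[out, "C" * 100 + "A" * 900])
        half = LocusAlignment(ids=["out", "x"],
                              seqs=[out, "C" * 50 + "A" * 950])
        nd2ish = LocusAlignment(ids=["out", "x"],
                                seqs=[out, "C" * 123 + "A" * 877])
        assert relative_rate(cytb, cytb, "out") == pytest.approx(1.0e-8)
        assert relative_rate(half, cytb, "out") == pytest.approx(5.0e-9)
        assert relative_rate(nd2ish, cytb, "out") == pytest.approx(1.23e-8)

    def test_relative_rate_zero_cytb_rejected(self):
        same = LocusAlignment(ids=["out", "x"], seqs=["AAA", "AAA"])
        with pytest.raises(ValueError, match="zero"):
            relative_rate(same, same, "out")

    def test_branch_length_cherry_and_self(self):
        t = read_newick("((a:0.1,b:0.2):0.05,c:0.3);")
        assert branch_length_to_outgroup(t, "a", "b") == pytest.approx(0.3)
        assert branch_length_to_outgroup(t, "a", "a") == 0.0

    def test_branch_length_matches_path_oracle(self, rng):
        from helpers import random_gene_tree
        g = random_gene_tree(7, rng)
        t = read_newick(g.to_newick())
        labels = list(g.labels)
        for a, b in itertools.combinations(labels[:5], 2):
            assert branch_length_to_outgroup(t, a, b) == pytest.approx(
                patristic_oracle(t, a, b), abs=1e-9)

    def test_group_mean_variant(self):
        t = read_newick("((a:0.1,b:0.2):0.05,c:0.3);")
        expect = np.mean([0.1 + 0.05 + 0.3, 0.2 + 0.05 + 0.3])
        assert branch_length_to_outgroup(t, ["a", "b"], "c") == \
            pytest.approx(expect)

    def test_missing_taxon_rejected(self):
        t = read_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError, match="zzz"):
            branch_length_to_outgroup(t, "zzz", "c")
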