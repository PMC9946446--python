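"""Variant classification, codon-aware realignment, naming, and filters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from crisprscan import genotypes as g
from crisprscan.simulate import AlleleSimSpec, make_toy_gene, simulate_allele_tables
from tests.conftest import make_class_table


def edit_del(ref, pos, size):
    """Alignment rows for a deletion of ``size`` nt starting at ``pos`` (1-based)."""
    return ref[: pos - 1] + "-" * size + ref[pos - 1 + size :], ref


def edit_ins(ref, bond, ins):
    return ref[:bond] + ins + ref[bond:], ref[:bond] + "-" * len(ins) + ref[bond:]


def edit_sub(ref, pos, alt):
    return ref[: pos - 1] + alt + ref[pos - 1 + len(alt) :], ref


class TestClassification:
    def test_unedited_is_wild_type(self, toy_gene):
        ref = toy_gene.amplicon
        assert g.classify_allele(ref, ref, toy_gene) == (g.WILD_TYPE, None)

    def test_inframe_deletion(self, toy_gene):
        s1 = toy_gene.exons[0][0]
        read, ref = edit_del(toy_gene.amplicon, s1 + 12, 6)
        cls, name = g.classify_allele(read, ref, toy_gene)
        assert cls == g.IN_FRAME and name and name.endswith("del")

    def test_frameshift_insertion(self, toy_gene):
        s1 = toy_gene.exons[0][0]
        read, ref = edit_ins(toy_gene.amplicon, s1 + 20, "ACGT")
        assert g.classify_allele(read, ref, toy_gene)[0] == g.FRAMESHIFT

    def test_splice_site_deletion_at_donor(self, toy_gene):
        e1 = toy_gene.exons[0][1]
        # 3-nt deletion overlapping the GT just 3' of exon 1
        read, ref = edit_del(toy_gene.amplicon, e1, 3)
        assert g.classify_allele(read, ref, toy_gene)[0] == g.SPLICE_SITE

    def test_splice_site_substitution_at_acceptor(self, toy_gene):
        s2 = toy_gene.exons[1][0]
        base = toy_gene.amplicon[s2 - 2]
        alt = "A" if base != "A" else "C"
        read, ref = edit_sub(toy_gene.amplicon, s2 - 1, alt)
        assert g.classify_allele(read, ref, toy_gene)[0] == g.SPLICE_SITE

    def test_deletion_spanning_junction_is_splice(self, toy_gene):
        s1, e1 = toy_gene.exons[0]
        read, ref = edit_del(toy_gene.amplicon, e1 - 3, 9)  # exon into intron
        assert g.classify_allele(read, ref, toy_gene)[0] == g.SPLICE_SITE

    def test_intronic_interior_edit_is_wild_type(self, toy_gene):
        e1 = toy_gene.exons[0][1]
        mid_intron = e1 + 15
        base = toy_gene.amplicon[mid_intron - 1]
        alt = "A" if base != "A" else "C"
        read, ref = edit_sub(toy_gene.amplicon, mid_intron, alt)
        assert g.classify_allele(read, ref, toy_gene) == (g.WILD_TYPE, None)

    def test_silent_substitution_merges_to_wild_type(self, flat_gene):
        cds = flat_gene.amplicon
        # find a codon with a synonymous third-position change
        for c in range(len(cds) // 3):
            codon = cds[3 * c : 3 * c + 3]
            aa = str(Seq(codon).translate())
            for b in "ACGT":
                alt = codon[:2] + b
                if alt != codon and str(Seq(alt).translate()) == aa:
                    read, ref = edit_sub(cds, 3 * c + 3, b)
                    assert g.classify_allele(read, ref, flat_gene) == (g.WILD_TYPE, None)
                    return
        pytest.skip("no synonymous edit found in this fixture")

    def test_nonsense_substitution(self, flat_gene):
        cds = flat_gene.amplicon
        # force codon 3 to TAA
        read, ref = edit_sub(cds, 7, "TAA")
        assert g.classify_allele(read, ref, flat_gene)[0] == g.NONSENSE

    def test_missense_substitution_named(self, flat_gene):
        cds = flat_gene.amplicon
        codon = cds[9:12]
        for alt in ("AAA", "GGG", "CCC"):
            if (
                str(Seq(alt).translate()) != str(Seq(codon).translate())
                and str(Seq(alt).translate()) != "*"
            ):
                read, ref = edit_sub(cds, 10, alt)
                cls, name = g.classify_allele(read, ref, flat_gene)
                assert cls == g.IN_FRAME
                ref_aa = str(Seq(codon).translate())
                assert name == f"{ref_aa}4{Seq(alt).translate()}"
                return

    def test_classification_exhaustive_and_exclusive(self, toy_gene):
        sim = simulate_allele_tables(AlleleSimSpec(regime="GOF"), seed=33, gene=toy_gene)
        for df in (sim.vehicle, sim.drug):
            out = g.classify_allele_table(df, toy_gene)
            assert out["classification"].isin(g.CLASSES).all()
            # LOF flag is exactly the union of the three LOF classes
            assert (
                out["lof"] == out["classification"].isin(g.LOF_CLASSES)
            ).all()


class TestCodonNW:
    def test_identical_sequences_score(self):
        cds = "ATGAAACCCGGG"
        cols, score = g.realign_codon_nw(cds, cds)
        assert score == 3 * 4
        assert all(a == b for a, b in cols)

    def test_single_codon_substitution_score(self):
        # AAG vs CTG share only the final G
        cols, score = g.realign_codon_nw("CTG", "AAG")
        assert score == 1 and len(cols) == 1

    def test_three_codon_gap_placement(self):
        ref = "AAACCCGGGTTTACGCAT"  # 6 codons
        var = ref[:3] + ref[12:]  # codons 2-4 deleted
        cols, score = g.realign_codon_nw(var, ref)
        gaps = [k for k, (_, v) in enumerate(cols) if v is None]
        assert gaps == [1, 2, 3]
        assert score == 3 * 3 + 3 * g.DEFAULT_GAP_PENALTY

    def test_tie_break_prefers_3prime_gap(self):
        cols, _ = g.realign_codon_nw("AAATTT", "AAAAAATTT")
        assert [v is None for _, v in cols] == [False, True, False]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        """Optimal score equals brute force over all codon alignments (<=6 codons)."""
        rng = np.random.default_rng(seed)
        bases = list("ACGT")
        n_ref = int(rng.integers(1, 7))
        n_var = int(rng.integers(1, 7))
        ref = "".join(rng.choice(bases, 3 * n_ref))
        var = "".join(rng.choice(bases, 3 * n_var))
        _, score = g.realign_codon_nw(var, ref)
        assert score == pytest.approx(_brute_force_best(ref, var))

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            g.realign_codon_nw("AAAA", "AAA")


def _brute_force_best(ref, var, gp=g.DEFAULT_GAP_PENALTY):
    """Enumerate every codon-unit global alignment and return the best score."""
    rc = [ref[i : i + 3] for i in range(0, len(ref), 3)]
    vc = [var[i : i + 3] for i in range(0, len(var), 3)]

    def rec(i, j):
        if i == len(rc) and j == len(vc):
            return 0.0
        best = -np.inf
        if i < len(rc) and j < len(vc):
            best = max(best, g.codon_match_score(rc[i], vc[j]) + rec(i + 1, j + 1))
        if i < len(rc):
            best = max(best, gp + rec(i + 1, j))
        if j < len(vc):
            best = max(best, gp + rec(i, j + 1))
        return best

    return rec(0, 0)


class TestNaming:
    def test_multi_codon_deletion_absolute_numbering(self):
        ref_prot = "MKLMNPQRSTD"
        var_prot = "MKD"  # residues 3..10 deleted (L..T), anchored at 694-ish
        name = g.name_protein_variant(ref_prot, var_prot, first_residue=692)
        assert name == "L694_T701del"

    def test_single_residue_deletion(self):
        assert g.name_protein_variant("MKD", "MD", 1) == "K2del"

    def test_repeat_deletion_right_aligned(self):
        assert g.name_protein_variant("MKKKD", "MKKD", 1) == "K4del"
        assert (
            g.name_protein_variant("MKKKD", "MKKD", 1, right_align=False) == "K2del"
        )

    def test_substitution_and_adjacent_pair(self):
        assert g.name_protein_variant("AKEB", "ALEB", 591) == "K592L"
        assert g.name_protein_variant("AKEB", "ASKB", 591) == "K592S/E593K"

    def test_delins(self):
        assert g.name_protein_variant("AFGHDB", "ALB", 544) == "F545_D548delinsL"

    def test_insertion(self):
        name = g.name_protein_variant("MKD", "MKXYD", 1)
        assert name == "K2_D3insXY"

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_name_parse_round_trip(self, data):
        """parse(name(variant)) reproduces the variant interval and payload."""
        aa = "ACDEFGHIKLMNPQRSTVWY"
        rng_prot = data.draw(
            st.text(alphabet=aa, min_size=6, max_size=15), label="protein"
        )
        kind = data.draw(st.sampled_from(["del", "sub", "delins"]))
        n = len(rng_prot)
        start = data.draw(st.integers(1, n - 2), label="start")
        end = data.draw(st.integers(start, min(n - 1, start + 4)), label="end")
        if kind == "del":
            var = rng_prot[: start - 1] + rng_prot[end:]
        elif kind == "sub":
            alt = data.draw(st.sampled_from(aa))
            end = start
            if alt == rng_prot[start - 1]:
                return
            var = rng_prot[: start - 1] + alt + rng_prot[start:]
        else:
            alt = data.draw(st.text(alphabet=aa, min_size=1, max_size=2))
            if end - start + 1 == len(alt):
                return
            var = rng_prot[: start - 1] + alt + rng_prot[end:]
        name = g.name_protein_variant(rng_prot, var, first_residue=1)
        if name is None:
            assert rng_prot == var
            return
        parsed = g.parse_variant_name(name, reference_protein=rng_prot)
        # re-applying the parsed edit reproduces the variant protein
        rebuilt = (
            rng_prot[: parsed.start - 1] + parsed.alt + rng_prot[parsed.end :]
            if parsed.kind != "ins"
            else rng_prot[: parsed.start] + parsed.alt + rng_prot[parsed.start :]
        )
        assert rebuilt == var


class TestFrequencies:
    def _table(self):
        return make_class_table(
            [
                ("WT", g.WILD_TYPE, 50.0, 40.0),
                ("a1", g.IN_FRAME, 0.05, 0.05),  # below threshold in both
                ("a2", g.IN_FRAME, 0.01, 0.2),  # retained: >=0.1% in drug
                ("a3", g.FRAMESHIFT, 30.0, 20.0),
                ("a4", g.SPLICE_SITE, 19.94, 39.75),
            ]
        )

    def test_filter_keeps_either_condition_rule(self):
        out = g.filter_and_normalize(self._table())
        assert set(out["allele"]) == {"WT", "a2", "a3", "a4"}

    def test_renormalization_sums_to_100(self):
        out = g.filter_and_normalize(self._table())
        for cond in ("vehicle", "drug"):
            assert out[f"freq_{cond}"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_after_filter_errors(self):
        t = make_class_table([("a1", g.IN_FRAME, 0.01, 0.01)])
        with pytest.raises(ValueError):
            g.filter_and_normalize(t)

    def test_conservation_through_merge(self, toy_gene):
        sim = simulate_allele_tables(AlleleSimSpec(), seed=8, gene=toy_gene)
        merged = g.merge_conditions(sim.vehicle, sim.drug, toy_gene)
        for cond in ("vehicle", "drug"):
            assert merged[f"freq_{cond}"].sum() == pytest.approx(100.0, abs=1e-9)


class TestEnrichment:
    def test_enrichment_criteria(self):
        t = make_class_table(
            [
                ("WT", g.WILD_TYPE, 80.0, 60.0),
                ("e1", g.IN_FRAME, 0.1, 1.5),  # log2fc ~ 3.9 -> enriched
                ("e2", g.IN_FRAME, 0.01, 0.9),  # fails >=1%
                ("e3", g.IN_FRAME, 2.0, 5.0),  # log2fc ~ 1.32 -> fails FC
                ("e4", g.FRAMESHIFT, 0.1, 30.0),  # not in-frame
            ]
        )
        out = g.enriched_inframe_variants(t)
        assert list(out["allele"]) == ["e1"]

    def test_sorted_by_drug_frequency(self):
        t = make_class_table(
            [
                ("WT", g.WILD_TYPE, 80.0, 60.0),
                ("e1", g.IN_FRAME, 0.1, 1.5),
                ("e2", g.IN_FRAME, 0.1, 8.0),
            ]
        )
        out = g.enriched_inframe_variants(t)
        assert list(out["allele"]) == ["e2", "e1"]

    def test_zero_vehicle_uses_floor(self):
        t = make_class_table([("WT", g.WILD_TYPE, 98.0, 90.0), ("e1", g.IN_FRAME, 0.0, 2.0)])
        out = g.enriched_inframe_variants(t)
        assert list(out["allele"]) == ["e1"]
        assert np.isfinite(out["log2fc"]).all()


class TestClassSummary:
    def test_relative_shares_arithmetic(self):
        t = make_class_table(
            [
                ("WT", g.WILD_TYPE, 50.0, 50.0),
                ("a", g.IN_FRAME, 30.0, 30.0),
                ("b", g.FRAMESHIFT, 20.0, 20.0),
            ]
        )
        s = g.summarize_classes(t)
        assert s.loc["drug", "if_rel"] == pytest.approx(60.0)
        assert s.loc["drug", "lof_rel"] == pytest.approx(40.0)
        assert s.loc["drug", ["wt_abs", "if_abs", "lof_abs"]].sum() == pytest.approx(100.0)

    def test_all_wild_type_relative_missing(self):
        t = make_class_table([("WT", g.WILD_TYPE, 100.0, 100.0)])
        s = g.summarize_classes(t)
        assert np.isnan(s.loc["drug", "if_rel"]) and np.isnan(s.loc["drug", "lof_rel"])
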