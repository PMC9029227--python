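"""RNA folding, duplex energies, genome mapping and hairpin evaluation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import min_energy_enumerated, structure_energy as oracle_energy
from sexmir.discovery import (
    GenomeLocus,
    MireapParams,
    call_novel,
    duplex_energy,
    excise_and_evaluate,
    fold_rna,
    map_tags,
    perfect_duplex_energy,
    assign_chromosome,
    revcomp,
)

rna = st.text(alphabet="ACGU", min_size=10, max_size=14)


class TestFoldRna:
    def test_unpairable_sequence_has_no_structure(self):
        f = fold_rna("AAAAAAAAAA")
        assert f.energy == 0.0 and f.structure == "." * 10

    def test_gc_hairpin_with_four_nt_loop(self):
        f = fold_rna("GGGGAAAACCCC")
        assert f.structure == "((((....))))"
        # three stacked G:C pairs plus the innermost (isolated-scored) pair
        assert f.energy == pytest.approx(-10.0)

    def test_minimum_loop_of_three_enforced(self):
        f = fold_rna("GGGAAACCCAAA")
        assert all(j - i - 1 >= 3 for i, j in f.pairs())

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="short"):
            fold_rna("ACGUACGUA")

    def test_invalid_alphabet_named(self):
        with pytest.raises(ValueError, match="X"):
            fold_rna("ACGUXACGUACGU")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(rna)
    def test_matches_exhaustive_enumeration(self, seq):
        assert fold_rna(seq).energy == pytest.approx(min_energy_enumerated(seq))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(rna)
    def test_traceback_structure_realizes_reported_energy(self, seq):
        f = fold_rna(seq)
        assert oracle_energy(seq, set(f.pairs())) == pytest.approx(f.energy)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=10, max_size=40))
    def test_energy_invariant_under_reversal(self, seq):
        # reversal maps every pair type onto itself (G:U -> U:G), so the
        # minimum energy is symmetric under it
        assert fold_rna(seq).energy == pytest.approx(fold_rna(seq[::-1]).energy)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="GC", min_size=10, max_size=40).map(
        lambda s: s if len(s) >= 10 else s + "G" * 10))
    def test_energy_invariant_under_reverse_complement_without_wobbles(self, seq):
        # with Watson-Crick pairs only, reverse-complementation also maps
        # structures one-to-one (a G:U wobble would map to unpairable A:C)
        rc = seq.translate(str.maketrans("ACGU", "UGCA"))[::-1]
        assert fold_rna(seq).energy == pytest.approx(fold_rna(rc).energy)


class TestDuplexEnergy:
    def test_perfect_gc_duplex(self):
        # 5 stacked G:C pairs + terminal isolated contribution
        e = duplex_energy("GCGCGC", "GCGCGC", [True] * 6)
        assert e == pytest.approx(-3.0 * 5 - 1.0)
        assert perfect_duplex_energy("GCGCGC") == pytest.approx(e)

    def test_all_mismatch_alignment_is_zero(self):
        assert duplex_energy("AAAA", "CCCC", [False] * 4) == 0.0

    def test_wobble_strictly_weaker_than_watson_crick(self):
        wc = duplex_energy("GGGG", "CCCC", [True] * 4)
        wob = duplex_energy("GGGG", "UUUU", [True] * 4)
        assert wob > wc

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            duplex_energy("ACGU", "ACG", [True] * 4)


class TestMapTags:
    GENOME = {"chr1": "T" * 100 + "ACGTGGCATCGATCGGATCCG" + "T" * 100,
              "chr2": "G" * 80 + revcomp("ACGTGGCATCGATCGGATCCG") + "G" * 80}

    def test_plus_strand_single_locus(self):
        tag = "ACGTGGCATCGATCGGATCCG"
        loci = map_tags([tag], {"chr1": self.GENOME["chr1"]})[tag]
        assert loci == [GenomeLocus("chr1", 100, 121, "+")]

    def test_minus_strand_reported_as_reverse_complement(self):
        tag = "ACGTGGCATCGATCGGATCCG"
        loci = map_tags([tag], {"chr2": self.GENOME["chr2"]})[tag]
        assert loci == [GenomeLocus("chr2", 80, 101, "-")]

    def test_absent_tag_has_no_loci(self):
        assert map_tags(["ACGTACGTACGTACGTACGTAC"], self.GENOME)[
            "ACGTACGTACGTACGTACGTAC"] == []

    def test_tags_beyond_copy_number_are_excluded_from_discovery(self):
        tag = "ACGTGGCATCGATCGGATCCG"
        genome = {"chr1": ("TTTT" + tag) * 25}
        novel, rejections = call_novel({tag: {"s": 10}}, genome)
        assert novel == []
        assert rejections and all(v == ["copy_number"] for _t, _l, v in rejections)


class TestExciseAndEvaluate:
    def test_planted_compliant_hairpins_pass_all_criteria(self, small_study):
        spec, genome, *_rest, truth = small_study
        for h in truth.hairpins:
            if not h.compliant:
                continue
            locus = GenomeLocus(h.chromosome, h.start, h.end, h.strand)
            cand = excise_and_evaluate(h.mature, locus, genome, spec.mireap)
            assert cand.compliant
            assert len(cand.criteria) == 11

    def test_decoys_rejected_naming_planted_criterion(self, small_study):
        spec, genome, *_rest, truth = small_study
        for h in truth.hairpins:
            if h.compliant:
                continue
            locus = GenomeLocus(h.chromosome, h.start, h.end, h.strand)
            cand = excise_and_evaluate(h.mature, locus, genome, spec.mireap)
            assert not cand.compliant
            assert cand.violated == h.violated

    def test_spacing_decoy_names_the_spacing_criterion(self, small_study):
        _spec, genome, *_rest, truth = small_study
        spaced = [h for h in truth.hairpins if h.cls == "decoy:spacing"]
        assert spaced
        assert all("star_space_max" in h.violated for h in spaced)

    def test_bulge_decoy_names_the_bulge_criterion(self, small_study):
        _spec, _genome, *_rest, truth = small_study
        bulged = [h for h in truth.hairpins if h.cls == "decoy:bulge"]
        assert bulged
        assert all("bulge" in h.violated for h in bulged)

    def test_out_of_bounds_locus_raises(self, small_study):
        _spec, genome, *_ = small_study
        with pytest.raises(ValueError, match="bounds"):
            excise_and_evaluate("ACGT" * 5, GenomeLocus("chr1", 29990, 30010 + 100, "+"),
                                genome)

    def test_mature_and_star_do_not_overlap(self, small_study):
        spec, genome, *_rest, truth = small_study
        for h in truth.hairpins:
            if not h.compliant:
                continue
            cand = excise_and_evaluate(
                h.mature, GenomeLocus(h.chromosome, h.start, h.end, h.strand),
                genome, spec.mireap)
            m0, m1 = cand.mature_offset, cand.mature_offset + len(cand.mature)
            s0, s1 = cand.star_offset, cand.star_offset + len(cand.star)
            assert s1 <= m0 or m1 <= s0


class TestCallNovel:
    def test_empty_input(self, small_study):
        _spec, genome, *_ = small_study
        novel, rejections = call_novel({}, genome)
        assert novel == [] and rejections == []

    def test_recovers_planted_hairpins_and_rejects_decoys(self, small_study):
        spec, genome, *_rest, truth = small_study
        tag_counts = {h.mature: {"s1": 50} for h in truth.hairpins}
        novel, _rej = call_novel(tag_counts, genome, spec.mireap)
        found = {nm.candidate.mature.replace("U", "T") for nm in novel}
        compliant = {h.mature for h in truth.hairpins if h.compliant}
        decoys = {h.mature for h in truth.hairpins if not h.compliant}
        assert found == compliant
        assert not (found & decoys)

    def test_ids_deterministic_and_order_invariant(self, small_study):
        spec, genome, *_rest, truth = small_study
        tags = [h.mature for h in truth.hairpins if h.compliant]
        tc1 = {t: {"s1": i + 1} for i, t in enumerate(tags)}
        tc2 = {t: tc1[t] for t in reversed(tags)}
        n1, _ = call_novel(tc1, genome, spec.mireap)
        n2, _ = call_novel(tc2, genome, spec.mireap)
        assert [(m.id, m.candidate.mature) for m in n1] == \
               [(m.id, m.candidate.mature) for m in n2]
        assert all(m.id.startswith("novel-m") for m in n1)


class TestAssignChromosome:
    def test_novel_and_known_assignment(self, small_study):
        spec, genome, *_rest, truth = small_study
        tags = {h.mature: {"s": 5} for h in truth.hairpins if h.compliant}
        novel, _ = call_novel(tags, genome, spec.mireap)
        known = {"kn-1": truth.hairpins[0].mature,
                 "kn-miss": "ACGT" * 6}
        assign, multi = assign_chromosome(novel, known, genome)
        for nm in novel:
            assert assign[nm.id] == nm.candidate.precursor_locus.chromosome
        assert assign["kn-1"] == truth.hairpins[0].chromosome
        assert assign["kn-miss"] == "unplaced"

    def test_multi_chromosome_known_flagged(self):
        seq = "ACGTGGCATCGATCGGATCCG"
        genome = {"chr1": "T" * 50 + seq + "T" * 50,
                  "chr3": "G" * 50 + seq + "G" * 50}
        assign, multi = assign_chromosome([], {"m": seq}, genome)
        assert assign["m"] == "chr1"
        assert multi["m"] == ["chr1", "chr3"]
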