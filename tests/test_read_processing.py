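"""Read filtering rules, category accounting and tag collapsing."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from sexmir.read_processing import (
    FilterParams,
    MalformedReadError,
    classify_read,
    collapse_tags,
    filter_reads,
)

A3 = "TGGAATTCTCGGGTGCCAAGG"
A5 = "GTTCAGAGTTCTACAGTCCGACGATC"
PARAMS = FilterParams(adapter3=A3, adapter5=A5)

GOOD_INSERT = "ACGTACGTCCGGATCAGTCC"   # 20 nt, 25% A, no adapter seed


def _read(insert: str, qual_override: str | None = None):
    seq = insert + A3
    qual = qual_override if qual_override is not None else "I" * len(seq)
    return ("r1", seq, qual)


class TestFilterRules:
    def test_two_low_quality_bases_removed(self):
        seq = GOOD_INSERT + A3
        qual = "5" + "I" * (len(seq) - 2) + "5"   # two bases at exactly Q20
        cat, _ = classify_read(seq, qual, PARAMS)
        assert cat == "low_quality"

    def test_single_low_quality_base_survives(self):
        seq = GOOD_INSERT + A3
        qual = "5" + "I" * (len(seq) - 1)
        cat, insert = classify_read(seq, qual, PARAMS)
        assert cat == "clean" and insert == GOOD_INSERT

    def test_n_base_counts_as_low_quality(self):
        seq = "N" + GOOD_INSERT[1:] + A3
        cat, _ = classify_read(seq, "I" * len(seq), PARAMS)
        assert cat == "low_quality"

    def test_missing_adapter_is_adapter3_null(self):
        seq = "ACGTCCGGATCAGTCCAAGCTGACCGGATCAGTCCAAGT"
        cat, _ = classify_read(seq, "I" * len(seq), PARAMS)
        assert cat == "adapter3_null"

    def test_adapter_at_position_zero_is_insert_null(self):
        seq = A3 + "ACGTCCGGATCAGT"
        cat, _ = classify_read(seq, "I" * len(seq), PARAMS)
        assert cat == "insert_null"

    def test_full_5prime_adapter_in_insert(self):
        seq = A5 + "ACG" + A3
        cat, _ = classify_read(seq, "I" * len(seq), PARAMS)
        assert cat == "adapter5_contaminant"

    def test_pure_polya_insert_removed(self):
        cat, _ = classify_read("A" * 20 + A3, "I" * (20 + len(A3)), PARAMS)
        assert cat == "polyA"

    def test_polya_fraction_strictly_above_threshold(self):
        # 14/20 = 0.70 exactly: retained ("higher than 70%" is strict)
        insert = "A" * 14 + "CGTCGG"
        cat, got = classify_read(insert + A3, "I" * (len(insert) + len(A3)), PARAMS)
        assert cat == "clean" and got == insert

    def test_17nt_insert_removed_as_short(self):
        insert = GOOD_INSERT[:17]
        cat, _ = classify_read(insert + A3, "I" * (17 + len(A3)), PARAMS)
        assert cat == "shorter_than_min"

    def test_adapter_seed_tolerates_one_mismatch(self):
        mutated = "A" + A3[1:]
        cat, insert = classify_read(GOOD_INSERT + mutated,
                                    "I" * (len(GOOD_INSERT) + len(mutated)), PARAMS)
        assert cat == "clean" and insert == GOOD_INSERT

    def test_rule_order_low_quality_before_polya(self):
        # a poly(A) read with bad quality is attributed to rule 1
        seq = "A" * 20 + A3
        qual = "##" + "I" * (len(seq) - 2)
        cat, _ = classify_read(seq, qual, PARAMS)
        assert cat == "low_quality"


class TestFilterReads:
    def test_conservation_and_report_balance(self):
        reads = [
            _read(GOOD_INSERT),
            ("r2", GOOD_INSERT + A3, "##" + "I" * (len(GOOD_INSERT) + len(A3) - 2)),
            ("r3", "ACGTCCGGATCAGTCCAAGCTGACCGGATCAGTCCAAGT", "I" * 39),
            ("r4", A3 + "ACGTACGTACGT", "I" * (len(A3) + 12)),
            ("r5", "A" * 22 + A3, "I" * (22 + len(A3))),
            ("r6", "ACGTCCGGATCAGTCC" + A3, "I" * (16 + len(A3))),
        ]
        inserts, rep = filter_reads(reads, PARAMS)
        assert rep.raw_reads == 6
        assert rep.high_quality == 5
        assert (rep.adapter3_null, rep.insert_null, rep.polyA,
                rep.shorter_than_min, rep.clean_reads) == (1, 1, 1, 1, 1)
        rep.check()
        assert inserts == [GOOD_INSERT]

    def test_quality_length_mismatch_raises(self):
        with pytest.raises(MalformedReadError, match="r9"):
            filter_reads([("r9", "ACGT", "II")], PARAMS)

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            FilterParams(adapter3="", adapter5=A5)

    def test_refiltering_clean_inserts_removes_nothing(self):
        reads = [_read(GOOD_INSERT), _read("CCGGATTACCGGATCAGTCCAG")]
        inserts, _ = filter_reads(reads, PARAMS)
        re_reads = [(f"q{i}", s + A3, "I" * (len(s) + len(A3)))
                    for i, s in enumerate(inserts)]
        inserts2, rep2 = filter_reads(re_reads, PARAMS)
        assert inserts2 == inserts
        assert rep2.clean_reads == len(inserts)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(
            st.text(alphabet="ACGTN", min_size=1, max_size=60),
            st.sampled_from(["good", "bad", "adapter"])),
        min_size=1, max_size=20))
    def test_scalar_classifier_agrees_with_vectorized_filter(self, raws):
        """Dual route: classify_read and filter_reads partition identically."""
        reads = []
        for i, (seq, kind) in enumerate(raws):
            if kind == "adapter":
                seq = seq + A3
            qual = "I" * len(seq) if kind != "bad" else "#" * len(seq)
            reads.append((f"r{i}", seq, qual))
        inserts, rep = filter_reads(reads, PARAMS)
        cats = [classify_read(s, q, PARAMS)[0] for _r, s, q in reads]
        from collections import Counter
        c = Counter(cats)
        assert rep.raw_reads - rep.high_quality == c["low_quality"]
        assert rep.adapter3_null == c["adapter3_null"]
        assert rep.adapter5_contaminant == c["adapter5_contaminant"]
        assert rep.insert_null == c["insert_null"]
        assert rep.polyA == c["polyA"]
        assert rep.shorter_than_min == c["shorter_than_min"]
        assert rep.clean_reads == c["clean"]
        expected = [classify_read(s, q, PARAMS)[1] for _r, s, q in reads
                    if classify_read(s, q, PARAMS)[0] == "clean"]
        assert inserts == expected


class TestCollapseTags:
    def test_identical_inserts_collapse(self):
        tags = collapse_tags({"A": ["ACGT" * 5] * 3})
        assert len(tags) == 1 and tags[0].counts == {"A": 3}

    def test_empty_input(self):
        assert collapse_tags({"A": []}) == []

    def test_shared_sequence_across_samples(self):
        seq = "ACGTACGTCCGGATCAGT"
        tags = collapse_tags({"s1": [seq], "s2": [seq, seq]})
        assert len(tags) == 1
        assert tags[0].counts == {"s1": 1, "s2": 2} and tags[0].total == 3

    def test_order_descending_total_then_lexicographic(self):
        tags = collapse_tags({"s": ["GG" * 9, "AA" * 9, "CC" * 9, "CC" * 9]})
        assert [t.sequence for t in tags] == ["CC" * 9, "AA" * 9, "GG" * 9]

    def test_count_conservation(self):
        inserts = {"s1": ["ACGT" * 5, "TGCA" * 5, "ACGT" * 5],
                   "s2": ["TGCA" * 5]}
        tags = collapse_tags(inserts)
        for sample, lst in inserts.items():
            assert sum(t.counts.get(sample, 0) for t in tags) == len(lst)


class TestSyntheticAccounting:
    def test_planted_category_counts_reproduced_exactly(self, small_study, small_tags):
        spec = small_study[0]
        _tags, reports = small_tags
        for sample, _sex in spec.samples:
            rep = reports[sample]
            exp = spec.category_counts
            assert rep.raw_reads == spec.depth
            assert rep.raw_reads - rep.high_quality == exp["low_quality"]
            assert rep.adapter3_null == exp["adapter3_null"]
            assert rep.adapter5_contaminant == exp["adapter5_contaminant"]
            assert rep.insert_null == exp["insert_null"]
            assert rep.polyA == exp["polyA"]
            assert rep.shorter_than_min == exp["shorter_than_min"]
            rep.check()
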