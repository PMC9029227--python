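"""TPM normalization, the exact count test, DE calling and classification."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import ac_brute
from sexmir.expression import (
    CountMatrix,
    DdCtInput,
    STAGE_PAIRS,
    ac_test,
    call_de,
    classify_sex_bias,
    ddct,
    filter_sex_chromosome,
    tpm_normalize,
)

SAMPLES = [f"{g}-{r}" for g in ("FNS", "FNB", "FYS", "M03", "M05", "M10")
           for r in (1, 2, 3)]
GROUPS = {s: s.split("-")[0] for s in SAMPLES}


def _cm(counts: pd.DataFrame, totals=None) -> CountMatrix:
    totals = totals or {s: max(1_000_000, int(counts[s].sum())) for s in counts}
    return CountMatrix(counts=counts, totals=totals,
                       groups={s: GROUPS[s] for s in counts.columns})


class TestTpm:
    def test_direct_formula(self):
        counts = pd.DataFrame({s: [5] for s in SAMPLES}, index=["m1"])
        cm = CountMatrix(counts=counts, totals={s: 500_000 for s in SAMPLES},
                         groups=GROUPS)
        assert (tpm_normalize(cm).loc["m1"] == 10.0).all()

    def test_zero_count_is_zero_tpm(self):
        counts = pd.DataFrame({s: [0] for s in SAMPLES}, index=["m1"])
        cm = CountMatrix(counts=counts, totals={s: 10 for s in SAMPLES}, groups=GROUPS)
        assert (tpm_normalize(cm).loc["m1"] == 0.0).all()

    def test_column_sums_to_1e6_when_totals_equal_column_sums(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, size=(50, len(SAMPLES))),
                              index=[f"m{i}" for i in range(50)], columns=SAMPLES)
        cm = CountMatrix(counts=counts,
                         totals={s: int(counts[s].sum()) for s in SAMPLES},
                         groups=GROUPS)
        assert np.allclose(tpm_normalize(cm).sum(axis=0), 1e6)

    def test_zero_total_raises_naming_sample(self):
        counts = pd.DataFrame({s: [0] for s in SAMPLES}, index=["m1"])
        cm = CountMatrix(counts=counts, totals={s: 0 for s in SAMPLES}, groups=GROUPS)
        with pytest.raises(ValueError, match="FNS-1"):
            tpm_normalize(cm)


class TestAcTest:
    def test_zero_zero_equal_libraries(self):
        r = ac_test(0, 0, 1e6, 1e6)
        assert r.C == pytest.approx(0.5)
        assert r.D == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)

    def test_closed_form_x10_y0(self):
        # p(0|x) = 2^-(x+1) at N1 == N2
        r = ac_test(10, 0, 1e6, 1e6)
        assert r.C == pytest.approx(2.0 ** -11, rel=1e-12)
        assert r.p == pytest.approx(2.0 ** -10, rel=1e-12)

    def test_matches_bruteforce_summation(self):
        r = ac_test(5, 20, 1e6, 1e6)
        C, D, p = ac_brute(5, 20, 1e6, 1e6)
        assert r.p == pytest.approx(p, rel=1e-9)
        assert r.C == pytest.approx(C, rel=1e-9)
        assert r.D == pytest.approx(D, rel=1e-9)

    def test_tail_overlap_invariant(self):
        for x, y in ((0, 0), (3, 7), (40, 12)):
            r = ac_test(x, y, 2e6, 1e6)
            assert 0 <= r.C <= 1 + 1e-12 and 0 <= r.D <= 1 + 1e-12
            assert r.C + r.D >= 1.0 - 1e-12

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 300), st.integers(0, 300),
           st.sampled_from([5e5, 1e6, 2e6]), st.sampled_from([5e5, 1e6, 2e6]))
    def test_exact_symmetry_under_condition_swap(self, x, y, N1, N2):
        assert ac_test(x, y, N1, N2).p == ac_test(y, x, N2, N1).p

    def test_rejects_non_integer_and_bad_totals(self):
        with pytest.raises(ValueError):
            ac_test(1.5, 2, 1e6, 1e6)
        with pytest.raises(ValueError):
            ac_test(1, 2, 0, 1e6)


class TestCallDe:
    def _counts(self, rows: dict) -> pd.DataFrame:
        return pd.DataFrame(rows, index=SAMPLES).T

    def test_identical_counts_not_de(self):
        counts = self._counts({"m1": [30] * 18})
        de = call_de(_cm(counts), "FNS", "M03")
        assert not de.loc["m1", "significant"]
        assert de.loc["m1", "log2fc"] == pytest.approx(0.0)

    def test_large_fold_but_tiny_counts_not_de(self):
        # pooled 1 vs 0 at huge depth: fold change passes, p does not
        row = [0] * 18
        row[SAMPLES.index("M03-1")] = 1
        de = call_de(_cm(self._counts({"m1": row})), "FNS", "M03")
        assert not de.loc["m1", "significant"]
        assert de.loc["m1", "p"] > 0.05

    def test_planted_fourfold_is_called_with_direction(self):
        rng = np.random.default_rng(1)
        rows = {}
        for i in range(50):
            f = rng.poisson(50, 9)
            m = rng.poisson(200, 9)
            rows[f"m{i}"] = list(f) + list(m)
        de = call_de(_cm(self._counts(rows)), "FNS", "M03")
        assert de["significant"].all()
        assert (de["direction"] == "up_in_b").all()

    def test_pooling_sums_replicates(self):
        counts = self._counts({"m1": list(range(18))})
        de = call_de(_cm(counts), "FNS", "M03")
        assert de.loc["m1", "x"] == 0 + 1 + 2
        assert de.loc["m1", "y"] == 9 + 10 + 11

    def test_empty_group_raises(self):
        counts = self._counts({"m1": [1] * 18})
        with pytest.raises(ValueError, match="empty group"):
            call_de(_cm(counts), "FNS", "NOPE")


class TestClassifySexBias:
    def _tables(self, verdicts):
        """verdicts: miRNA -> list of 'M'/'F'/None for the three pairs."""
        tables = {}
        for k, pair in enumerate(STAGE_PAIRS):
            rows = []
            for mid, vs in verdicts.items():
                v = vs[k]
                sig = v is not None
                direction = {"M": "up_in_b", "F": "up_in_a", None: "none"}[v]
                rows.append((sig, direction))
            tables[pair] = pd.DataFrame(
                rows, index=list(verdicts), columns=["significant", "direction"])
        return tables

    def _tpm(self, values: dict) -> pd.DataFrame:
        return pd.DataFrame(values, index=SAMPLES).T

    def test_male_specific_call(self):
        tables = self._tables({"m1": ["M", "M", "M"]})
        tpm = self._tpm({"m1": [0.0] * 9 + [50.0] * 9})
        calls = classify_sex_bias(tables, tpm, GROUPS)
        assert calls[0].label == "male-specific"

    def test_two_of_three_pairs_is_none(self):
        tables = self._tables({"m1": ["M", "M", None]})
        tpm = self._tpm({"m1": [0.0] * 9 + [50.0] * 9})
        assert classify_sex_bias(tables, tpm, GROUPS)[0].label == "none"

    def test_inconsistent_direction_is_none(self):
        tables = self._tables({"m1": ["M", "F", "M"]})
        tpm = self._tpm({"m1": [10.0] * 18})
        assert classify_sex_bias(tables, tpm, GROUPS)[0].label == "none"

    def test_biased_but_expressed_in_both_sexes(self):
        tables = self._tables({"m1": ["F", "F", "F"]})
        tpm = self._tpm({"m1": [80.0] * 9 + [10.0] * 9})
        assert classify_sex_bias(tables, tpm, GROUPS)[0].label == "female-biased"

    def test_missing_pair_raises(self):
        tables = self._tables({"m1": ["F", "F", "F"]})
        del tables[STAGE_PAIRS[2]]
        with pytest.raises(ValueError, match="missing"):
            classify_sex_bias(tables, self._tpm({"m1": [1.0] * 18}), GROUPS)

    def test_matches_bruteforce_set_logic_on_random_tables(self):
        rng = np.random.default_rng(9)
        mids = [f"m{i}" for i in range(400)]
        verdicts = {m: [rng.choice(["M", "F", None]) for _ in range(3)]
                    for m in mids}
        tpm = self._tpm({m: list(rng.uniform(0, 3, size=18)) for m in mids})
        calls = {c.mirna: c.label
                 for c in classify_sex_bias(self._tables(verdicts), tpm, GROUPS)}
        female = [s for s in SAMPLES if s.startswith("F")]
        male = [s for s in SAMPLES if not s.startswith("F")]
        for m in mids:
            vs = verdicts[m]
            if all(v == "M" for v in vs):
                expect = "male-specific" if (tpm.loc[m, female] < 1.0).all() \
                    else "male-biased"
            elif all(v == "F" for v in vs):
                expect = "female-specific" if (tpm.loc[m, male] < 1.0).all() \
                    else "female-biased"
            else:
                expect = "none"
            assert calls[m] == expect, m

    def test_invariant_to_sample_column_order(self):
        rng = np.random.default_rng(3)
        mids = [f"m{i}" for i in range(30)]
        verdicts = {m: [rng.choice(["M", "F", None])] * 3 for m in mids}
        tables = self._tables(verdicts)
        tpm = self._tpm({m: list(rng.uniform(0, 3, size=18)) for m in mids})
        shuffled = tpm[list(reversed(SAMPLES))]
        c1 = [(c.mirna, c.label) for c in classify_sex_bias(tables, tpm, GROUPS)]
        c2 = [(c.mirna, c.label) for c in classify_sex_bias(tables, shuffled, GROUPS)]
        assert c1 == c2


class TestFilterSexChromosome:
    def test_subset_property(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({"p": rng.uniform(size=40)},
                             index=[f"m{i}" for i in range(40)])
        chrom = {f"m{i}": ("chr4" if i % 3 == 0 else "chr1") for i in range(40)}
        sub = filter_sex_chromosome(table, chrom, "chr4")
        assert set(sub.index) == {m for m in table.index if chrom[m] == "chr4"}
        assert sub.index.isin(table.index).all()

    def test_empty_when_no_mirna_on_sex_chromosome(self):
        table = pd.DataFrame({"p": [0.1]}, index=["m0"])
        assert len(filter_sex_chromosome(table, {"m0": "chr1"}, "chr4")) == 0

    def test_unknown_chromosome_name_raises(self):
        table = pd.DataFrame({"p": [0.1]}, index=["m0"])
        with pytest.raises(ValueError, match="chrX"):
            filter_sex_chromosome(table, {"m0": "chr1"}, "chrX",
                                  known_chromosomes={"chr1", "chr4"})


class TestDdct:
    @pytest.mark.parametrize("tt,rt,tc,rc,expected", [
        (20.0, 20.0, 20.0, 20.0, 1.0),     # ddCt = 0
        (19.0, 20.0, 20.0, 20.0, 2.0),     # ddCt = -1
        (25.0, 20.0, 22.0, 20.0, 0.125),   # ddCt = 3
    ])
    def test_reference_values(self, tt, rt, tc, rc, expected):
        inp = DdCtInput(ct_target_treated=tt, ct_reference_treated=rt,
                        ct_target_control=tc, ct_reference_control=rc)
        assert ddct(inp) == pytest.approx(expected)

    def test_missing_ct_rejected(self):
        with pytest.raises(ValueError):
            DdCtInput(ct_target_treated=math.nan, ct_reference_treated=20,
                      ct_target_control=20, ct_reference_control=20)
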