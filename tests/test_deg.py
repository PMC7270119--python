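"""Signed fold change, DEG calling and the cross-intersection set logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetexpress.datasets import LILY_DEG_COUNTS, example_deg_sets
from hetexpress.deg import (
    call_degs,
    common_degs_per_cross,
    library_correlation,
    signed_fold_change,
    universal_degs,
)
from hetexpress.io import DataError, ExpressionMatrix, TrioDesign


class TestSignedFoldChange:
    def test_equal_inputs_give_one(self):
        assert signed_fold_change(10, 10, 0.01) == 1.0

    def test_direct_arithmetic(self):
        assert signed_fold_change(8, 2, 0.01) == pytest.approx(8.01 / 2.01)
        assert signed_fold_change(2, 8, 0.01) == pytest.approx(-8.01 / 2.01)

    def test_zero_handled_by_pseudocount(self):
        assert signed_fold_change(1, 0, 0.01) == pytest.approx(1.01 / 0.01)

    nonneg = st.floats(min_value=0, max_value=1e5, allow_nan=False)

    @given(a=nonneg, b=nonneg)
    @settings(max_examples=300, derandomize=True)
    def test_antisymmetry_and_gap(self, a, b):
        fc = signed_fold_change(a, b, 0.01)
        assert abs(fc) >= 1
        # antisymmetry is defined on the pseudocounted operands
        if a + 0.01 != b + 0.01:
            assert signed_fold_change(b, a, 0.01) == pytest.approx(-fc, rel=1e-12)
        else:
            assert fc == 1.0


class TestCallDegs:
    def test_two_calls_per_gene_in_gene_order(self, small_matrix, trio_a):
        calls = call_degs(small_matrix, trio_a)
        assert len(calls) == 2 * 3
        assert [c.gene_id for c in calls[:2]] == ["g_up", "g_up"]
        assert calls[0].comparison == ("A_F1", "A_P1")
        assert calls[1].comparison == ("A_F1", "A_P2")

    def test_up_down_and_mixed(self, small_matrix, trio_a):
        calls = {(c.gene_id, c.comparison[1]): c.call for c in call_degs(small_matrix, trio_a)}
        assert calls[("g_up", "A_P1")] == "up" and calls[("g_up", "A_P2")] == "up"
        assert calls[("g_down", "A_P1")] == "down" and calls[("g_down", "A_P2")] == "down"
        assert calls[("g_mixed", "A_P1")] == "up" and calls[("g_mixed", "A_P2")] == "down"

    def test_equal_abundances_are_ns(self, trio_a):
        values = pd.DataFrame(
            {"A_P1": [10.0], "A_F1": [10.0], "A_P2": [10.0]}, index=["g"]
        )
        calls = call_degs(ExpressionMatrix(values), trio_a)
        assert {c.call for c in calls} == {"ns"}

    def test_thresholds_inclusive(self, trio_a):
        # unit pseudocount makes the ratio exactly 2: a call, not ns
        values = pd.DataFrame(
            {"A_P1": [1.0], "A_F1": [3.0], "A_P2": [1.0]}, index=["g"]
        )
        calls = call_degs(ExpressionMatrix(values, pseudocount=1.0), trio_a)
        assert all(c.signed_fc == 2.0 and c.call == "up" for c in calls)

    def test_monotone_in_threshold(self, small_matrix, trio_a):
        loose = sum(c.call == "up" for c in call_degs(small_matrix, trio_a, up_threshold=2))
        tight = sum(c.call == "up" for c in call_degs(small_matrix, trio_a, up_threshold=5))
        assert tight <= loose

    def test_unknown_genotype_raises(self, small_matrix):
        rogue = TrioDesign("Z", "A_P1", "A_P2", "nope")
        with pytest.raises(DataError, match="unknown genotype"):
            call_degs(small_matrix, rogue)

    def test_min_abundance_floor_silences_low_genes(self, trio_a):
        values = pd.DataFrame(
            {"A_P1": [0.01], "A_F1": [0.2], "A_P2": [0.01]}, index=["g"]
        )
        loud = call_degs(ExpressionMatrix(values), trio_a)
        quiet = call_degs(ExpressionMatrix(values), trio_a, min_abundance=1.0)
        assert {c.call for c in loud} == {"up"}
        assert {c.call for c in quiet} == {"ns"}


class TestCommonSets:
    def test_fixture_counts(self, trio_a):
        # 10 genes: 3 up-up, 2 down-down, 5 mixed/ns
        rows = {
            "up1": (10, 40, 10), "up2": (5, 25, 6), "up3": (1, 8, 2),
            "dn1": (40, 10, 40), "dn2": (9, 3, 8),
            "mx1": (10, 40, 100), "mx2": (100, 40, 10),
            "ns1": (10, 15, 10), "ns2": (10, 10, 10), "ns3": (8, 4.5, 9),
        }
        values = pd.DataFrame(
            {
                "A_P1": [v[0] for v in rows.values()],
                "A_F1": [v[1] for v in rows.values()],
                "A_P2": [v[2] for v in rows.values()],
            },
            index=list(rows),
        )
        calls = call_degs(ExpressionMatrix(values), trio_a)
        up, down = common_degs_per_cross(calls, trio_a)
        assert up == {"up1", "up2", "up3"}
        assert down == {"dn1", "dn2"}

    def test_up_vs_one_parent_only_is_excluded(self, small_matrix, trio_a):
        calls = call_degs(small_matrix, trio_a)
        up, down = common_degs_per_cross(calls, trio_a)
        assert "g_mixed" not in up and "g_mixed" not in down


class TestUniversalSets:
    def test_simple_intersections(self):
        sets = universal_degs(({"g1", "g2"}, set()), ({"g2", "g3"}, set()))
        assert sets.universal_up == {"g2"}
        sets = universal_degs(({"g1"}, set()), (set(), {"g1"}))
        assert sets.discordant == {"g1"}

    def test_same_cross_up_and_down_is_integrity_error(self):
        with pytest.raises(DataError, match="both up and down"):
            universal_degs(({"g1"}, {"g1"}), (set(), set()))

    def test_published_venn_structure(self):
        """The printed per-cross common counts and overlaps give 703 unique genes."""
        a_sets, b_sets = example_deg_sets()
        assert (len(a_sets[0]), len(a_sets[1])) == (276, 189)
        assert (len(b_sets[0]), len(b_sets[1])) == (137, 135)
        sets = universal_degs(a_sets, b_sets)
        assert len(sets.universal_up) == LILY_DEG_COUNTS["overlap"]["concordant_up"] == 11
        assert len(sets.universal_down) == LILY_DEG_COUNTS["overlap"]["concordant_down"] == 7
        assert len(sets.discordant) == 16
        assert sets.unique_union_count == 703

    @given(data=st.data())
    @settings(max_examples=100, derandomize=True)
    def test_inclusion_exclusion_on_random_sets(self, data):
        genes = [f"g{i}" for i in range(30)]
        def subset():
            return set(data.draw(st.sets(st.sampled_from(genes))))
        a_up = subset()
        a_down = subset() - a_up
        b_up = subset()
        b_down = subset() - b_up
        sets = universal_degs((a_up, a_down), (b_up, b_down))
        a_all, b_all = a_up | a_down, b_up | b_down
        assert sets.unique_union_count == len(a_all) + len(b_all) - len(a_all & b_all)
        assert sets.universal_up <= a_up and sets.universal_up <= b_up
        assert sets.universal_down <= a_down and sets.universal_down <= b_down
        for x, y in [
            (sets.universal_up, sets.universal_down),
            (sets.universal_up, sets.discordant),
            (sets.universal_down, sets.discordant),
        ]:
            assert not (x & y)


class TestLibraryCorrelation:
    def test_self_and_scaled_columns(self, trio_a):
        base = np.array([1.0, 4.0, 16.0, 3.0])
        values = pd.DataFrame(
            {"A_P1": base, "A_F1": base, "A_P2": 2 * base},
            index=[f"g{i}" for i in range(4)],
        )
        corr = library_correlation(ExpressionMatrix(values, pseudocount=1e-9))
        assert corr.loc["A_P1", "A_P1"] == 1.0
        assert corr.loc["A_P1", "A_F1"] == pytest.approx(1.0)
        # doubling is additive on the log scale: correlation still 1
        assert corr.loc["A_P1", "A_P2"] == pytest.approx(1.0)
        assert ((corr.values >= -1 - 1e-12) & (corr.values <= 1 + 1e-12)).all()

    def test_hand_computed_pearson(self, trio_a):
        values = pd.DataFrame(
            {"A_P1": [1.0, 2.0, 4.0], "A_F1": [4.0, 2.0, 1.0], "A_P2": [1.0, 1.0, 1.0]},
            index=["g1", "g2", "g3"],
        )
        mat = ExpressionMatrix(values, pseudocount=1e-9)
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = library_correlation(mat)
        # log2 columns are (0,1,2) and (2,1,0): perfectly anti-ordered
        assert corr.loc["A_P1", "A_F1"] == pytest.approx(-1.0)
        assert np.isnan(corr.loc["A_P1", "A_P2"])
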