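import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from httcag.cohort_stats import (
    GroupSummary,
    bonferroni_threshold,
    classify_allele,
    compare_to_controls,
    exclude_intermediate_carriers,
    intermediate_carrier_tally,
    pooled_t_test,
    sum_of_repeats,
    summarize_group,
    table_one,
)
from httcag.synthetic_cohort import Genotype


def reference_pooled_t(m1, s1, n1, m2, s2, n2):
    """Textbook pooled two-sample t-test, coded independently of the package."""
    from scipy.stats import t as tdist

    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


class TestClassifyAllele:
    @pytest.mark.parametrize(
        "cag,expected",
        [
            (1, "normal"),
            (26, "normal"),
            (27, "intermediate"),
            (35, "intermediate"),
            (36, "incomplete_penetrance"),
            (39, "incomplete_penetrance"),
            (40, "full_penetrance"),
            (120, "full_penetrance"),
        ],
    )
    def test_band_boundaries(self, cag, expected):
        assert classify_allele(cag) == expected

    def test_partition_of_1_to_100_has_no_gaps_or_overlaps(self):
        # every integer lands in exactly one class and bands are contiguous
        classes = [classify_allele(c) for c in range(1, 101)]
        changes = [
            c for c, prev, cur in zip(range(2, 101), classes, classes[1:]) if prev != cur
        ]
        assert changes == [27, 36, 40]

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_allele(0)


class TestSumOfRepeats:
    def test_sum_and_homozygote_counted_twice(self):
        assert sum_of_repeats(Genotype("s", "g", 17, 18)) == 35
        assert sum_of_repeats(Genotype("s", "g", 17, 17)) == 34


class TestSummarizeGroup:
    def test_closed_form(self):
        s = summarize_group([34, 36], "g")
        assert s.mean == pytest.approx(35.0)
        assert s.sd == pytest.approx(math.sqrt(2))

    def test_constant_sequence_sd_zero(self):
        assert summarize_group([34, 34, 34], "g").sd == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([34], "g")

    def test_two_decimal_display_convention(self):
        vals = np.array([36, 41, 33, 38, 35, 40, 37, 36])
        s = summarize_group(vals, "g")
        assert round(s.mean, 2) == pytest.approx(37.0)
        assert f"{round(s.mean, 2):.2f} ± {round(s.sd, 1)}" == "37.00 ± 2.6"


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 5, 0.01)])
    def test_direct_division(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_three_comparisons_displays_0017(self):
        assert f"{bonferroni_threshold(0.05, 3):.3f}" == "0.017"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 3)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestPooledTTest:
    def test_identical_groups_t_zero_p_one(self):
        g = GroupSummary("a", 10, 36.0, 4.0)
        res = pooled_t_test(g, GroupSummary("b", 10, 36.0, 4.0))
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a = GroupSummary("a", 12, 35.0, 3.0)
        b = GroupSummary("b", 20, 37.0, 4.0)
        ab = pooled_t_test(a, b)
        ba = pooled_t_test(b, a)
        assert ab.t == pytest.approx(-ba.t)
        assert ab.p == pytest.approx(ba.p)
        assert ab.ci_low == pytest.approx(-ba.ci_high)
        assert ab.ci_high == pytest.approx(-ba.ci_low)

    def test_zero_variance_flags(self):
        a = GroupSummary("a", 5, 36.0, 0.0)
        same = pooled_t_test(a, GroupSummary("b", 5, 36.0, 0.0))
        assert same.p == 1.0 and "zero-pooled-variance" in same.flags
        diff = pooled_t_test(a, GroupSummary("b", 5, 38.0, 0.0))
        assert "degenerate-zero-variance-unequal-means" in diff.flags

    @settings(max_examples=200, derandomize=True)
    @given(
        m1=st.floats(20, 60),
        m2=st.floats(20, 60),
        s1=st.floats(0.5, 10),
        s2=st.floats(0.5, 10),
        n1=st.integers(2, 600),
        n2=st.integers(2, 600),
    )
    def test_agrees_with_independent_reference(self, m1, m2, s1, s2, n1, n2):
        a = GroupSummary("a", n1, m1, s1)
        b = GroupSummary("b", n2, m2, s2)
        res = pooled_t_test(a, b)
        t_ref, p_ref = reference_pooled_t(m1, s1, n1, m2, s2, n2)
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_published_group_summaries_are_significant(self):
        # case group n=60 mean 35.40 sd 3.6 vs controls n=559 mean 36.89 sd 4.5
        res = pooled_t_test(
            GroupSummary("MLH1", 60, 35.40, 3.6),
            GroupSummary("controls", 559, 36.89, 4.5),
            alpha=0.05,
            m_comparisons=3,
        )
        assert res.p < 0.017
        assert res.significant


def example_cohort():
    rows = []
    data = {
        "controls": [(17, 17)] * 3 + [(17, 30)],
        "MLH1": [(15, 20), (17, 18), (16, 28)],
    }
    for group, pairs in data.items():
        for i, (a, b) in enumerate(pairs):
            rows.append(
                {
                    "sample_id": f"{group}-{i}",
                    "group": group,
                    "allele_a": a,
                    "allele_b": b,
                }
            )
    return pd.DataFrame(rows)


class TestCarrierOperations:
    def test_tally_counts_and_percent(self):
        tally = intermediate_carrier_tally(example_cohort()).set_index("group")
        assert tally.loc["controls", "carriers"] == 1
        assert tally.loc["controls", "percent"] == 25.0
        assert tally.loc["MLH1", "carriers"] == 1
        assert tally.loc["MLH1", "percent"] == pytest.approx(33.3)

    def test_zero_carriers_gives_zero_percent(self):
        df = example_cohort()
        df = df[~(df["allele_b"] >= 27)]
        tally = intermediate_carrier_tally(df).set_index("group")
        assert (tally["percent"] == 0.0).all()

    def test_exclusion_removes_every_carrier(self):
        reduced = exclude_intermediate_carriers(example_cohort())
        assert len(reduced) == 5
        assert not (
            ((reduced["allele_a"] >= 27) & (reduced["allele_a"] <= 35))
            | ((reduced["allele_b"] >= 27) & (reduced["allele_b"] <= 35))
        ).any()

    def test_exclusion_no_carriers_is_identity(self):
        df = example_cohort()
        df = df[df["allele_b"] <= 26].reset_index(drop=True)
        pd.testing.assert_frame_equal(exclude_intermediate_carriers(df), df)


class TestTables:
    def test_table_one_layout_and_without_ia_rows(self):
        t = table_one(example_cohort())
        assert list(t.columns) == [
            "group",
            "analysis",
            "n",
            "mean_sum",
            "sd_sum",
            "carriers",
            "carrier_pct",
        ]
        without = t[t["analysis"] == "without_ia"].set_index("group")
        assert without.loc["controls", "n"] == 3
        assert without.loc["MLH1", "n"] == 2

    def test_compare_to_controls_shapes_and_threshold(self):
        out = compare_to_controls(example_cohort(), m_comparisons=3)
        assert set(out["analysis"]) == {"all", "without_ia"}
        primary = out[out["analysis"] == "all"].iloc[0]
        assert primary["alpha_adjusted"] == pytest.approx(0.05 / 3)
        sensitivity = out[out["analysis"] == "without_ia"].iloc[0]
        assert sensitivity["alpha_adjusted"] == pytest.approx(0.05)

    def test_missing_control_label_rejected(self):
        with pytest.raises(ValueError):
            compare_to_controls(example_cohort(), control_label="nope")
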