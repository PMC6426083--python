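import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from dtukit.stats import (
    DegenerateTableError,
    bh_adjust,
    classify,
    find_switches,
    g_test,
    gene_effect_size,
    gene_level_test,
    isoform_proportions,
    transcript_level_test,
)


class TestGTest:
    def test_perfect_independence(self):
        g, df, p = g_test([[10, 10], [10, 10]])
        assert g == 0.0
        assert df == 1
        assert p == 1.0

    def test_complete_dependence(self):
        g, df, p = g_test([[100, 0], [0, 100]])
        assert g == pytest.approx(400 * np.log(2), rel=1e-12)
        assert df == 1
        assert p < 1e-60

    def test_proportional_columns_give_zero(self):
        g, df, p = g_test([[20, 40], [30, 60], [5, 10]])
        assert g == pytest.approx(0.0, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_zero_rows_dropped_before_df(self):
        g_full, df_full, p_full = g_test([[5, 7], [0, 0], [3, 2]])
        g_red, df_red, p_red = g_test([[5, 7], [3, 2]])
        assert g_full == pytest.approx(g_red)
        assert df_full == df_red == 1
        assert p_full == pytest.approx(p_red)

    def test_degenerate_table_raises(self):
        with pytest.raises(DegenerateTableError, match="degenerate"):
            g_test([[5, 7], [0, 0]])

    def test_matches_independent_likelihood_ratio_oracle(self):
        """1,000 random k x 2 integer tables agree with scipy's generic
        log-likelihood contingency computation to 1e-10."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            k = rng.integers(2, 7)
            table = rng.integers(0, 51, size=(k, 2))
            if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
                continue
            res = scipy.stats.chi2_contingency(
                table, correction=False, lambda_="log-likelihood"
            )
            g, df, p = g_test(table)
            assert g == pytest.approx(res.statistic, abs=1e-10)
            assert df == res.dof
            assert p == pytest.approx(res.pvalue, abs=1e-10)
            checked += 1

    @given(
        st.lists(
            st.tuples(st.integers(1, 500), st.integers(1, 500)),
            min_size=2,
            max_size=6,
        ),
        st.integers(2, 20),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_g_scales_linearly_at_fixed_proportions(self, rows, factor):
        """Multiplying both columns by c multiplies G by c exactly."""
        table = np.array(rows, dtype=float)
        g1, df1, _ = g_test(table)
        g2, df2, _ = g_test(table * factor)
        assert df1 == df2
        assert g2 == pytest.approx(factor * g1, rel=1e-9, abs=1e-9)

    @given(
        st.lists(st.floats(0.01, 1000), min_size=2, max_size=6),
        st.floats(0.1, 10),
        st.floats(0.1, 10),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_nonnegative_and_zero_iff_proportional(self, rows, ca, cb):
        """G >= 0 always, and G = 0 when the columns are proportional."""
        r = np.array(rows)
        table = np.column_stack([r * ca, r * cb])
        g, _, p = g_test(table)
        # p = chi2.sf(g, 1) ~ 1 - sqrt(2g/pi) near g = 0, so its distance
        # from 1 scales as sqrt(g)
        assert g == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-3)


class TestLevelTests:
    def test_gene_level_proportional_columns(self):
        g, _, p = gene_level_test([[20, 40], [30, 60]])
        assert g == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_gene_level_matches_oracle(self):
        table = [[50, 10], [30, 30], [20, 60]]
        res = scipy.stats.chi2_contingency(
            table, correction=False, lambda_="log-likelihood"
        )
        g, df, p = gene_level_test(table)
        assert g == pytest.approx(res.statistic, abs=1e-10)
        assert (df, p) == (res.dof, pytest.approx(res.pvalue, abs=1e-12))

    def test_transcript_level_no_change(self):
        g, df, p = transcript_level_test((30, 30), (70, 70))
        assert (g, df, p) == (0.0, 1, 1.0)

    def test_transcript_level_is_a_2x2_g_test(self):
        assert transcript_level_test((80, 20), (20, 80)) == g_test([[80, 20], [20, 80]])

    def test_two_isoform_gene_levels_coincide(self):
        """For a 2-isoform gene the transcript-level table is the gene-level
        table up to row order, so G, df and p are identical."""
        table = [[83, 21], [17, 70]]
        gg = gene_level_test(table)
        t1 = transcript_level_test((83, 21), (17, 70))
        t2 = transcript_level_test((17, 70), (83, 21))
        for tx in (t1, t2):
            assert tx[0] == pytest.approx(gg[0], rel=1e-12)
            assert tx[1] == gg[1]
            assert tx[2] == pytest.approx(gg[2], rel=1e-12)


class TestBhAdjust:
    def test_single_value_is_identity(self):
        assert bh_adjust([0.04]).tolist() == [0.04]

    def test_step_up_cumulative_min(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_statsmodels_under_permutation(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=137)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)
        perm = rng.permutation(p.size)
        np.testing.assert_allclose(bh_adjust(p[perm]), expected[perm], rtol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_outputs_bounded_and_monotone_on_sorted_input(self, ps):
        q = bh_adjust(sorted(ps))
        assert np.all(q <= 1.0)
        assert np.all(np.diff(q) >= 0)
        assert np.all(q >= sorted(ps))

    @pytest.mark.parametrize("bad", [[-0.1], [1.5], [float("nan")]])
    def test_rejects_values_outside_unit_interval(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


class TestProportions:
    def test_dprop_arithmetic(self):
        out = isoform_proportions([[70, 20], [30, 80]])
        np.testing.assert_allclose(out[0], [0.7, 0.2, -0.5])

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(3)
        table = rng.uniform(0.1, 50, size=(5, 2))
        out = isoform_proportions(table)
        assert out[:, 0].sum() == pytest.approx(1.0, abs=1e-12)
        assert out[:, 1].sum() == pytest.approx(1.0, abs=1e-12)

    def test_full_swap_of_two_isoforms(self):
        # proportions (0.8, 0.2) swapped in condition B
        out = isoform_proportions([[80, 20], [20, 80]])
        np.testing.assert_allclose(out[:, 2], [-0.6, 0.6])

    def test_zero_column_total_raises(self):
        with pytest.raises(DegenerateTableError):
            isoform_proportions([[0, 5], [0, 5]])


class TestGeneEffectSize:
    @pytest.mark.parametrize(
        "dprops,expected",
        [([-0.6, 0.6], 0.6), ([0.0, 0.0, 0.0], 0.0), ([0.1, -0.3, 0.2], 0.3)],
    )
    def test_max_absolute_dprop(self, dprops, expected):
        assert gene_effect_size(dprops) == pytest.approx(expected)

    def test_two_isoform_symmetry(self):
        out = isoform_proportions([[75, 30], [25, 70]])
        assert gene_effect_size(out[:, 2]) == pytest.approx(abs(out[0, 2]))
        assert gene_effect_size(out[:, 2]) == pytest.approx(abs(out[1, 2]))


class TestClassify:
    def test_significant_and_large_effect_is_called(self):
        cls = classify([True], [0.01], [0.5], alpha=0.05, dprop_threshold=0.2)
        assert cls.dtu_call.tolist() == [True]
        assert cls.rejection_cause.tolist() == ["none"]

    def test_significant_but_small_effect_rejected(self):
        cls = classify([True], [0.01], [0.1], alpha=0.05, dprop_threshold=0.2)
        assert cls.dtu_call.tolist() == [False]
        assert cls.rejection_cause.tolist() == ["small_effect"]

    def test_cause_order(self):
        cls = classify(
            [False, True, True],
            [np.nan, 0.5, 0.001],
            [np.nan, 0.9, 0.05],
            alpha=0.05,
            dprop_threshold=0.2,
        )
        assert cls.rejection_cause.tolist() == [
            "ineligible",
            "not_significant",
            "small_effect",
        ]

    def test_call_set_shrinks_with_effect_threshold(self, sim_dtu):
        """Raising the Dprop threshold through the explored values never adds
        calls on fixed data."""
        from dtukit.model import align
        from dtukit.engine import point_run

        data, _ = sim_dtu
        ax = align(data)
        previous = None
        for thr in (0.05, 0.1, 0.2):
            res = point_run(ax, 0.0, 0.05, thr)
            called = set(ax.gene_ids[res.gene_call])
            if previous is not None:
                assert called <= previous
            previous = called


class TestFindSwitches:
    def test_dominant_isoform_change_reported(self):
        rows = find_switches(
            ["g1", "g1"], ["t1", "t2"], [0.8, 0.2], [0.3, 0.7]
        )
        assert rows == [("g1", "t1", "t2", False)]

    def test_identical_proportions_no_switch(self):
        assert find_switches(["g1", "g1"], ["t1", "t2"], [0.8, 0.2], [0.8, 0.2]) == []

    def test_tie_flagged_and_broken_lexicographically(self):
        rows = find_switches(
            ["g1", "g1"], ["t2", "t1"], [0.5, 0.5], [0.2, 0.8]
        )
        assert rows == []  # lexicographic winner t1 dominates both conditions
        rows = find_switches(
            ["g1", "g1"], ["t2", "t1"], [0.5, 0.5], [0.8, 0.2]
        )
        assert rows == [("g1", "t1", "t2", True)]
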