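"""Statistical kernel: frozen hand examples, reference-implementation
oracles, and distributional/property invariants."""

import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from tknet.errors import DegenerateInputError
from tknet.stats import (
    bh_fdr,
    fisher_combined,
    one_proportion_test,
    pearson_corr,
    rank_ascending,
    spearman_corr,
    two_group_test,
)

finite_floats = st.floats(-1e6, 1e6, allow_nan=False)


class TestTwoGroupTest:
    def test_identical_samples_give_zero_statistic_unit_p(self):
        res = two_group_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_welch_reference(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]
        res = two_group_test(x, y)
        ref_t, ref_p = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic < 0
        assert res.statistic == pytest.approx(ref_t, abs=1e-12)
        assert res.p_value == pytest.approx(ref_p, abs=1e-12)

    def test_pooled_variant_matches_student_reference(self, rng):
        x, y = rng.normal(0, 1, 6), rng.normal(1, 2, 9)
        res = two_group_test(x, y, equal_var=True)
        ref_t, ref_p = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(ref_t, abs=1e-12)
        assert res.p_value == pytest.approx(ref_p, abs=1e-12)
        assert res.df == len(x) + len(y) - 2

    def test_both_constant_raises_naming_feature(self):
        with pytest.raises(DegenerateInputError, match="otu7"):
            two_group_test([0, 0, 0], [0, 0, 0], name="otu7")

    def test_short_sample_rejected(self):
        with pytest.raises(ValueError):
            two_group_test([1.0], [1.0, 2.0])


class TestBhFdr:
    def test_single_test_unchanged(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_step_up_hand_example(self):
        # q_(i) = min over j >= i of p_(j) * n / j
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_inputs_unchanged(self):
        assert bh_fdr([0.2] * 7) == pytest.approx([0.2] * 7)

    def test_empty_input_gives_empty_output(self):
        assert bh_fdr([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_statsmodels_reference(self, rng):
        p = rng.uniform(0, 1, 200)
        ref = multipletests(p, method="fdr_bh")[1]
        assert bh_fdr(p) == pytest.approx(ref, abs=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_q_dominates_p_and_permutation_equivariance(self, p):
        q = bh_fdr(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        assert ((q >= 0) & (q <= 1)).all()
        perm = np.argsort(np.argsort(p, kind="mergesort"))  # some permutation
        assert bh_fdr(np.asarray(p)[np.argsort(p, kind="mergesort")])[
            perm
        ] == pytest.approx(q)


class TestFisherCombined:
    def test_all_ones_no_evidence(self):
        res = fisher_combined([1, 1, 1, 1])
        assert res.chi2 == 0.0
        assert res.p_combined == pytest.approx(1.0)
        assert res.df == 8 and res.k == 4

    def test_k1_is_identity(self):
        for p in np.logspace(-6, 0, 25):
            assert fisher_combined([p]).p_combined == pytest.approx(p, abs=1e-10)

    def test_hand_example_and_scipy_oracle(self):
        res = fisher_combined([0.05] * 4)
        assert res.chi2 == pytest.approx(-8.0 * math.log(0.05), abs=1e-12)
        stat, p = sps.combine_pvalues([0.05] * 4, method="fisher")
        assert res.chi2 == pytest.approx(stat, abs=1e-10)
        assert res.p_combined == pytest.approx(p, abs=1e-10)

    def test_monotone_in_each_p(self, rng):
        for _ in range(200):
            p = rng.uniform(0.01, 1.0, rng.integers(2, 6))
            base = fisher_combined(p).p_combined
            i = rng.integers(p.size)
            p[i] *= rng.uniform(0.1, 0.999)
            assert fisher_combined(p).p_combined <= base + 1e-12

    def test_zero_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            res = fisher_combined([0.0, 0.5])
        assert np.isfinite(res.chi2)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_combined([0.5, 1.2])


class TestCorrelations:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_corr(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_corr(x, -x).statistic == pytest.approx(-1.0)

    def test_pearson_matches_scipy(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 6]
        res = pearson_corr(x, y)
        ref = sps.pearsonr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_spearman_monotone_extremes_and_tie_handling(self):
        assert spearman_corr([1, 2, 5, 9], [2, 4, 5, 20]).statistic == pytest.approx(1.0)
        assert spearman_corr([1, 2, 5], [5, 3, -1]).statistic == pytest.approx(-1.0)
        x, y = [1, 2, 2, 3], [10, 20, 20, 40]
        ref = sps.spearmanr(x, y)
        res = spearman_corr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        # and equals Pearson on tie-averaged ranks by construction
        assert res.statistic == pytest.approx(
            pearson_corr(rank_ascending(x), rank_ascending(y)).statistic
        )

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_corr([1, 1, 1], [1, 2, 3])

    @given(
        st.lists(st.integers(-(10**6), 10**6), min_size=4, max_size=12, unique=True),
        st.floats(0.1, 50),
        st.floats(-100, 100),
    )
    def test_symmetry_and_affine_invariance(self, xs, a, b):
        y = np.linspace(0, 1, len(xs)) ** 2  # fixed nonconstant partner
        x = np.asarray(xs, dtype=float)
        r_xy = pearson_corr(x, y).statistic
        assert pearson_corr(y, x).statistic == pytest.approx(r_xy, abs=1e-9)
        assert pearson_corr(a * x + b, y).statistic == pytest.approx(r_xy, abs=1e-6)
        rho = spearman_corr(x, y).statistic
        assert spearman_corr(np.exp(x / 1e6), y).statistic == pytest.approx(
            rho, abs=1e-9
        )  # strictly monotone transform


class TestOneProportion:
    def test_single_bernoulli_less(self):
        assert one_proportion_test(0, 1, 0.5, "less").p_value == pytest.approx(0.5)

    def test_all_successes_greater_tail(self):
        res = one_proportion_test(69, 69, 0.5, "greater")
        assert res.p_value == pytest.approx(0.5**69, rel=1e-9)

    def test_matches_scipy_binomtest_all_alternatives(self):
        for k, n, p0 in [(3, 10, 0.5), (9, 12, 0.3), (0, 8, 0.6)]:
            for alt, scipy_alt in [
                ("two_sided", "two-sided"),
                ("greater", "greater"),
                ("less", "less"),
            ]:
                ours = one_proportion_test(k, n, p0, alt).p_value
                ref = sps.binomtest(k, n, p0, alternative=scipy_alt).pvalue
                assert ours == pytest.approx(ref, rel=1e-9), (k, n, p0, alt)

    def test_greater_equals_bruteforce_for_all_small_n(self):
        for n in range(1, 21):
            for k in range(n + 1):
                brute = sum(math.comb(n, j) * 0.5**n for j in range(k, n + 1))
                assert one_proportion_test(k, n, 0.5, "greater").p_value == pytest.approx(
                    brute, rel=1e-12
                )

    def test_invalid_successes_rejected(self):
        with pytest.raises(ValueError):
            one_proportion_test(5, 4, 0.5)


class TestRankAscending:
    def test_hand_examples(self):
        assert rank_ascending([10, 20, 30]) == pytest.approx([1, 2, 3])
        assert rank_ascending([3, 1, 3]) == pytest.approx([2.5, 1, 2.5])
        assert rank_ascending([7, 7, 7, 7]) == pytest.approx([2.5] * 4)
        assert rank_ascending([]).size == 0

    @given(st.lists(st.floats(-1e9, 1e9, allow_nan=False), min_size=1, max_size=40))
    def test_matches_scipy_rankdata_and_sums(self, values):
        ours = rank_ascending(values)
        assert ours == pytest.approx(sps.rankdata(values, method="average"))
        n = len(values)
        assert ours.sum() == pytest.approx(n * (n + 1) / 2)
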