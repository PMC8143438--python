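"""Rank statistics against closed forms, enumeration and library oracles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from dermtrack.errors import ComputationError
from dermtrack.stats import (
    dunn_posthoc,
    holm_sidak,
    kruskal_wallis,
    mann_whitney,
    welch_t_battery,
)


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0
        assert r.p_value == pytest.approx(0.1)
        assert "exact" in r.method

    def test_identical_samples_give_p_one(self):
        r = mann_whitney([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert r.p_value == 1.0

    def test_two_sided_symmetry(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(3, 12))
            y = rng.normal(size=rng.integers(3, 12))
            assert mann_whitney(x, y).p_value == pytest.approx(
                mann_whitney(y, x).p_value, rel=1e-12)

    def test_exact_agrees_with_scipy_small_tie_free(self):
        """Exhaustive check of every tie-free rank configuration, n <= 5."""
        for n1 in range(1, 6):
            for n2 in range(n1, 6):
                n = n1 + n2
                for idx in combinations(range(n), n1):
                    pooled = np.arange(1.0, n + 1)
                    x = pooled[list(idx)]
                    y = np.delete(pooled, list(idx))
                    ours = mann_whitney(x, y, mode="exact").p_value
                    ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                           method="exact").pvalue
                    assert ours == pytest.approx(ref, rel=1e-12)

    def test_normal_approx_close_to_scipy_asymptotic(self, rng):
        x = rng.normal(0, 1, size=30)
        y = rng.normal(0.5, 1, size=25)
        ours = mann_whitney(x, y, mode="normal_approx").p_value
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_handles_ties_via_corrected_variance(self, rng):
        x = rng.integers(0, 4, size=15).astype(float)
        y = rng.integers(1, 5, size=18).astype(float)
        ours = mann_whitney(x, y).p_value
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").pvalue
        assert "normal_approx" in mann_whitney(x, y).method
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_type_i_error_calibrated(self, rng):
        rejections = 0
        reps = 500
        for _ in range(reps):
            x, y = rng.normal(size=10), rng.normal(size=10)
            if mann_whitney(x, y).p_value <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.08

    def test_empty_sample_errors(self):
        with pytest.raises(ComputationError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        r = kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_hand_computed_rank_formula(self):
        # ranks 1..6 -> rank sums 3, 7, 11; H = 12/(6*7) * (9/2+49/2+121/2) - 21
        r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        expected_h = 12 / 42 * (4.5 + 24.5 + 60.5) - 21
        assert r.statistic == pytest.approx(expected_h)

    def test_agrees_with_scipy_including_ties(self, rng):
        groups = [rng.integers(0, 6, size=n).astype(float) for n in (8, 11, 9, 7)]
        ours = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.uniform(1, 10, size=n) for n in (6, 8, 7)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_null_rejection_rate(self, rng):
        rejections = 0
        reps = 400
        for _ in range(reps):
            groups = [rng.normal(size=8) for _ in range(3)]
            if kruskal_wallis(groups).p_value <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.09

    @pytest.mark.parametrize("groups", [[[1.0], [2.0]], [[1.0], [], [2.0]]])
    def test_preconditions(self, groups):
        with pytest.raises(ComputationError):
            kruskal_wallis(groups)


class TestDunnPosthoc:
    def test_identical_groups_all_p_one(self):
        results = dunn_posthoc([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert all(r.p_value == 1.0 for r in results)

    def test_shifted_group_detected(self, rng):
        a = rng.normal(0, 1, size=12)
        b = rng.normal(0, 1, size=12)
        c = rng.normal(10, 1, size=12)  # +10 SD shift
        results = {r.comparison: r for r in
                   dunn_posthoc([a, b, c], labels=["a", "b", "c"])}
        assert results["a vs c"].p_value < 0.01
        assert results["b vs c"].p_value < 0.01
        assert results["a vs b"].p_value > 0.5

    def test_vs_control_makes_fewer_comparisons(self, rng):
        groups = [rng.normal(size=8) for _ in range(4)]
        assert len(dunn_posthoc(groups, comparisons="all_pairs")) == 6
        assert len(dunn_posthoc(groups, comparisons="vs_control")) == 3

    def test_equal_raw_p_get_equal_adjusted_p(self):
        # symmetric design: group0 vs group1 and group0 vs group2 mirror each
        # other around the pooled mean rank -> identical |z| and raw p
        results = dunn_posthoc([[4.0, 5.0], [1.0, 2.0], [7.0, 8.0]])
        assert abs(results[0].statistic) == pytest.approx(abs(results[1].statistic))
        assert results[0].p_value == pytest.approx(results[1].p_value)


class TestHolmSidak:
    def test_single_p_unchanged(self):
        adj, rej = holm_sidak([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej == [True]

    def test_closed_form_three_p(self):
        adj, _ = holm_sidak([0.01, 0.04, 0.03])
        assert min(adj) == pytest.approx(1 - 0.99 ** 3, abs=1e-9)
        assert adj[0] == pytest.approx(0.029701, abs=1e-9)

    def test_all_ones(self):
        adj, rej = holm_sidak([1.0, 1.0, 1.0])
        assert adj == [1.0, 1.0, 1.0]
        assert rej == [False, False, False]

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(0, 1, size=9)
        ours, ours_rej = holm_sidak(p, alpha=0.05)
        rej_ref, adj_ref, _, _ = multipletests(p, alpha=0.05, method="holm-sidak")
        np.testing.assert_allclose(ours, adj_ref, rtol=1e-12)
        np.testing.assert_array_equal(ours_rej, rej_ref)

    def test_adjusted_dominate_raw_and_monotone(self, rng):
        p = rng.uniform(0, 1, size=12)
        adj, _ = holm_sidak(p)
        assert all(a >= r for a, r in zip(adj, p))
        assert all(a <= 1.0 for a in adj)
        order = np.argsort(p)
        sorted_adj = np.asarray(adj)[order]
        assert all(b >= a for a, b in zip(sorted_adj, sorted_adj[1:]))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=15))
    def test_adjustment_properties_for_arbitrary_p(self, p):
        """Adjusted values dominate raw p, stay in [0, 1], and are monotone
        non-decreasing along the sorted order, for any input family."""
        adj, _ = holm_sidak(p)
        assert all(r <= a <= 1.0 for r, a in zip(p, adj))
        sorted_adj = np.asarray(adj)[np.argsort(p, kind="stable")]
        assert all(b >= a - 1e-15 for a, b in zip(sorted_adj, sorted_adj[1:]))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.5])


class TestWelchBattery:
    def test_separated_pair_detected_family_corrected(self, rng):
        pairs = [
            (rng.normal(0, 1, 8), rng.normal(6, 1, 8)),
            (rng.normal(0, 1, 8), rng.normal(0, 1, 8)),
        ]
        results = welch_t_battery(pairs, labels=["shifted", "null"])
        by_label = {r.comparison: r for r in results}
        assert by_label["shifted"].p_value < 0.01
        assert by_label["null"].p_value > 0.05
        assert all(r.adjusted for r in results)
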