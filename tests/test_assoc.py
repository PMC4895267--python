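"""ANOVA filter, pairwise one-sided t-tests, mark combination, ranking.

scipy.stats.f_oneway and ttest_ind serve as the independent per-window
oracles for the vectorised implementations.
"""

import numpy as np
import pytest
from scipy import stats

from epom.assoc import (
    TestingThresholds,
    anova_filter,
    associate,
    association_percentages,
    combine_marks,
    pairwise_ttest,
    rank_marks_by_differential_regions,
)
from conftest import make_matrix


GROUPS5 = ["G1"] * 4 + ["G2"] * 4 + ["G3"] * 4 + ["G4"] * 4 + ["G5"] * 4


class TestAnovaFilter:
    def test_all_values_equal_gives_p_one(self):
        m = make_matrix(np.full((3, 20), 2.0), GROUPS5)
        kept, corrected = anova_filter(m, TestingThresholds(alpha1=0.5))
        assert kept == []
        np.testing.assert_array_equal(corrected, [1.0, 1.0, 1.0])

    def test_zero_within_variance_unequal_means_gives_p_zero(self):
        values = np.zeros((1, 20))
        values[0, :4] = 10.0  # G1 all 10, everyone else all 0
        m = make_matrix(values, GROUPS5)
        kept, corrected = anova_filter(m, TestingThresholds(alpha1=1e-10))
        assert len(kept) == 1
        assert corrected[0] == 0.0

    def test_matches_scipy_f_oneway_per_window(self, rng):
        values = rng.normal(size=(40, 20))
        m = make_matrix(values, GROUPS5)
        _, corrected = anova_filter(m, TestingThresholds(alpha1=0.5))
        for k in range(40):
            groups = [values[k, 4 * g: 4 * g + 4] for g in range(5)]
            expected = min(1.0, stats.f_oneway(*groups).pvalue * 40)
            assert corrected[k] == pytest.approx(expected, rel=1e-10)

    def test_bonferroni_uses_window_count_of_matrix(self, rng):
        values = rng.normal(size=(10, 20))
        m_small = make_matrix(values[:5], GROUPS5)
        m_large = make_matrix(values, GROUPS5)
        _, c_small = anova_filter(m_small, TestingThresholds(alpha1=0.5))
        _, c_large = anova_filter(m_large, TestingThresholds(alpha1=0.5))
        raw = c_small / 5
        np.testing.assert_allclose(
            c_large[:5], np.minimum(1.0, raw * 10), rtol=1e-12)

    def test_group_below_two_samples_raises(self):
        with pytest.raises(ValueError):
            m = make_matrix(np.zeros((2, 3)), ["G1", "G1", "G2"])
            anova_filter(m, TestingThresholds())


class TestPairwiseTTest:
    def test_equal_groups_give_half_p_no_rejection(self):
        m = make_matrix(np.full((2, 8), 5.0), ["G1"] * 4 + ["G2"] * 4)
        out = pairwise_ttest(m, TestingThresholds(alpha2=0.4, m=0))
        assert out == {"G1": set(), "G2": set()}

    def test_matches_scipy_welch_one_sided(self, rng):
        values = rng.normal(size=(30, 20))
        m = make_matrix(values, GROUPS5)
        # reproduce the rejection counts with scipy as the oracle
        th = TestingThresholds(alpha2=0.1, m=0, strict=True)
        out = pairwise_ttest(m, th)
        for k in range(30):
            xs = {f"G{g + 1}": values[k, 4 * g: 4 * g + 4] for g in range(5)}
            for gi, xi in xs.items():
                count = sum(
                    stats.ttest_ind(xi, xj, equal_var=False,
                                    alternative="greater").pvalue < th.alpha2
                    for gj, xj in xs.items() if gj != gi
                )
                window = m.windows[k]
                assert (window in out[gi]) == (count > th.m)

    def test_planted_group_dominates(self, rng):
        G, n, R = 4, 6, 50
        groups = [f"G{g + 1}" for g in range(G) for _ in range(n)]
        values = rng.normal(size=(R, G * n))
        planted = list(range(0, R, 5))
        values[np.ix_(planted, range(n))] += 10.0  # G1 exceeds all by 10 sd
        m = make_matrix(values, groups)
        out = pairwise_ttest(m, TestingThresholds(alpha2=0.01, m=G - 2))
        expected = {m.windows[k] for k in planted}
        assert out["G1"] >= expected
        for g in ("G2", "G3", "G4"):
            assert not out[g] & expected

    def test_rejections_mutually_exclusive_between_directions(self, rng):
        from epom.assoc import _group_stats, _welch_one_sided

        values = rng.normal(size=(40, 20))
        m = make_matrix(values, GROUPS5)
        groups, ns, means, variances = _group_stats(m)
        for i in range(5):
            for j in range(i + 1, 5):
                pij = _welch_one_sided(means[i], variances[i], ns[i],
                                       means[j], variances[j], ns[j])
                pji = _welch_one_sided(means[j], variances[j], ns[j],
                                       means[i], variances[i], ns[i])
                np.testing.assert_allclose(pij + pji, 1.0, rtol=1e-9)
                for alpha2 in (0.01, 0.2, 0.5):
                    assert not np.any((pij < alpha2) & (pji < alpha2))

    def test_monotone_in_m_and_alpha2(self, rng):
        values = rng.normal(size=(60, 20))
        values[:10, :4] += 3.0
        m = make_matrix(values, GROUPS5)
        base = pairwise_ttest(m, TestingThresholds(alpha2=0.05, m=3))
        lower_m = pairwise_ttest(m, TestingThresholds(alpha2=0.05, m=2))
        higher_a = pairwise_ttest(m, TestingThresholds(alpha2=0.2, m=3))
        for g in base:
            assert base[g] <= lower_m[g]
            assert base[g] <= higher_a[g]

    def test_m_must_be_below_group_count(self):
        m = make_matrix(np.zeros((2, 8)), ["G1"] * 4 + ["G2"] * 4)
        with pytest.raises(ValueError, match="smaller than the number"):
            pairwise_ttest(m, TestingThresholds(m=2))


class TestCombineMarks:
    def _results(self, rng):
        values = rng.normal(size=(30, 20))
        values[:6, :4] += 8.0
        m1 = make_matrix(values, GROUPS5, mark="H3K4me1")
        v2 = values.copy()
        v2[3:9, :4] += 8.0
        m2 = make_matrix(v2, GROUPS5, mark="H3K27ac")
        th = TestingThresholds(alpha1=1e-4, alpha2=0.01, m=3)
        return associate(m1, th), associate(m2, th)

    def test_union_and_intersection(self, rng):
        r1, r2 = self._results(rng)
        union = combine_marks([r1, r2], "union")
        inter = combine_marks([r1, r2], "intersection")
        for g in union.groups:
            assert union.associated[g] == r1.associated[g] | r2.associated[g]
            assert inter.associated[g] == r1.associated[g] & r2.associated[g]
            assert inter.associated[g] <= union.associated[g]

    def test_identical_inputs_union_equals_intersection(self, rng):
        r1, _ = self._results(rng)
        u = combine_marks([r1, r1], "union")
        i = combine_marks([r1, r1], "intersection")
        assert u.associated == i.associated == r1.associated

    def test_mismatched_groups_raise(self, rng):
        r1, r2 = self._results(rng)
        r2.associated = {g + "x": s for g, s in r2.associated.items()}
        with pytest.raises(ValueError, match="mismatched"):
            combine_marks([r1, r2])


class TestMarkRanking:
    def test_planted_mark_ranks_first(self, rng):
        values = rng.normal(size=(200, 20))
        vA = values.copy()
        vA[:50, :4] += 10.0
        mA = make_matrix(vA, GROUPS5, mark="H3K4me1")
        mB = make_matrix(values, GROUPS5, mark="H3K9me3")
        ranked = rank_marks_by_differential_regions([mA, mB], alpha1=1e-4)
        assert ranked[0][0] == "H3K4me1"
        assert ranked[0][1] >= 40 > ranked[1][1]

    def test_tie_broken_alphabetically(self, rng):
        values = rng.normal(size=(50, 20))
        mA = make_matrix(values, GROUPS5, mark="H3K9me3")
        mB = make_matrix(values, GROUPS5, mark="H3K4me1")
        ranked = rank_marks_by_differential_regions([mA, mB])
        assert [r[0] for r in ranked] == ["H3K4me1", "H3K9me3"]
        assert ranked[0][1] == ranked[1][1]

    def test_single_mark(self, rng):
        m = make_matrix(rng.normal(size=(10, 20)), GROUPS5)
        assert len(rank_marks_by_differential_regions([m])) == 1


class TestReporting:
    def test_percentage_arithmetic(self):
        pct = association_percentages({"A": 51_666, "B": 0}, 4_056_578)
        assert pct == {"A": 1.27, "B": 0.0}

    def test_zero_candidates_raise(self):
        with pytest.raises(ValueError):
            association_percentages({"A": 1}, 0)
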