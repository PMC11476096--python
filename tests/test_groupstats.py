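import itertools
import math

import numpy as np
import pytest
from scipy import stats

from hjorth2d import (
    DegenerateInputError,
    GroupedSample,
    InputError,
    RankSummary,
    dunn_posthoc,
    kruskal_wallis,
    kruskal_wallis_from_ranks,
    levene,
    rank_all,
    shapiro_wilk,
)

# Printed worked example: group sizes and rank sums of the three-taxa design
SIZES = (18, 8, 9)
RANK_SUMS = {
    "activity": (348.0, 229.0, 53.0),
    "mobility": (310.0, 242.0, 78.0),
    "complexity": (339.0, 41.0, 250.0),
}


def sample_from(groups):
    return GroupedSample("x", tuple((lab, tuple(vals)) for lab, vals in groups))


class TestGroupedSample:
    def test_rejects_single_group(self):
        with pytest.raises(InputError):
            sample_from([("a", [1, 2])])

    def test_rejects_empty_group_and_duplicates(self):
        with pytest.raises(InputError):
            sample_from([("a", [1]), ("b", [])])
        with pytest.raises(InputError):
            sample_from([("a", [1]), ("a", [2])])

    def test_total_n(self):
        s = sample_from([("a", [1, 2]), ("b", [3])])
        assert s.total_n == 3


class TestRankAll:
    def test_symmetric_ranks(self):
        rs = rank_all(sample_from([("a", [1, 4]), ("b", [2, 3])]))
        assert rs.rank_sums == (5.0, 5.0)

    def test_midrank_ties(self):
        rs = rank_all(sample_from([("a", [1, 1]), ("b", [2])]))
        assert rs.rank_sums == (3.0, 3.0)
        assert rs.tie_groups == (2,)
        assert rs.tie_correction == pytest.approx(1 - (8 - 2) / (27 - 3))

    def test_rank_conservation_random(self, rng):
        for _ in range(10):
            sizes = rng.integers(2, 8, size=3)
            groups = [(f"g{i}", rng.normal(size=n).tolist()) for i, n in enumerate(sizes)]
            rs = rank_all(sample_from(groups))
            n = rs.total_n
            assert sum(rs.rank_sums) == pytest.approx(n * (n + 1) / 2, abs=1e-9)

    def test_printed_rank_sums_conserve(self):
        for sums in RANK_SUMS.values():
            assert sum(sums) == 630 == 35 * 36 / 2


class TestKruskalWallisFromRanks:
    def test_equal_rank_means_give_zero(self):
        # 3 groups of 2, every group rank-average (N+1)/2 = 3.5
        res = kruskal_wallis_from_ranks((2, 2, 2), (7, 7, 7))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_conservation_enforced(self):
        with pytest.raises(InputError):
            kruskal_wallis_from_ranks((2, 2), (3, 8))

    @pytest.mark.parametrize("name,expected", [
        ("activity", 21.478), ("mobility", 19.004), ("complexity", 20.944),
    ])
    def test_worked_examples(self, name, expected):
        res = kruskal_wallis_from_ranks(SIZES, RANK_SUMS[name])
        assert res.statistic == pytest.approx(expected, abs=1e-3)


class TestKruskalWallis:
    def test_matches_scipy_with_ties(self, rng):
        for _ in range(10):
            groups = [rng.integers(0, 6, size=n).astype(float) for n in (6, 5, 7)]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            ours = kruskal_wallis(sample_from([(f"g{i}", g) for i, g in enumerate(groups)]))
            h_ref, p_ref = stats.kruskal(*groups)
            assert ours.statistic == pytest.approx(h_ref, rel=1e-12)
            assert ours.p_value == pytest.approx(p_ref, rel=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.normal(size=n) for n in (5, 6, 4)]
        s1 = sample_from([(f"g{i}", g) for i, g in enumerate(groups)])
        s2 = sample_from([(f"g{i}", np.exp(g)) for i, g in enumerate(groups)])
        assert kruskal_wallis(s1).statistic == pytest.approx(
            kruskal_wallis(s2).statistic, rel=1e-12
        )

    def test_all_identical_degenerate(self):
        with pytest.raises(DegenerateInputError):
            kruskal_wallis(sample_from([("a", [1.0, 1.0]), ("b", [1.0, 1.0])]))

    def test_permutation_matches_independent_enumeration(self, rng):
        """Exact permutation p cross-checked against a from-scratch
        enumeration over all 6!/(2!2!2!) = 90 group assignments."""
        vals = rng.normal(size=6)
        groups = [("a", vals[:2]), ("b", vals[2:4]), ("c", vals[4:])]
        res = kruskal_wallis(sample_from(groups), method="permutation")

        ranks = stats.rankdata(vals)
        n = 6

        def h_stat(assign):
            h = 0.0
            for g in range(3):
                r = [ranks[i] for i in range(n) if assign[i] == g]
                h += sum(r) ** 2 / len(r)
            return 12 / (n * (n + 1)) * h - 3 * (n + 1)

        observed = h_stat([0, 0, 1, 1, 2, 2])
        perms = set(itertools.permutations([0, 0, 1, 1, 2, 2]))
        count = sum(h_stat(p) >= observed - 1e-12 for p in perms)
        assert res.p_value == pytest.approx(count / len(perms), abs=1e-12)
        # and the chi-square approximation genuinely differs at this tiny n
        chi2_p = kruskal_wallis(sample_from(groups), method="chi2").p_value
        assert chi2_p != pytest.approx(res.p_value, abs=1e-6)

    def test_type_one_error_small(self, rng):
        """Quick null calibration; the full-size run lives in the
        acceptance suite."""
        rejections = 0
        reps = 300
        for _ in range(reps):
            vals = rng.normal(size=35)
            s = sample_from([("a", vals[:18]), ("b", vals[18:26]), ("c", vals[26:])])
            rejections += kruskal_wallis(s).p_value < 0.05
        rate = rejections / reps
        assert 0.01 < rate < 0.10


class TestDunn:
    def test_equal_rank_averages(self):
        rs = RankSummary(("a", "b"), (3, 3), (10.5, 10.5))
        m = dunn_posthoc(rs)
        assert m.z[0, 1] == 0.0 and m.p_adj[0, 1] == 1.0

    def test_symmetry_and_range(self, rng):
        groups = [(f"g{i}", rng.normal(size=n)) for i, n in enumerate((5, 7, 6, 4))]
        m = dunn_posthoc(sample_from(groups))
        np.testing.assert_array_equal(m.p_adj, m.p_adj.T)
        off = m.p_adj[~np.eye(4, dtype=bool)]
        assert ((off > 0) & (off <= 1)).all()

    def test_bonferroni_factor_is_three_for_three_groups(self):
        rs = RankSummary(("a", "b", "c"), SIZES, RANK_SUMS["activity"])
        m = dunn_posthoc(rs)
        ra = rs.rank_averages
        se = math.sqrt(35 * 36 / 12 * (1 / 18 + 1 / 8))
        raw = 2 * stats.norm.sf(abs(ra[0] - ra[1]) / se)
        assert m.p_adj[0, 1] == pytest.approx(min(1, 3 * raw), rel=1e-12)


class TestLevene:
    def test_toy_groups_match_anova_on_deviations(self):
        """F equals a hand-built one-way ANOVA on |x - group mean|."""
        res = levene(sample_from([("a", [1, 2, 3]), ("b", [1, 5, 9])]))
        f_ref, p_ref = stats.f_oneway([1, 0, 1], [4, 0, 4])  # |x-2|, |x-5|
        assert res.statistic == pytest.approx(f_ref, rel=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-12)
        assert res.ms_between == pytest.approx(res.ss_between / res.df_between)
        assert res.statistic == pytest.approx(res.ms_between / res.ms_within)

    def test_matches_scipy_levene_both_centers(self, rng):
        groups = [rng.normal(scale=s, size=n) for s, n in ((1, 8), (2, 6), (0.5, 7))]
        sample = sample_from([(f"g{i}", g) for i, g in enumerate(groups)])
        for center in ("mean", "median"):
            ours = levene(sample, center=center)
            w_ref, p_ref = stats.levene(*groups, center=center)
            assert ours.statistic == pytest.approx(w_ref, rel=1e-10)
            assert ours.p_value == pytest.approx(p_ref, rel=1e-10)

    def test_design_degrees_of_freedom(self, rng):
        groups = [(lab, rng.normal(size=n)) for lab, n in zip("abc", SIZES)]
        res = levene(sample_from(groups))
        assert res.df_between == 2 and res.df_within == 32

    def test_identical_deviation_means_give_zero_f(self):
        res = levene(sample_from([("a", [1.0, 2.0, 3.0]), ("b", [1.0, 2.0, 3.0])]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_and_size_errors(self):
        with pytest.raises(DegenerateInputError):
            levene(sample_from([("a", [1.0, 1.0]), ("b", [2.0, 2.0])]))
        with pytest.raises(InputError):
            levene(sample_from([("a", [1.0]), ("b", [1.0, 2.0])]))


class TestShapiroWilk:
    def test_normal_samples_rarely_rejected(self):
        rng = np.random.default_rng(11)
        passed = sum(
            shapiro_wilk(rng.normal(size=50)).p_value > 0.05 for _ in range(200)
        )
        assert passed >= 180

    def test_exponential_samples_usually_rejected(self):
        rng = np.random.default_rng(12)
        rejected = sum(
            shapiro_wilk(rng.exponential(size=50)).p_value < 0.05 for _ in range(200)
        )
        assert rejected >= 180

    def test_input_errors(self):
        with pytest.raises(InputError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(DegenerateInputError):
            shapiro_wilk([3.0] * 10)
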