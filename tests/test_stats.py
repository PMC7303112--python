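"""Rank tests against exhaustive-enumeration and hand-formula oracles."""
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from tracerflux import (
    GroupedSamples,
    compare_groups,
    dunn_posthoc,
    kruskal_wallis,
    wilcoxon_rank_sum,
)
from tracerflux.errors import InvalidInputError


def enumerate_ranksum_p(x, y, alternative):
    """Exhaustive oracle: full null distribution of U over all C(n+m, n)
    assignments of the pooled ranks to the first sample."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = np.array(
        [
            ranks[list(idx)].sum() - n * (n + 1) / 2
            for idx in combinations(range(len(pooled)), n)
        ]
    )
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxonRankSum:
    def test_separated_samples_one_sided_exact(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1.0 / 20.0)

    def test_identical_multisets_two_sided_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("alternative", ["two_sided", "less", "greater"])
    def test_exact_p_equals_enumeration_for_all_small_sizes(self, alternative):
        # full sweep over every (n, m) with n + m <= 10, distinct values
        rng = np.random.default_rng(12)
        for n in range(1, 10):
            for m in range(1, 10 - n + 1):
                values = rng.permutation(np.arange(1.0, n + m + 1.0))
                x, y = values[:n], values[n:]
                res = wilcoxon_rank_sum(x, y, alternative=alternative)
                assert res.method == "exact"
                assert res.p_value == pytest.approx(
                    enumerate_ranksum_p(x, y, alternative), abs=1e-12
                ), (n, m, alternative)

    def test_ties_fall_back_to_normal_approximation(self):
        res = wilcoxon_rank_sum([1, 1, 2], [2, 3, 3])
        assert res.method == "normal_approx"
        assert 0 < res.p_value <= 1

    def test_exact_and_approximate_agree_for_larger_samples(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1.0, 12)
        y = rng.normal(0.5, 1.0, 12)
        exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        approx = wilcoxon_rank_sum(x, y)  # n + m > 16 -> normal approximation
        assert approx.method == "normal_approx"
        assert abs(approx.p_value - exact) < 0.01

    def test_invariant_under_monotone_transform(self):
        x = [0.2, 1.4, 3.0, 0.9]
        y = [2.2, 4.0, 5.5]
        a = wilcoxon_rank_sum(x, y)
        b = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert a.p_value == pytest.approx(b.p_value)
        assert a.statistic == pytest.approx(b.statistic)


class TestKruskalWallis:
    def test_all_identical_gives_zero_h(self):
        s = GroupedSamples([("a", [5.0, 5.0]), ("b", [5.0]), ("c", [5.0, 5.0])])
        h, p = kruskal_wallis(s)
        assert h == 0.0 and p == 1.0

    def test_three_groups_of_three_hand_formula(self):
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2 with ranks 1..9:
        # Rbar = (2, 5, 8), N = 9 -> H = 12/90 * (27 + 0 + 27) = 7.2
        s = GroupedSamples([("a", [1, 2, 3]), ("b", [4, 5, 6]), ("c", [7, 8, 9])])
        h, p = kruskal_wallis(s)
        assert h == pytest.approx(7.2, rel=1e-12)
        assert p == pytest.approx(sps.chi2.sf(7.2, df=2), rel=1e-12)

    def test_invariant_under_monotone_transform(self):
        groups = [("a", [0.1, 2.0, 1.1]), ("b", [3.0, 2.5]), ("c", [0.5, 4.0, 3.3])]
        h1, _ = kruskal_wallis(GroupedSamples(groups))
        h2, _ = kruskal_wallis(
            GroupedSamples([(k, list(np.exp(v))) for k, v in groups])
        )
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            GroupedSamples([("a", [1.0]), ("b", [])])


class TestDunnPosthoc:
    def test_hand_computed_z_without_ties(self):
        # ranks 1..9 in three groups: S = N(N+1)/12 = 7.5,
        # se = sqrt(7.5 * 2/3) = sqrt(5); z13 = (2 - 8)/sqrt(5) = -2.683282
        s = GroupedSamples([("a", [1, 2, 3]), ("b", [4, 5, 6]), ("c", [7, 8, 9])])
        out = dunn_posthoc(s, adjust="none")
        z = dict(zip(zip(out.group_1, out.group_2), out.z))
        assert z[("a", "b")] == pytest.approx(-3.0 / np.sqrt(5.0), rel=1e-12)
        assert z[("a", "c")] == pytest.approx(-6.0 / np.sqrt(5.0), rel=1e-12)
        p = dict(zip(zip(out.group_1, out.group_2), out.p_raw))
        assert p[("a", "c")] == pytest.approx(2 * sps.norm.sf(6.0 / np.sqrt(5.0)))

    def test_identical_pair_has_zero_z_and_unit_p(self):
        s = GroupedSamples(
            [("a", [1.0, 2.0, 3.0]), ("b", [1.0, 2.0, 3.0]), ("c", [10.0, 11.0, 12.0])]
        )
        out = dunn_posthoc(s)
        row = out[(out.group_1 == "a") & (out.group_2 == "b")].iloc[0]
        assert row.z == pytest.approx(0.0, abs=1e-12)
        assert row.p_raw == pytest.approx(1.0)

    @pytest.mark.parametrize("adjust", ["holm", "bonferroni", "fdr_bh"])
    def test_adjusted_p_never_below_raw(self, adjust):
        rng = np.random.default_rng(9)
        s = GroupedSamples(
            [(f"g{i}", list(rng.normal(i * 0.5, 1.0, 4))) for i in range(4)]
        )
        out = dunn_posthoc(s, adjust=adjust)
        assert (out.p_adjusted >= out.p_raw - 1e-12).all()
        assert (out.p_adjusted <= 1.0 + 1e-12).all()

    def test_two_groups_fall_back_to_rank_sum(self):
        s = GroupedSamples([("a", [1.0, 2.0, 3.0]), ("b", [4.0, 5.0, 6.0])])
        with pytest.warns(UserWarning, match="unnecessary"):
            out = dunn_posthoc(s)
        assert len(out) == 1
        assert out.p_raw.iloc[0] == pytest.approx(0.1)  # two-sided exact 2/20


def test_compare_groups_emits_tidy_battery(zero_noise_results):
    table = compare_groups(
        zero_noise_results.budget, "respiration_total", "group"
    )
    assert set(table.test) >= {"kruskal_wallis", "dunn"}
    assert {"value", "groups", "statistic", "p", "p_adjusted"} <= set(table.columns)
    dunn_rows = table[table.test == "dunn"]
    assert (dunn_rows.p_adjusted >= dunn_rows.p - 1e-12).all()
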