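import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from beemaze.stats import (
    anova_with_tukey,
    fdr_adjust,
    mann_whitney_u,
    outlier_flags,
    wilcoxon_signed_rank,
)


def exact_signed_rank_p(d):
    """Brute-force two-sided permutation p for the signed-rank test.

    Enumerates all sign assignments of the |d| midranks and counts
    statistics at least as far from the null mean as observed.
    """
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = d.size * (d.size + 1) / 4.0
    hits = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=d.size):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def exact_mannwhitney_p(x, y):
    """Brute-force two-sided permutation p for the U test."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = x.size
    mu = n1 * y.size / 2.0
    off = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - off
    hits = total = 0
    for idx in itertools.combinations(range(pooled.size), n1):
        u = ranks[list(idx)].sum() - off
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxonSignedRank:
    def test_identical_vectors_give_p_one(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == 1.0 and res.z == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_mode_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        x = rng.integers(0, 6, n).astype(float)  # integer data forces ties
        y = rng.integers(0, 6, n).astype(float)
        res = wilcoxon_signed_rank(x, y, method="exact")
        assert res.p == pytest.approx(exact_signed_rank_p(x - y))

    def test_approx_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.4, 1.0, 30)
        ours = wilcoxon_signed_rank(x)
        ref = sps.wilcoxon(x, correction=False, mode="approx")
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_z_sign_tracks_direction(self):
        base = np.arange(1.0, 13.0)
        assert wilcoxon_signed_rank(base + 5, base).z > 0
        assert wilcoxon_signed_rank(base - 5, base).z < 0

    def test_pratt_zero_handling_available(self):
        x = np.array([0.0, 0.0, 1.0, 2.0, 3.0, -1.0, 4.0, 2.0])
        drop = wilcoxon_signed_rank(x, zero_method="wilcox")
        pratt = wilcoxon_signed_rank(x, zero_method="pratt")
        assert drop.p != pratt.p  # zeros change the reference distribution


class TestMannWhitney:
    def test_identical_samples_give_z_zero(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.z == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_exact_mode_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(3, 7)), int(rng.integers(3, 7))
        x = rng.integers(0, 5, n1).astype(float)
        y = rng.integers(0, 5, n2).astype(float)
        res = mann_whitney_u(x, y, method="exact")
        assert res.p == pytest.approx(exact_mannwhitney_p(x, y))

    def test_approx_matches_scipy_with_ties(self):
        rng = np.random.default_rng(13)
        x = rng.integers(0, 10, 25).astype(float)
        y = rng.integers(2, 12, 30).astype(float)
        ours = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_complete_separation_hits_bounds(self):
        res = mann_whitney_u([1, 2, 3], [10, 11, 12, 13])
        assert res.statistic == 0.0
        res = mann_whitney_u([10, 11, 12, 13], [1, 2, 3])
        assert res.statistic == 4 * 3

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.04])[0] == pytest.approx(0.04)

    def test_step_up_hand_computation(self):
        out = fdr_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_adjusted_dominates_raw_and_is_order_invariant(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(0, 1, 20)
        adj = fdr_adjust(p)
        assert (adj >= p - 1e-12).all()
        perm = rng.permutation(20)
        assert np.allclose(fdr_adjust(p[perm]), adj[perm])

    def test_families_adjust_independently(self):
        p = [0.01, 0.02, 0.01, 0.02]
        fam = ["a", "a", "b", "b"]
        joint = fdr_adjust(p, fam)
        assert np.allclose(joint[:2], fdr_adjust(p[:2]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([-0.1, 0.5])


class TestAnovaTukey:
    @staticmethod
    def toy_table():
        return pd.DataFrame(
            {
                "value": [3.0, 4, 5, 6, 7, 9, 2, 2, 3],
                "grp": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
            }
        )

    def test_f_matches_sums_of_squares_oracle(self):
        data = self.toy_table()
        table, tukey = anova_with_tukey(data, "value", "grp")
        # brute-force between/within sums of squares
        grand = data["value"].mean()
        groups = [g["value"].to_numpy() for _, g in data.groupby("grp")]
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ss_between / 2) / (ss_within / 6)
        assert table.loc["C(grp)", "F"] == pytest.approx(f_oracle)
        assert len(tukey) == 3  # all pairwise comparisons

    def test_two_level_f_equals_t_squared(self):
        rng = np.random.default_rng(15)
        data = pd.DataFrame(
            {
                "value": np.concatenate(
                    [rng.normal(0, 1, 10), rng.normal(1, 1, 10)]
                ),
                "grp": ["a"] * 10 + ["b"] * 10,
            }
        )
        table, _ = anova_with_tukey(data, "value", "grp")
        t = sps.ttest_ind(
            data[data["grp"] == "a"]["value"], data[data["grp"] == "b"]["value"]
        )
        assert table.loc["C(grp)", "F"] == pytest.approx(t.statistic**2)

    def test_equal_means_give_small_f(self):
        data = pd.DataFrame(
            {"value": [1.0, 2, 3] * 3, "grp": ["a"] * 3 + ["b"] * 3 + ["c"] * 3}
        )
        table, tukey = anova_with_tukey(data, "value", "grp")
        assert table.loc["C(grp)", "F"] == pytest.approx(0.0)
        assert not tukey["reject"].any()

    def test_additive_two_factor_model(self):
        rng = np.random.default_rng(16)
        data = pd.DataFrame(
            {
                "speed": rng.normal(30, 3, 40),
                "season": ["summer", "winter"] * 20,
                "phase": (["training"] * 2 + ["stm"] * 2) * 10,
            }
        )
        table, _ = anova_with_tukey(
            data, "speed", ["season", "phase"], tukey_on="phase"
        )
        assert {"C(season)", "C(phase)", "Residual"} <= set(table.index)

    def test_degenerate_levels_rejected(self):
        data = pd.DataFrame({"value": [1.0, 2.0], "grp": ["a", "a"]})
        with pytest.raises(ValueError):
            anova_with_tukey(data, "value", "grp")


class TestOutlierFlags:
    def test_far_value_flagged(self):
        flags = outlier_flags([1, 2, 3, 4, 100])
        assert list(flags) == [False, False, False, False, True]

    def test_constant_vector_flags_nothing(self):
        assert not outlier_flags([5.0] * 6).any()

    def test_symmetric_data_within_fences(self):
        assert not outlier_flags([1, 2, 3, 4, 5, 6]).any()

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            outlier_flags([1, 2, 3])
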