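"""Permutation inference: exact arithmetic, calibration, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from herdnet.permstats import (
    assortment_test,
    attribute_difference_matrix,
    bonferroni,
    classify_lameness,
    correlate_daily_series,
    group_statistic_tests,
    mantel_spearman,
    permutation_p,
    social_differentiation,
    temporal_block_comparison,
)


def sym(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"c{i}" for i in range(values.shape[0])]
    m = pd.DataFrame(values, index=ids, columns=ids)
    np.fill_diagonal(m.values, np.nan)
    return m


def random_sym(n, rng, kind="poisson"):
    v = rng.poisson(3.0, (n, n)).astype(float) if kind == "poisson" else rng.random((n, n))
    v = np.triu(v, 1)
    return sym(v + v.T)


class TestPermutationP:
    def test_250_of_10000(self):
        t_p = np.concatenate([np.full(250, 2.0), np.full(9750, -1.0)])
        assert permutation_p(1.0, t_p) == 0.025

    def test_biased_estimator_when_none_exceed(self):
        assert permutation_p(5.0, np.zeros(10000)) == pytest.approx(1 / 10001)

    def test_all_exceed_gives_one(self):
        assert permutation_p(-3.0, np.zeros(10000)) == 1.0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        t_p = rng.normal(size=500)
        assert permutation_p(0.3, t_p) == permutation_p(0.3, np.sort(t_p))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            permutation_p(np.nan, np.ones(10))
        with pytest.raises(ValueError):
            permutation_p(0.0, np.array([]))


class TestBonferroni:
    def test_worked_cases(self):
        assert bonferroni(0.002, 28) == pytest.approx(0.056)
        assert bonferroni(0.2, 28) == 1.0
        assert bonferroni(0.03, 1) == 0.03

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(0.0, 5)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)


class TestLamenessClassification:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ((0, 0, 0), "non_lame"),
            ((0, 1, 1), "non_lame"),
            ((0, 1, 2), "non_lame"),  # NL-NL-L dominant not lame
            ((2, 0, 0), "non_lame"),  # L-NL-NL dominant not lame
            ((2, 3, 2), "lame"),
            ((2, 3, 1), "lame"),  # L-L-NL dominant lame
            ((1, 2, 3), "lame"),  # NL-L-L dominant lame
            ((0, 2, 0), "excluded"),  # NL-L-NL changed twice
            ((3, 0, 2), "excluded"),  # L-NL-L changed twice
            ((0, "NS", 0), "excluded"),
        ],
    )
    def test_all_patterns(self, scores, expected):
        assert classify_lameness(scores) == expected

    def test_invalid_score_rejected(self):
        with pytest.raises(ValueError):
            classify_lameness((0, 5, 0))
        with pytest.raises(ValueError):
            classify_lameness((0, 0))


class TestAttributeDifference:
    def make_attrs(self):
        return pd.DataFrame(
            {
                "animal_id": ["a", "b", "c"],
                "parity": [1, 3, 3],
                "days_in_milk": [100, 100, 250],
                "lameness_class": ["lame", "non_lame", "excluded"],
            }
        )

    def test_parity_difference(self):
        d = attribute_difference_matrix(self.make_attrs(), "parity")
        assert d.loc["a", "b"] == 2
        assert d.loc["b", "c"] == 0

    def test_lameness_binary_and_excluded_dropped(self):
        d = attribute_difference_matrix(self.make_attrs(), "lameness")
        assert list(d.index) == ["a", "b"]
        assert d.loc["a", "b"] == 1

    def test_identical_dim_is_zero(self):
        d = attribute_difference_matrix(self.make_attrs(), "days_in_milk")
        assert d.loc["a", "b"] == 0

    def test_missing_values_excluded_with_warning(self):
        attrs = self.make_attrs()
        attrs.loc[0, "parity"] = np.nan
        with pytest.warns(UserWarning, match="excluding"):
            d = attribute_difference_matrix(attrs, "parity")
        assert list(d.index) == ["b", "c"]


class TestSocialDifferentiation:
    def test_uniform_counts_give_zero(self):
        res = social_differentiation(sym(np.full((4, 4), 3.0)), q=200, seed=0)
        assert res.S == 0.0
        assert res.p == 1.0

    def test_worked_case_8_thirds(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 4
        v[1, 2] = v[2, 1] = 2
        res = social_differentiation(sym(v), q=200, seed=0)
        assert res.S == pytest.approx(8 / 3)
        assert res.expected == pytest.approx(2.0)

    def test_ordered_and_dyad_forms_agree(self):
        # S as ordered double sum / n(n-1) equals dyad sum / dyad_count
        rng = np.random.default_rng(1)
        for _ in range(10):
            m = random_sym(7, rng)
            v = np.nan_to_num(m.to_numpy())
            n = 7
            total = v.sum() / 2
            E = total / (n * (n - 1) / 2)
            ordered = ((v - E) ** 2)[~np.eye(n, dtype=bool)].sum() / (n * (n - 1))
            res = social_differentiation(m, q=10, seed=0)
            assert res.S == pytest.approx(ordered)

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(2)
        m = random_sym(6, rng)
        s1 = social_differentiation(m, q=10, seed=0).S
        s2 = social_differentiation(m * 2, q=10, seed=0).S
        assert s2 == pytest.approx(4 * s1)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        m = random_sym(6, rng)
        perm = rng.permutation(6)
        v = np.nan_to_num(m.to_numpy())
        mp = sym(v[np.ix_(perm, perm)])
        assert social_differentiation(m, q=10, seed=0).S == pytest.approx(
            social_differentiation(mp, q=10, seed=0).S
        )

    def test_zero_total_warns(self):
        with pytest.warns(UserWarning, match="zero total"):
            res = social_differentiation(sym(np.zeros((4, 4))), q=10, seed=0)
        assert res.S == 0.0 and res.p == 1.0


class TestMantel:
    def test_identical_matrices_give_one(self):
        rng = np.random.default_rng(4)
        m = random_sym(8, rng)
        res = mantel_spearman(m, m, q=100, seed=0)
        assert res.r_s == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self):
        rng = np.random.default_rng(5)
        m = random_sym(8, rng, kind="uniform")
        rev = sym(1.0 - np.nan_to_num(m.to_numpy()))
        res = mantel_spearman(m, rev, q=100, seed=0)
        assert res.r_s == pytest.approx(-1.0)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(6)
        m1 = random_sym(8, rng, kind="uniform")
        m2 = random_sym(8, rng, kind="uniform")
        r_raw = mantel_spearman(m1, m2, q=50, seed=1).r_s
        r_exp = mantel_spearman(sym(np.exp(np.nan_to_num(m1.to_numpy()))), m2, q=50, seed=1).r_s
        assert r_raw == pytest.approx(r_exp)

    def test_constant_matrix_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="constant"):
            mantel_spearman(sym(np.ones((5, 5))), random_sym(5, rng), q=10)

    def test_null_calibration(self):
        """Independent matrices reject at ~alpha (one-sided, q=200)."""
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 120
        for _ in range(reps):
            m1 = random_sym(10, rng, kind="uniform")
            m2 = random_sym(10, rng, kind="uniform")
            res = mantel_spearman(m1, m2, q=200, seed=int(rng.integers(2**31)))
            if res.p < 0.05:
                rejections += 1
        assert 0.01 <= rejections / reps <= 0.10

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        m1, m2 = random_sym(8, rng), random_sym(8, rng)
        a = mantel_spearman(m1, m2, q=200, seed=42)
        b = mantel_spearman(m1, m2, q=200, seed=42)
        assert a.p == b.p and a.r_s == b.r_s


class TestTemporalBlocks:
    def test_28_days_block4_gives_6_comparisons(self):
        rng = np.random.default_rng(10)
        mats = [random_sym(6, rng) for _ in range(28)]
        results = temporal_block_comparison(mats, 4, q=50, seed=0)
        assert len(results) == 6

    def test_identical_days_give_rs_one(self):
        rng = np.random.default_rng(11)
        m = random_sym(6, rng)
        results = temporal_block_comparison([m] * 8, 4, q=50, seed=0)
        assert all(r.r_s == pytest.approx(1.0) for r in results)

    def test_fewer_than_two_blocks_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError):
            temporal_block_comparison([random_sym(5, rng)] * 3, 4, q=10)


class TestGroupTests:
    def test_identical_data_gives_p_one(self):
        x = np.tile(np.arange(10.0), (6, 1))  # every cow identical across days
        res = group_statistic_tests(x.T, "betweenday_kw", q=100, seed=0)
        assert res.p == 1.0

    def test_wilcoxon_type1_calibration(self):
        rng = np.random.default_rng(13)
        reps, rej = 300, 0
        labels = np.array([0] * 10 + [1] * 10)
        for _ in range(reps):
            x = rng.normal(size=20)
            res = group_statistic_tests(
                x, "wilcoxon", q=200, seed=int(rng.integers(2**31)), labels=labels
            )
            if res.p < 0.05:
                rej += 1
        assert 0.03 <= rej / reps <= 0.08

    def test_wilcoxon_power_with_2sd_shift(self):
        rng = np.random.default_rng(14)
        reps, rej = 100, 0
        labels = np.array([0] * 20 + [1] * 20)
        for _ in range(reps):
            x = np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 20)])
            res = group_statistic_tests(
                x, "wilcoxon", q=200, seed=int(rng.integers(2**31)), labels=labels
            )
            if res.p < 0.05:
                rej += 1
        assert rej / reps >= 0.8

    def test_interindividual_kw_detects_cow_effect(self):
        rng = np.random.default_rng(15)
        base = rng.normal(0, 1, (12, 8))
        base += np.linspace(0, 4, 12)[:, None]  # strong cow effect
        res = group_statistic_tests(base, "interindividual_kw", q=300, seed=0)
        assert res.p < 0.05

    def test_kw_observed_matches_scipy(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=(6, 9))
        res = group_statistic_tests(x, "interindividual_kw", q=10, seed=0)
        expected = stats.kruskal(*[row for row in x]).statistic
        assert res.t_o == pytest.approx(expected)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            group_statistic_tests(
                np.arange(4.0), "wilcoxon", q=10, labels=np.array([0, 0, 0, 1])
            )


class TestAssortment:
    def test_attribute_equal_to_interactions_gives_one(self):
        rng = np.random.default_rng(17)
        m = random_sym(8, rng, kind="uniform")
        res = assortment_test(m, m, q=50, seed=0)
        assert res.r_s == pytest.approx(1.0)

    def test_degenerate_attribute_rejected(self):
        rng = np.random.default_rng(18)
        m = random_sym(6, rng)
        attrs = pd.DataFrame(
            {
                "animal_id": list(m.index),
                "parity": [2] * 6,
                "days_in_milk": [1, 2, 3, 4, 5, 6],
                "lameness_class": ["lame"] * 6,
            }
        )
        with pytest.raises(ValueError):
            d = attribute_difference_matrix(attrs, "parity")
            assortment_test(m, d, q=10)


class TestPearson:
    def test_self_correlation(self):
        x = np.arange(10.0)
        r, _ = correlate_daily_series(x, x)
        assert r == pytest.approx(1.0)

    def test_negation(self):
        x = np.arange(10.0)
        r, _ = correlate_daily_series(x, -x)
        assert r == pytest.approx(-1.0)

    def test_independent_series_mean_near_zero(self):
        rng = np.random.default_rng(19)
        rs = [
            correlate_daily_series(rng.normal(size=28), rng.normal(size=28))[0]
            for _ in range(500)
        ]
        assert abs(np.mean(rs)) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_daily_series(np.ones(5), np.arange(5.0))


def test_null_pvalues_approximately_uniform():
    """Wilcoxon permutation p-values under the null pass a KS check."""
    rng = np.random.default_rng(20)
    labels = np.array([0] * 8 + [1] * 8)
    ps = []
    for _ in range(300):
        x = rng.normal(size=16)
        res = group_statistic_tests(
            x, "wilcoxon", q=99, seed=int(rng.integers(2**31)), labels=labels
        )
        ps.append(res.p)
    # discrete p-values: compare against uniform generously
    stat = stats.kstest(ps, "uniform").statistic
    assert stat < 0.12
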