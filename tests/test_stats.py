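"""Statistical engine tests: closed forms, brute-force enumeration oracles,
library cross-checks and Monte-Carlo calibration."""

import itertools
import math

import numpy as np
import pandas as pd
import pingouin
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from kindex.stats import (
    chi_square_2x2,
    cronbach_alpha,
    descriptives,
    item_criterion_comparison,
    kruskal_wallis,
    ks_normality,
    mann_whitney,
    spearman_matrix,
    student_t,
)


class TestCronbachAlpha:
    def test_identical_items_give_alpha_one(self):
        item = pd.Series([0, 1, 1, 0, 1])
        res = cronbach_alpha(pd.DataFrame({"a": item, "b": item}))
        assert res.alpha == pytest.approx(1.0)

    def test_independent_items_give_alpha_near_zero(self):
        rng = np.random.default_rng(11)
        items = pd.DataFrame(
            rng.binomial(1, 0.3, size=(5000, 28)),
            columns=[f"i{k}" for k in range(28)],
        )
        res = cronbach_alpha(items)
        assert abs(res.alpha) < 0.05

    def test_zero_variance_items_excluded_and_named(self):
        rng = np.random.default_rng(3)
        items = pd.DataFrame(
            rng.binomial(1, 0.4, size=(50, 31)).astype(float),
            columns=[f"i{k}" for k in range(31)],
        )
        for c in ("i3", "i17", "i30"):
            items[c] = 0.0
        res = cronbach_alpha(items)
        assert res.n_items_input == 31
        assert res.n_items_retained == 28
        assert {i for i, _ in res.excluded_items} == {"i3", "i17", "i30"}
        assert all(reason == "zero_variation" for _, reason in res.excluded_items)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(4)
        latent = rng.standard_normal(200)
        items = pd.DataFrame({
            f"i{k}": (latent + rng.standard_normal(200) > 0).astype(int)
            for k in range(8)
        })
        res = cronbach_alpha(items)
        expected = pingouin.cronbach_alpha(items)[0]
        assert res.alpha == pytest.approx(expected, abs=1e-10)

    def test_equicorrelated_closed_form(self):
        """alpha ~= k*rbar / (1 + (k-1)*rbar) on exchangeable binary items."""
        rng = np.random.default_rng(12)
        n, k = 20000, 10
        latent = rng.standard_normal(n)
        items = pd.DataFrame(
            (0.8 * latent[:, None] + rng.standard_normal((n, k)) > 0).astype(int)
        )
        res = cronbach_alpha(items)
        rbar = np.corrcoef(items.T.to_numpy())
        rbar = rbar[np.triu_indices(k, 1)].mean()
        closed = k * rbar / (1 + (k - 1) * rbar)
        assert res.alpha == pytest.approx(closed, abs=0.02)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(pd.DataFrame({"a": [0, 1, 0], "b": [0, 0, 0]}))


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = pd.Series(np.arange(1.0, 11.0))
        df = pd.DataFrame({"x": x, "y": x ** 2, "z": -x})
        results = {r.pair: r for r in spearman_matrix(df)}
        assert results[("x", "y")].rho == pytest.approx(1.0)
        assert results[("x", "z")].rho == pytest.approx(-1.0)

    def test_four_point_rank_pearson(self):
        # hand-computed product-moment correlation on ranks
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 1, 4, 3]})
        (res,) = spearman_matrix(df)
        assert res.rho == pytest.approx(0.6)
        assert res.n == 4

    def test_pairwise_complete_n(self):
        df = pd.DataFrame({
            "x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, np.nan],
            "z": [1, 2, 3, 4, 5],
        })
        results = {r.pair: r for r in spearman_matrix(df)}
        assert results[("x", "y")].n == 4
        assert results[("x", "z")].n == 5

    def test_constant_variable_reports_undefined(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "c": [7, 7, 7, 7]})
        (res,) = spearman_matrix(df)
        assert math.isnan(res.rho)

    @given(st.integers(1, 5))
    @settings(derandomize=True, max_examples=5)
    def test_invariance_under_strictly_monotone_maps(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        base = spearman_matrix(pd.DataFrame({"x": x, "y": y}))[0].rho
        mapped = spearman_matrix(
            pd.DataFrame({"x": np.exp(x), "y": np.arctan(y)})
        )[0].rho
        assert base == pytest.approx(mapped)


def _exact_u_pvalue(a, b, observed_u):
    """Two-sided p by full enumeration of group assignments (no ties)."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n_a):
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        u = sum((x > y) for x in grp for y in rest)
        us.append(u)
    us = np.asarray(us, dtype=float)
    mean_u = n_a * (len(pooled) - n_a) / 2.0
    return float(np.mean(np.abs(us - mean_u) >= abs(observed_u - mean_u) - 1e-12))


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.method == "exact"

    def test_interleaved_pairs(self):
        # cross-pairs (1>2? no) (1>4? no) (3>2 yes) (3>4 no) -> U_A = 1
        res = mann_whitney([1, 3], [2, 4])
        assert res.statistic == 1.0

    def test_identical_groups_half_of_pairs(self):
        n = 5
        vals = list(range(n))
        res = mann_whitney(vals, vals)
        assert res.statistic == n * n / 2.0

    def test_u_complement_identity(self):
        rng = np.random.default_rng(8)
        a, b = rng.standard_normal(12), rng.standard_normal(9)
        ua = mann_whitney(a, b).statistic
        ub = mann_whitney(b, a).statistic
        assert ua + ub == pytest.approx(12 * 9)

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(9)
        a = rng.permutation(20)[:4].astype(float)
        b = np.setdiff1d(np.arange(20), a)[:5].astype(float)
        res = mann_whitney(a, b)
        assert res.method == "exact"
        assert res.p == pytest.approx(_exact_u_pvalue(a, b, res.statistic),
                                      abs=1e-9)

    def test_ties_fall_back_to_corrected_normal(self):
        res = mann_whitney([1, 2, 2, 3], [2, 3, 3, 4])
        assert res.method == "asymptotic"
        expected = sps.mannwhitneyu(
            [1, 2, 2, 3], [2, 3, 3, 4], method="asymptotic",
            use_continuity=False,
        ).pvalue
        assert res.p == pytest.approx(float(expected))

    def test_group_summaries_feed_the_report_tables(self):
        res = mann_whitney([3, 1, 7], [2, 8])
        assert res.group_summaries[0] == {"n": 3, "median": 3.0, "min": 1.0,
                                          "max": 7.0}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)

    def test_three_singletons(self):
        res = kruskal_wallis([[1], [2], [3]])
        assert res.statistic == pytest.approx(2.0)
        assert res.df == 2

    def test_two_groups_consistent_with_mann_whitney_normal_approx(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal(15)
        b = rng.standard_normal(12) + 0.5
        kw = kruskal_wallis([a, b])
        mw = mann_whitney(a, b, exact_max_n=0)  # force normal approximation
        # H = z^2 for two untied groups => identical p-values
        assert kw.p == pytest.approx(mw.p, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestStudentT:
    def test_identical_distributions_give_zero(self):
        res = student_t([1, 2, 3], [2, 1, 3])
        assert res.statistic == pytest.approx(0.0)

    def test_hand_computed_pooled_t(self):
        res = student_t([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.22474487, abs=1e-6)
        assert res.df == 4

    def test_degrees_of_freedom_sum_rule(self):
        rng = np.random.default_rng(6)
        res = student_t(rng.standard_normal(73), rng.standard_normal(46))
        assert res.df == 117

    def test_zero_variance_degenerate(self):
        with pytest.raises(ValueError, match="zero"):
            student_t([0, 0], [1, 1])


class TestChiSquare:
    def test_independent_table_gives_zero(self):
        res = chi_square_2x2([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)

    def test_perfect_association_equals_n(self):
        res = chi_square_2x2([[20, 0], [0, 20]])
        assert res.statistic == pytest.approx(40.0)
        assert res.df == 1

    def test_zero_margin_names_the_margin(self):
        with pytest.raises(ValueError, match="column margin"):
            chi_square_2x2([[5, 0], [3, 0]])
        with pytest.raises(ValueError, match="row margin"):
            chi_square_2x2([[0, 0], [3, 2]])


class TestKsNormality:
    def test_type_one_error_calibration(self):
        """Standard-normal samples should pass the gate at least 94% of
        the time at alpha .05."""
        passes = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(5000)
            passes += ks_normality(x, variable="x").normal
        assert passes >= 94

    def test_detects_lognormal_skew(self):
        x = np.exp(np.random.default_rng(0).standard_normal(200))
        res = ks_normality(x, variable="x")
        assert not res.normal and res.p < 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality([3, 3, 3, 3], variable="c")

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1, 2, 3], variable="x")


class TestItemCriterion:
    def test_type_one_calibration_under_independence(self):
        rejections = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            flag = pd.Series(rng.random(2000) < 0.3)
            scores = pd.DataFrame({"y": rng.standard_normal(2000)})
            table = item_criterion_comparison(flag, scores)
            rejections += table.loc["y", "p"] <= 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_perfect_separation_is_significant(self):
        rng = np.random.default_rng(2)
        y = pd.Series(rng.standard_normal(200))
        flag = y > y.median()
        table = item_criterion_comparison(flag, pd.DataFrame({"y": y}))
        assert table.loc["y", "p"] < 1e-3

    def test_table_layout_matches_group_summaries(self):
        flag = pd.Series([True, True, False, False, False])
        scores = pd.DataFrame({"y": [5.0, 7.0, 1.0, 2.0, 3.0]})
        table = item_criterion_comparison(flag, scores)
        row = table.loc["y"]
        assert (row["n_yes"], row["mdn_yes"], row["min_yes"], row["max_yes"]) \
            == (2, 6.0, 5.0, 7.0)
        assert (row["n_no"], row["mdn_no"]) == (3, 2.0)
        assert row["U"] == 6.0  # complete separation: all cross-pairs won

    def test_all_negative_indicator_rejected(self):
        flag = pd.Series([False] * 5)
        scores = pd.DataFrame({"y": [1.0, 2, 3, 4, 5]})
        with pytest.raises(ValueError, match="empty group"):
            item_criterion_comparison(flag, scores)


class TestDescriptives:
    def test_indicator_counts_and_percentages(self):
        profiles = pd.DataFrame({
            "smoking_mother": [True, True] + [False] * 8,
        }, index=[f"r{i}" for i in range(10)])
        table = descriptives(profiles, ["smoking_mother"])
        assert table.loc["smoking_mother", "n"] == 2
        assert table.loc["smoking_mother", "pct"] == pytest.approx(20.0)

    def test_subgroup_split_with_difference_test(self):
        rng = np.random.default_rng(13)
        n = 60
        profiles = pd.DataFrame({"flagged": rng.random(n) < 0.4},
                                index=[f"r{i}" for i in range(n)])
        sub = pd.Series(rng.random(n) < 0.5, index=profiles.index)
        table = descriptives(profiles, ["flagged"], subgroup=sub)
        assert table.loc["flagged", "n_in"] + table.loc["flagged", "n_out"] \
            == table.loc["flagged", "n"]
        assert 0 <= table.loc["flagged", "p_diff"] <= 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            descriptives(pd.DataFrame(), ["x"])
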