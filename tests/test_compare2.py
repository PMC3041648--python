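"""Two-group and k-group comparisons, checked against independent oracles."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pepikit as pk
from pepikit import compare2 as c2


# ---------------------------------------------------------------------------
# Effect measures


class TestOddsRatio:
    def test_hand_computed_woolf_interval(self):
        # exp(ln 4 +/- 1.96 sqrt(1/10 + 1/20 + 1/5 + 1/40))
        est = c2.odds_ratio(pk.build_2x2(10, 20, 5, 40))
        assert est.point == 4.0
        se = math.sqrt(1 / 10 + 1 / 20 + 1 / 5 + 1 / 40)
        z = stats.norm.ppf(0.975)
        assert est.ci().low == pytest.approx(4 * math.exp(-z * se), rel=1e-9)
        assert est.ci().high == pytest.approx(4 * math.exp(z * se), rel=1e-9)

    @pytest.mark.parametrize("k", [1, 3, 17])
    def test_symmetric_table_is_null(self, k):
        assert c2.odds_ratio(pk.build_2x2(k, k, k, k)).point == 1.0

    def test_zero_denominator_flagged_not_nan(self):
        est = c2.odds_ratio(pk.build_2x2(10, 0, 5, 40), correction=None)
        assert est.point == math.inf
        assert "upper_unbounded" in est.flags

    def test_exact_interval_matches_scipy_conditional(self):
        table = pk.build_2x2(10, 20, 5, 40)
        est = c2.odds_ratio(table, method="exact")
        ref = stats.contingency.odds_ratio([[10, 20], [5, 40]], kind="conditional")
        assert est.point == pytest.approx(ref.statistic)
        ci = ref.confidence_interval(0.95)
        assert tuple(est.ci()) == pytest.approx((ci.low, ci.high))

    @pytest.mark.parametrize("m", [1, 2, 5])
    def test_interval_shrinks_with_scaled_cells(self, m):
        base = c2.odds_ratio(pk.build_2x2(10, 20, 5, 40)).ci()
        scaled = c2.odds_ratio(pk.build_2x2(10 * 2 * m, 20 * 2 * m, 5 * 2 * m, 40 * 2 * m)).ci()
        assert scaled.high / scaled.low < base.high / base.low


class TestRiskRatioAndDifference:
    def test_point_values(self):
        table = pk.build_2x2(10, 90, 5, 95)
        assert c2.risk_ratio(table).point == pytest.approx(2.0)
        assert c2.risk_difference(table).point == pytest.approx(0.05)

    def test_identical_rows_null(self):
        table = pk.build_2x2(7, 13, 7, 13)
        assert c2.risk_ratio(table).point == 1.0
        assert c2.risk_difference(table).point == 0.0

    def test_katz_interval_hand_evaluation(self):
        table = pk.build_2x2(10, 90, 5, 95)
        se = math.sqrt(1 / 10 - 1 / 100 + 1 / 5 - 1 / 100)
        z = stats.norm.ppf(0.975)
        est = c2.risk_ratio(table)
        assert est.ci().low == pytest.approx(2 * math.exp(-z * se), rel=1e-9)
        assert est.ci().high == pytest.approx(2 * math.exp(z * se), rel=1e-9)

    def test_newcombe_interval_contains_point(self):
        table = pk.build_2x2(10, 90, 5, 95)
        est = c2.risk_difference(table, method="newcombe")
        assert est.point in est.ci()

    @pytest.mark.parametrize("m", [2, 4, 8])
    def test_intervals_shrink_with_sample_size(self, m):
        small = pk.build_2x2(10, 90, 5, 95)
        big = pk.build_2x2(10 * m, 90 * m, 5 * m, 95 * m)
        for fn in (c2.risk_ratio, lambda t: c2.risk_difference(t, method="wald")):
            assert fn(big).ci().width < fn(small).ci().width


# ---------------------------------------------------------------------------
# Tests of association


class TestChiSquare2x2:
    def test_identical_rows_null(self):
        for res in c2.chi_square_2x2(pk.build_2x2(5, 10, 5, 10)):
            assert res.statistic == pytest.approx(0.0)
            assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        # n (ad-bc)^2 / (r1 r2 c1 c2) = 6 * 81 / 81 = 6
        pearson = c2.chi_square_2x2(pk.build_2x2(3, 0, 0, 3))[0]
        assert pearson.statistic == pytest.approx(6.0)

    def test_yates_shrinks_statistic(self):
        table = pk.build_2x2(10, 20, 5, 40)
        plain = c2.chi_square_2x2(table, yates=False)[0].statistic
        corrected = c2.chi_square_2x2(table, yates=True)[0].statistic
        assert corrected < plain

    def test_zero_margin_degenerate(self):
        res = c2.chi_square_2x2(pk.build_2x2(0, 0, 5, 10))
        assert all(r.statistic == 0 and r.p_value == 1 for r in res)
        assert all("degenerate_margin" in r.flags for r in res)

    @given(st.tuples(*[st.integers(0, 40)] * 4).filter(lambda c: sum(c) > 0))
    @settings(max_examples=150, derandomize=True)
    def test_lr_statistic_nonnegative(self, cells):
        results = c2.chi_square_2x2(pk.TwoByTwoTable(*cells))
        assert results[1].statistic >= 0


def _fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration with exact rational pmf."""
    from fractions import Fraction

    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = math.comb(n, c1)
    probs = {
        k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisherExact:
    @pytest.mark.parametrize(
        "cells,expected",
        [((3, 0, 0, 3), 0.1), ((2, 0, 0, 2), 1 / 3)],
    )
    def test_enumeration_examples(self, cells, expected):
        assert c2.fisher_exact(pk.build_2x2(*cells)).p_value == pytest.approx(expected)

    def test_matches_scipy(self):
        for cells in [(10, 20, 5, 40), (1, 9, 11, 3), (5, 0, 1, 4)]:
            ours = c2.fisher_exact(pk.build_2x2(*cells)).p_value
            theirs = stats.fisher_exact([[cells[0], cells[1]], [cells[2], cells[3]]])[1]
            assert ours == pytest.approx(theirs, rel=1e-9)

    @given(st.tuples(*[st.integers(0, 12)] * 4).filter(lambda c: sum(c) > 0))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_mid_p_never_exceeds_standard(self, cells):
        table = pk.TwoByTwoTable(*cells)
        standard = c2.fisher_exact(table).p_value
        mid = c2.fisher_exact(table, mid_p=True).p_value
        assert mid <= standard + 1e-12

    def test_one_sided_is_smaller_tail(self):
        table = pk.build_2x2(8, 2, 2, 8)
        one = c2.fisher_exact(table, sidedness="one").p_value
        two = c2.fisher_exact(table).p_value
        assert one <= two


class TestChiSquareCalibration:
    def test_null_rejection_rate_near_nominal(self):
        """Uncorrected Pearson chi-square at alpha = 0.05 under
        p1 = p2 = 0.3, n = 50 per group: the Monte-Carlo rejection rate
        should sit inside the binomial 99% band around 0.05."""
        rng = np.random.default_rng(20260927)
        reps = 2000
        n = 50
        a = rng.binomial(n, 0.3, size=reps)
        c = rng.binomial(n, 0.3, size=reps)
        rejections = 0
        for ai, ci in zip(a, c):
            res = c2.chi_square_2x2(pk.TwoByTwoTable(ai, n - ai, ci, n - ci))[0]
            rejections += res.p_value < 0.05
        rate = rejections / reps
        half = 2.576 * math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < half + 0.005  # chi-square approx is slightly conservative


# ---------------------------------------------------------------------------
# Stratified analysis


class TestMantelHaenszel:
    def test_single_stratum_reduces_to_crude(self):
        table = pk.build_2x2(10, 20, 5, 40)
        strata = pk.StratifiedTwoByTwo((("only", table),))
        res = c2.mantel_haenszel(strata)
        assert res.pooled.point == pytest.approx(c2.odds_ratio(table).point)

    def test_identical_strata_homogeneous(self):
        table = pk.build_2x2(10, 20, 5, 40)
        strata = pk.StratifiedTwoByTwo((("s1", table), ("s2", table)))
        res = c2.mantel_haenszel(strata)
        assert res.pooled.point == pytest.approx(4.0)
        assert res.heterogeneity.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.heterogeneity.p_value == pytest.approx(1.0)
        assert res.heterogeneity.df == 1

    def test_pooled_or_matches_statsmodels(self):
        import statsmodels.stats.contingency_tables as ct

        tables = [pk.build_2x2(12, 18, 7, 33), pk.build_2x2(4, 46, 2, 58)]
        strata = pk.StratifiedTwoByTwo(tuple((f"s{i}", t) for i, t in enumerate(tables)))
        ours = c2.mantel_haenszel(strata)
        ref = ct.StratifiedTable([t.to_array() for t in tables])
        assert ours.pooled.point == pytest.approx(ref.oddsratio_pooled)
        lo, hi = ref.oddsratio_pooled_confint(alpha=0.05)
        assert tuple(ours.pooled.ci()) == pytest.approx((lo, hi), rel=1e-6)

    def test_pooled_rr_matches_statsmodels(self):
        import statsmodels.stats.contingency_tables as ct

        tables = [pk.build_2x2(12, 18, 7, 33), pk.build_2x2(4, 46, 2, 58)]
        strata = pk.StratifiedTwoByTwo(tuple((f"s{i}", t) for i, t in enumerate(tables)))
        ours = c2.mantel_haenszel(strata, measure="rr")
        ref = ct.StratifiedTable([t.to_array() for t in tables])
        assert ours.pooled.point == pytest.approx(ref.riskratio_pooled)

    def test_confounded_fixture_recovered(self):
        """On a confounded synthetic dataset the pooled estimate recovers
        the generating stratum OR while the crude OR is biased away."""
        from pepikit.fixtures import FixtureSpec, generate_fixture

        fx = generate_fixture(
            FixtureSpec("stratified_confounded", {"n_per_stratum": 100_000}, seed=11)
        )
        pooled = c2.mantel_haenszel(fx.data).pooled.point
        crude = c2.odds_ratio(fx.data.collapsed()).point
        truth = fx.truth["stratum_or"]
        assert pooled == pytest.approx(truth, rel=0.03)
        assert abs(crude - truth) / truth > 0.25

    def test_all_uninformative_errors(self):
        strata = pk.StratifiedTwoByTwo((("s", pk.build_2x2(0, 5, 0, 5)),))
        with pytest.raises(ValueError, match="uninformative"):
            c2.mantel_haenszel(strata)


# ---------------------------------------------------------------------------
# Ordered categories


class TestCochranArmitage:
    def test_equal_proportions_null(self):
        res = c2.cochran_armitage_trend(pk.OrderedTwoByK((10, 10, 10), (10, 10, 10)))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_score_reversal_negates_z(self):
        table = pk.OrderedTwoByK((5, 10, 20), (20, 10, 5))
        forward = c2.cochran_armitage_trend(table)
        backward = c2.cochran_armitage_trend(
            pk.OrderedTwoByK(table.row1, table.row2, scores=(3, 2, 1))
        )
        assert backward.statistic == pytest.approx(-forward.statistic)
        assert backward.p_value == pytest.approx(forward.p_value)

    def test_increasing_proportions_positive_z(self):
        res = c2.cochran_armitage_trend(pk.OrderedTwoByK((1, 10, 30), (30, 10, 1)))
        assert res.statistic > 0

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="scores"):
            c2.cochran_armitage_trend(pk.OrderedTwoByK((1, 2), (3, 4), scores=(2, 2)))


def _pair_probabilities(row1, row2):
    """Brute force over all n1*n2 cross-group pairs."""
    gt = lt = tie = 0
    for i, n_i in enumerate(row1):
        for j, n_j in enumerate(row2):
            count = n_i * n_j
            if i > j:
                gt += count
            elif i < j:
                lt += count
            else:
                tie += count
    total = sum(row1) * sum(row2)
    return gt / total, lt / total, tie / total


class TestRidit:
    def test_reference_mean_ridit_is_half(self):
        res = c2.ridit_analysis(pk.OrderedTwoByK((3, 9, 2, 7), (1, 1, 1, 1)))
        assert res.mean_ridit_reference == pytest.approx(0.5)

    def test_identical_rows_comparison_half(self):
        res = c2.ridit_analysis(pk.OrderedTwoByK((5, 10, 5), (5, 10, 5)))
        assert res.mean_ridit_comparison == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "row1,row2",
        [((10, 20, 30), (30, 20, 10)), ((1, 0, 5, 2), (4, 4, 0, 1)), ((7, 3), (2, 8))],
    )
    def test_mean_ridit_equals_pair_enumeration(self, row1, row2):
        """Comparison mean ridit = P(comparison > reference) + P(tie)/2."""
        res = c2.ridit_analysis(pk.OrderedTwoByK(row1, row2), reference="row1")
        gt, _, tie = _pair_probabilities(row2, row1)
        assert res.mean_ridit_comparison == pytest.approx(gt + tie / 2)


class TestGeneralizedOddsRatio:
    def test_identical_rows_is_one(self):
        est = c2.generalized_odds_ratio(pk.OrderedTwoByK((5, 10, 5), (5, 10, 5)))
        assert est.point == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "row1,row2",
        [((10, 20, 30), (30, 20, 10)), ((1, 0, 5, 2), (4, 4, 0, 1)), ((3, 9), (8, 2))],
    )
    def test_point_equals_pair_enumeration(self, row1, row2):
        est = c2.generalized_odds_ratio(pk.OrderedTwoByK(row1, row2))
        gt, lt, _ = _pair_probabilities(row1, row2)
        assert est.point == pytest.approx(gt / lt)

    def test_k2_reduction_to_ordinary_or(self):
        """With two categories the generalized OR is the cross-product
        ratio bc/ad of the table (row1, row2) x (low, high) — row 1 'greater'
        means row 1 in the high category while row 2 is in the low one."""
        a, b, c, d = 10, 20, 5, 40
        est = c2.generalized_odds_ratio(pk.OrderedTwoByK((a, b), (c, d)))
        assert est.point == pytest.approx((b * c) / (a * d))

    def test_k2_interval_matches_woolf(self):
        """The delta-method interval must collapse to the Woolf interval
        in the 2-category case."""
        est = c2.generalized_odds_ratio(pk.OrderedTwoByK((10, 20), (5, 40)))
        se = math.sqrt(1 / 10 + 1 / 20 + 1 / 5 + 1 / 40)
        z = stats.norm.ppf(0.975)
        assert est.ci().low == pytest.approx(est.point * math.exp(-z * se), rel=1e-9)

    def test_zero_discordance_flagged(self):
        est = c2.generalized_odds_ratio(pk.OrderedTwoByK((0, 5), (5, 0)))
        assert est.point == math.inf
        assert "upper_unbounded" in est.flags


# ---------------------------------------------------------------------------
# r x c analysis


class TestRxC:
    def test_uniform_table_null(self):
        res = c2.rxc_analysis(pk.RxCTable(np.full((3, 3), 7)))
        assert res.pearson.statistic == pytest.approx(0.0)
        assert np.allclose(res.adjusted_residuals, 0.0)

    def test_diagonal_table_perfect_association(self):
        res = c2.rxc_analysis(pk.RxCTable(np.array([[12, 0], [0, 12]])))
        assert res.cramers_v == pytest.approx(1.0)

    @given(
        st.lists(st.lists(st.integers(0, 30), min_size=3, max_size=3), min_size=3, max_size=3)
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_pearson_equals_brute_force(self, grid):
        arr = np.array(grid, dtype=float)
        if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
            return
        res = c2.rxc_analysis(pk.RxCTable(arr))
        expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
        brute = float(((arr - expected) ** 2 / expected).sum())
        assert res.pearson.statistic == pytest.approx(brute)

    def test_matches_scipy_chi2_contingency(self):
        arr = np.array([[10, 5, 8], [3, 12, 9]])
        res = c2.rxc_analysis(pk.RxCTable(arr))
        chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
        assert res.pearson.statistic == pytest.approx(chi2)
        assert res.pearson.p_value == pytest.approx(p)
        assert res.pearson.df == df
        g2, p_lr, _, _ = stats.chi2_contingency(arr, correction=False,
                                                lambda_="log-likelihood")
        assert res.likelihood_ratio.statistic == pytest.approx(g2)

    def test_zero_margin_dropped(self):
        arr = np.array([[5, 0, 5], [5, 0, 5], [0, 0, 0]])
        res = c2.rxc_analysis(pk.RxCTable(arr))
        assert res.dropped_rows == (2,)
        assert res.dropped_cols == (1,)

    def test_ordered_columns_add_trend_and_ranks(self):
        table = pk.RxCTable(np.array([[20, 10, 5], [5, 10, 20]]), col_ordered=True)
        res = c2.rxc_analysis(table)
        assert res.trend is not None and res.trend.p_value < 0.01
        assert res.kruskal_wallis_ranks is not None

    def test_pairwise_columns_bonferroni(self):
        res = c2.rxc_analysis(pk.RxCTable(np.array([[20, 20, 2], [20, 20, 38]])))
        assert len(res.pairwise_columns) == 3
        # identical first two columns: adjusted P capped at 1
        assert res.pairwise_columns[0].p_value == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# k numeric samples


class TestKruskalWallis:
    def test_identical_groups_zero(self):
        samples = pk.GroupedNumericSamples((np.array([1.0, 2, 3]), np.array([1.0, 2, 3])))
        assert c2.kruskal_wallis(samples).statistic == pytest.approx(0.0)

    def test_label_permutation_invariance(self):
        g = (np.array([1.0, 5, 2]), np.array([3.0, 8, 9]), np.array([2.0, 2, 4]))
        h1 = c2.kruskal_wallis(pk.GroupedNumericSamples(g)).statistic
        h2 = c2.kruskal_wallis(pk.GroupedNumericSamples(g[::-1])).statistic
        assert h1 == pytest.approx(h2)

    def test_all_identical_flagged(self):
        samples = pk.GroupedNumericSamples((np.array([2.0, 2]), np.array([2.0, 2])))
        res = c2.kruskal_wallis(samples)
        assert res.statistic == 0 and res.p_value == 1
        assert "all_identical" in res.flags

    def test_matches_hand_rank_computation(self):
        """Tie-free case: H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)."""
        groups = (np.array([1.0, 3, 5]), np.array([2.0, 4, 6]), np.array([7.0, 8, 9]))
        n = 9
        rank_sums = [1 + 3 + 5, 2 + 4 + 6, 7 + 8 + 9]
        h_hand = 12 / (n * (n + 1)) * sum(r * r / 3 for r in rank_sums) - 3 * (n + 1)
        res = c2.kruskal_wallis(pk.GroupedNumericSamples(groups))
        assert res.statistic == pytest.approx(h_hand)


class TestAnovaWithEffects:
    def test_identical_groups_f_zero(self):
        g = np.array([1.0, 2, 3, 4])
        res = c2.anova_with_effects(pk.GroupedNumericSamples((g, g.copy())))
        assert res.f_test.statistic == pytest.approx(0.0)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        g1, g2 = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        res = c2.anova_with_effects(pk.GroupedNumericSamples((g1, g2)))
        t, p = stats.ttest_ind(g1, g2)
        assert res.f_test.statistic == pytest.approx(t * t)
        assert res.f_test.p_value == pytest.approx(p)

    def test_location_invariance(self):
        rng = np.random.default_rng(6)
        groups = tuple(rng.normal(m, 1, 10) for m in (0, 0.5, 1.0))
        shifted = tuple(g + 100.0 for g in groups)
        r1 = c2.anova_with_effects(pk.GroupedNumericSamples(groups))
        r2 = c2.anova_with_effects(pk.GroupedNumericSamples(shifted))
        assert r1.f_test.statistic == pytest.approx(r2.f_test.statistic)
        assert r1.omega_squared == pytest.approx(r2.omega_squared)
        assert r1.cohens_f == pytest.approx(r2.cohens_f)

    def test_omega_leq_adjusted_eta(self):
        rng = np.random.default_rng(7)
        groups = tuple(rng.normal(m, 1, 15) for m in (0, 1, 2))
        res = c2.anova_with_effects(pk.GroupedNumericSamples(groups))
        assert res.omega_squared <= res.eta_squared_adjusted + 1e-9

    def test_f_matches_scipy(self):
        rng = np.random.default_rng(8)
        groups = tuple(rng.normal(m, 1, 10) for m in (0, 0.3, 0.9))
        res = c2.anova_with_effects(pk.GroupedNumericSamples(groups))
        f, p = stats.f_oneway(*groups)
        assert res.f_test.statistic == pytest.approx(f)
        assert res.f_test.p_value == pytest.approx(p)

    def test_linear_trend_detects_monotone_means(self):
        rng = np.random.default_rng(9)
        groups = tuple(rng.normal(m, 0.5, 20) for m in (0.0, 1.0, 2.0))
        res = c2.anova_with_effects(pk.GroupedNumericSamples(groups))
        assert res.trend_slope == pytest.approx(1.0, abs=0.3)
        assert res.linear_trend.p_value < 1e-6
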