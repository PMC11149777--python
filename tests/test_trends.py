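"""Median aggregation, trend fits, rank-sum tests, per-aa correlations, 2×2."""

import math
from itertools import combinations

import numpy as np
import pytest

from denovostruct.io_formats import BranchTable
from denovostruct.trends import (
    TrendFit,
    TwoByTwo,
    branch_medians,
    fisher_exact_p,
    fit_linear_trend,
    fit_log10_trend,
    per_aa_age_correlation,
    rate_percent_per_my,
    ratio_2x2,
    time_to_benchmark,
    wilcoxon_rank_sum,
)


def ols_normal_equations(points):
    """Closed-form slope/intercept from the normal equations."""
    pts = np.asarray(points, float)
    t, y = pts[:, 0], pts[:, 1]
    n = t.size
    sxx = (t**2).sum() - t.sum() ** 2 / n
    sxy = (t * y).sum() - t.sum() * y.sum() / n
    slope = sxy / sxx
    return slope, y.mean() - slope * t.mean()


def rank_sum_enumeration(x, y, alternative):
    """Exact null distribution of U by enumerating all rank splits."""
    x, y = list(x), list(y)
    nx = len(x)
    combined = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(combined)}  # assumes no ties
    u_obs = sum(ranks[v] for v in x) - nx * (nx + 1) / 2
    n = len(combined)
    us = []
    for idx in combinations(range(n), nx):
        r = sum(i + 1 for i in idx)
        us.append(r - nx * (nx + 1) / 2)
    us = np.asarray(us, float)
    if alternative == "less":
        return float(np.mean(us <= u_obs))
    if alternative == "greater":
        return float(np.mean(us >= u_obs))
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return float(min(1.0, p))


class TestBranchMedians:
    def test_odd_list(self, six_branch_table):
        pts = branch_medians({"br1": [0.2, 0.4, 0.9]}, six_branch_table)
        assert pts == [(0.1, 0.4)]

    def test_even_list_central_pair_mean(self, six_branch_table):
        pts = branch_medians({"br2": [1, 2, 3, 4]}, six_branch_table)
        assert pts == [(0.3, 2.5)]

    def test_matches_sort_oracle_and_time_order(self, six_branch_table, rng):
        values = {
            b: rng.uniform(size=rng.integers(5, 30)).tolist()
            for b in six_branch_table.ids
        }
        pts = branch_medians(values, six_branch_table)
        assert [t for t, _ in pts] == sorted(t for t, _ in pts)
        for b in six_branch_table.ids:
            vals = sorted(values[b])
            n = len(vals)
            med = (vals[(n - 1) // 2] + vals[n // 2]) / 2
            t = six_branch_table.time_of(b)
            assert dict(pts)[t] == pytest.approx(med)

    def test_empty_branch_errors(self, six_branch_table):
        with pytest.raises(ValueError):
            branch_medians({"br1": []}, six_branch_table)


class TestLinearTrend:
    def test_exact_line(self):
        fit = fit_linear_trend([(0, 1.0), (1, 0.9), (2, 0.8)])
        assert fit.slope == pytest.approx(-0.1)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_flat_points_have_no_trend(self):
        fit = fit_linear_trend([(0, 0.5), (1, 0.5), (2, 0.5), (3, 0.5)])
        assert fit.slope == pytest.approx(0.0)
        assert fit.p_value == pytest.approx(1.0)

    def test_matches_normal_equations(self, rng):
        for _ in range(20):
            pts = [(float(t), float(rng.normal())) for t in range(6)]
            fit = fit_linear_trend(pts)
            slope, intercept = ols_normal_equations(pts)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_trend([(0, 1), (0, 2), (1, 3)])

    def test_rate_helper_scales_proportion_slope(self):
        fit = fit_linear_trend([(0, 0.9), (1, 0.76), (2, 0.62)])
        assert rate_percent_per_my(fit) == pytest.approx(14.0)


class TestLog10Trend:
    def test_exact_in_log_space(self):
        fit = fit_log10_trend([(1, 0.3), (10, 0.2), (100, 0.1)])
        assert fit.slope == pytest.approx(-0.1)
        assert fit.time_scale == "log10"

    def test_zero_time_rejected(self):
        with pytest.raises(ValueError):
            fit_log10_trend([(0, 0.3), (1, 0.2), (10, 0.1)])


class TestTimeToBenchmark:
    def _fit(self, intercept, slope):
        return TrendFit(slope=slope, intercept=intercept, p_value=0.01,
                        adj_r2=0.9, n_points=6)

    def test_simple_arithmetic(self):
        assert time_to_benchmark(self._fit(1.0, -0.1), 0.5) == pytest.approx(5.0)

    def test_disorder_benchmark_arithmetic(self):
        # de novo ISD trend (0.97 − 0.14 t) reaching the duplicate median 0.31
        assert time_to_benchmark(self._fit(0.97, -0.14), 0.31) == pytest.approx(
            4.71, abs=0.005
        )

    def test_benchmark_behind_the_trend_errors(self):
        with pytest.raises(ValueError):
            time_to_benchmark(self._fit(1.0, 0.1), 0.5)

    def test_benchmark_at_intercept_is_now(self):
        assert time_to_benchmark(self._fit(0.8, -0.1), 0.8) == 0.0


class TestWilcoxonRankSum:
    def test_smallest_one_sided_case(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4], "less") == pytest.approx(1 / 6)

    def test_identical_samples_two_sided(self):
        p = wilcoxon_rank_sum([1, 2, 3, 4, 5] * 4, [1, 2, 3, 4, 5] * 4, "two_sided")
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("nx,ny", [(2, 2), (3, 3), (2, 5), (4, 5), (6, 6)])
    @pytest.mark.parametrize("alternative", ["less", "greater", "two_sided"])
    def test_exact_branch_equals_enumeration(self, nx, ny, alternative, rng):
        vals = rng.permutation(np.arange(1.0, nx + ny + 1))
        x, y = vals[:nx], vals[nx:]
        assert wilcoxon_rank_sum(x, y, alternative) == pytest.approx(
            rank_sum_enumeration(x, y, alternative), abs=1e-12
        )

    def test_large_sample_matches_normal_approximation_oracle(self, rng):
        x = rng.normal(0.0, 1.0, size=40)
        y = rng.normal(0.5, 1.0, size=35)
        # independent hand-coded normal approximation with continuity correction
        nx, ny = len(x), len(y)
        combined = np.concatenate([x, y])
        order = combined.argsort()
        ranks = np.empty_like(combined)
        ranks[order] = np.arange(1, nx + ny + 1)
        u = ranks[:nx].sum() - nx * (nx + 1) / 2
        mu = nx * ny / 2
        sigma = math.sqrt(nx * ny * (nx + ny + 1) / 12)
        from scipy.stats import norm

        p_hand = 2 * norm.sf((abs(u - mu) - 0.5) / sigma)
        assert wilcoxon_rank_sum(x, y, "two_sided") == pytest.approx(p_hand, abs=1e-6)


class TestPerAaCorrelation:
    def test_perfectly_increasing_medians(self):
        out = per_aa_age_correlation({"K": [(0, 0.1), (1, 0.2), (2, 0.3)]})
        assert out["K"][0] == pytest.approx(1.0)

    def test_constant_medians_flagged(self):
        out = per_aa_age_correlation({"A": [(0, 0.1), (1, 0.1), (2, 0.1)]})
        assert math.isnan(out["A"][0])

    def test_sign_convention(self):
        out = per_aa_age_correlation(
            {
                "G": [(0, 0.3), (1, 0.25), (2, 0.18)],
                "Y": [(0, 0.02), (1, 0.03), (2, 0.05)],
            }
        )
        assert out["G"][0] < 0 < out["Y"][0]


class TestRatio2x2:
    def test_equal_rates_give_unity(self):
        est, lo, hi, _ = ratio_2x2(TwoByTwo(10, 10, 20, 20), "risk")
        assert est == pytest.approx(1.0)

    def test_young_vs_old_parent_risk_ratio(self):
        est, lo, hi, p = ratio_2x2(TwoByTwo(53, 215, 26, 252), "risk")
        assert est == pytest.approx(2.389, abs=5e-4)
        assert lo < est < hi
        assert p < 0.001

    def test_young_vs_old_parent_odds_ratio(self):
        est, *_ = ratio_2x2(TwoByTwo(53, 215, 26, 252), "odds")
        assert est == pytest.approx(2.844, abs=5e-4)

    def test_zero_cell_continuity_correction(self):
        est, lo, hi, p = ratio_2x2(TwoByTwo(0, 10, 5, 10), "risk")
        assert est > 0
        with pytest.raises(ValueError):
            ratio_2x2(TwoByTwo(0, 10, 5, 10), "risk", continuity=None)

    def test_fisher_route_agrees_in_order_of_magnitude(self):
        p_wald = ratio_2x2(TwoByTwo(53, 215, 26, 252), "risk")[3]
        p_fisher = fisher_exact_p(TwoByTwo(53, 215, 26, 252))
        assert p_fisher < 0.01 and p_wald < 0.01
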