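import numpy as np
import pytest

from tsmr.harmonization import HarmonizedSet
from tsmr.mr_estimators import (
    egger,
    estimate_all,
    ivw,
    max_likelihood,
    median_estimate,
    to_odds_ratio,
    wald_ratios,
)
from tsmr.synthetic_data import SimulationConfig, simulate_pair
from tsmr.harmonization import harmonize

from .conftest import random_harmonized


def wls_through_origin(x, y, w):
    """Generic weighted-least-squares oracle via normal equations."""
    beta = float((w * x * y).sum() / (w * x * x).sum())
    se = float((w * x * x).sum() ** -0.5)
    return beta, se


def wls_with_intercept(x, y, w):
    """Generic 2-parameter WLS oracle via explicit normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    coef = np.linalg.solve(A, b)
    cov = np.linalg.inv(A)
    return coef, cov


class TestWaldRatios:
    def test_direct_arithmetic(self):
        h = HarmonizedSet.from_arrays([0.1], [0.01], [0.05], [0.1])
        r = wald_ratios(h)
        assert r.ratio[0] == pytest.approx(0.5)
        assert r.ratio_se[0] == pytest.approx(1.0)

    def test_sign_flip_symmetry(self):
        h1 = HarmonizedSet.from_arrays([0.1], [0.01], [0.05], [0.1])
        h2 = HarmonizedSet.from_arrays([-0.1], [0.01], [-0.05], [0.1])
        assert wald_ratios(h1).ratio[0] == pytest.approx(wald_ratios(h2).ratio[0])

    def test_zero_exposure_beta_raises(self):
        h = HarmonizedSet.from_arrays([0.0, 0.1], [0.01, 0.01], [0.05, 0.02], [0.1, 0.1])
        with pytest.raises(ValueError, match="snp1"):
            wald_ratios(h)

    def test_first_order_le_second_order(self):
        h = random_harmonized(seed=3, j=40)
        first = wald_ratios(h, second_order=False)
        second = wald_ratios(h, second_order=True)
        assert np.all(first.ratio_se <= second.ratio_se + 1e-15)


class TestIvw:
    def test_single_snp_raises(self):
        h = HarmonizedSet.from_arrays([0.1], [0.01], [0.05], [0.1])
        with pytest.raises(ValueError, match=">= 2"):
            ivw(h)

    def test_two_identical_snps_meta_identity(self):
        h = HarmonizedSet.from_arrays([0.1, 0.1], [0.01, 0.01], [0.05, 0.05], [0.1, 0.1])
        est = ivw(h)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(1.0 / np.sqrt(2))

    def test_fixed_matches_wls_oracle_j50(self, h50):
        bx, sx, by, sy = h50.arrays()
        beta_o, se_o = wls_through_origin(bx, by, 1.0 / sy**2)
        est = ivw(h50, model="fixed")
        assert est.beta == pytest.approx(beta_o, abs=1e-10)
        assert est.se == pytest.approx(se_o, abs=1e-10)

    def test_random_se_floored_at_fixed(self):
        for seed in range(5):
            h = random_harmonized(seed=seed, j=15)
            assert ivw(h, "random").se >= ivw(h, "fixed").se - 1e-15
            assert ivw(h, "random").beta == pytest.approx(ivw(h, "fixed").beta)

    def test_penalized_downweights_outlier(self):
        h = random_harmonized(seed=12, j=30)
        bx, sx, by, sy = h.arrays()
        by = by.copy()
        by[0] += 15 * sy[0]  # gross outlier
        h_out = HarmonizedSet.from_arrays(bx, sx, by, sy)
        plain = ivw(h_out, "fixed")
        pen = ivw(h_out, "fixed", penalized=True)
        clean = ivw(h, "fixed")
        assert abs(pen.beta - clean.beta) < abs(plain.beta - clean.beta)

    def test_robust_resists_outlier(self):
        h = random_harmonized(seed=12, j=30)
        bx, sx, by, sy = h.arrays()
        by = by.copy()
        by[0] += 15 * sy[0]
        h_out = HarmonizedSet.from_arrays(bx, sx, by, sy)
        plain = ivw(h_out, "fixed")
        rob = ivw(h_out, "fixed", robust=True)
        clean = ivw(h, "fixed")
        assert abs(rob.beta - clean.beta) < abs(plain.beta - clean.beta)

    def test_allele_frame_invariance(self, h20):
        bx, sx, by, sy = h20.arrays()
        bx2, by2 = bx.copy(), by.copy()
        bx2[3] *= -1
        by2[3] *= -1
        h2 = HarmonizedSet.from_arrays(bx2, sx, by2, sy)
        for kwargs in [dict(), dict(model="random"), dict(penalized=True),
                       dict(penalized=True, robust=True)]:
            assert ivw(h2, **kwargs).beta == pytest.approx(
                ivw(h20, **kwargs).beta, abs=1e-8
            )


class TestEgger:
    def test_exact_line(self):
        bx = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        by = 0.01 + 0.5 * bx
        sy = np.full(5, 0.01)
        h = HarmonizedSet.from_arrays(bx, np.full(5, 0.001), by, sy)
        slope, intercept = egger(h)
        assert slope.beta == pytest.approx(0.5, abs=1e-12)
        assert intercept.beta == pytest.approx(0.01, abs=1e-12)
        # exact fit: residual scale 0 -> scaling floored at 1
        w = 1.0 / sy**2
        _, cov = wls_with_intercept(bx, by, w)
        assert intercept.se == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-12)
        assert slope.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-12)

    def test_matches_wls_oracle(self, h50):
        bx, sx, by, sy = h50.arrays()
        sign = np.where(bx < 0, -1.0, 1.0)
        x, y = bx * sign, by * sign
        w = 1.0 / sy**2
        coef, cov = wls_with_intercept(x, y, w)
        slope, intercept = egger(h50)
        assert intercept.beta == pytest.approx(coef[0], abs=1e-10)
        assert slope.beta == pytest.approx(coef[1], abs=1e-10)
        resid = y - coef[0] - coef[1] * x
        scale = max(1.0, np.sqrt((w * resid**2).sum() / (len(x) - 2)))
        assert intercept.se == pytest.approx(np.sqrt(cov[0, 0]) * scale, abs=1e-10)
        assert slope.se == pytest.approx(np.sqrt(cov[1, 1]) * scale, abs=1e-10)

    def test_orientation_invariance(self, h20):
        bx, sx, by, sy = h20.arrays()
        bx2, by2 = bx.copy(), by.copy()
        bx2[[1, 4]] *= -1
        by2[[1, 4]] *= -1
        h2 = HarmonizedSet.from_arrays(bx2, sx, by2, sy)
        s1, i1 = egger(h20)
        s2, i2 = egger(h2)
        assert s2.beta == pytest.approx(s1.beta, abs=1e-12)
        assert i2.beta == pytest.approx(i1.beta, abs=1e-12)

    def test_too_few_snps(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.03] * 2)
        with pytest.raises(ValueError, match=">= 3"):
            egger(h)


class TestMedians:
    def test_symmetric_three_ratios(self):
        h = HarmonizedSet.from_arrays(
            [1.0, 1.0, 1.0], [0.1] * 3, [0.1, 0.5, 0.9], [1.0] * 3
        )
        for weighting in ("simple", "weighted"):
            est = median_estimate(h, weighting, n_boot=100, seed=0)
            assert est.beta == pytest.approx(0.5)

    def test_equal_weights_weighted_equals_simple(self):
        h = HarmonizedSet.from_arrays(
            [1.0] * 5, [0.1] * 5, [0.1, 0.3, 0.5, 0.7, 1.1], [1.0] * 5
        )
        simple = median_estimate(h, "simple", n_boot=50, seed=0)
        weighted = median_estimate(h, "weighted", n_boot=50, seed=0)
        assert weighted.beta == pytest.approx(simple.beta)

    def test_even_j_mean_of_middle_two(self):
        h = HarmonizedSet.from_arrays(
            [1.0] * 4, [0.1] * 4, [0.1, 0.2, 0.6, 0.9], [1.0] * 4
        )
        est = median_estimate(h, "simple", n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.4)

    def test_seeded_determinism(self, h20):
        a = median_estimate(h20, "weighted", n_boot=10_000, seed=123)
        b = median_estimate(h20, "weighted", n_boot=10_000, seed=123)
        assert a.se == b.se
        assert a.beta == b.beta

    def test_estimate_within_ratio_range(self, h50):
        r = wald_ratios(h50)
        for weighting in ("simple", "weighted"):
            est = median_estimate(h50, weighting, n_boot=200, seed=5)
            assert r.ratio.min() - 1e-12 <= est.beta <= r.ratio.max() + 1e-12

    def test_too_few_snps(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.03] * 2)
        with pytest.raises(ValueError, match=">= 3"):
            median_estimate(h)


def ml_grid_oracle(bx, sx, by, sy, lo, hi):
    """Three-stage grid refinement of the profile objective."""
    def objective(thetas):
        t = thetas[:, None]
        return ((by - t * bx) ** 2 / (sy**2 + t**2 * sx**2)).sum(axis=1)

    for _ in range(3):
        grid = np.linspace(lo, hi, 2001)
        vals = objective(grid)
        k = int(np.argmin(vals))
        span = grid[1] - grid[0]
        lo, hi = grid[k] - 2 * span, grid[k] + 2 * span
    return float(grid[k])


class TestMaxLikelihood:
    def test_zero_exposure_noise_limit_equals_ivw(self):
        h = random_harmonized(seed=21, j=15)
        bx, sx, by, sy = h.arrays()
        h_exact = HarmonizedSet.from_arrays(bx, np.full_like(sx, 1e-12), by, sy)
        ml = max_likelihood(h_exact)
        fixed = ivw(h_exact, "fixed")
        assert ml.beta == pytest.approx(fixed.beta, abs=1e-8)
        assert ml.se == pytest.approx(fixed.se, rel=1e-4)

    def test_grid_oracle_j10(self):
        for seed in range(5):
            h = random_harmonized(seed=seed + 100, j=10)
            bx, sx, by, sy = h.arrays()
            ml = max_likelihood(h)
            grid = ml_grid_oracle(bx, sx, by, sy, ml.beta - 0.5, ml.beta + 0.5)
            assert ml.beta == pytest.approx(grid, abs=1e-6)

    def test_too_few_snps(self):
        h = HarmonizedSet.from_arrays([0.1], [0.01], [0.05], [0.1])
        with pytest.raises(ValueError, match=">= 2"):
            max_likelihood(h)


class TestToOddsRatio:
    def test_zero_beta_gives_unit_or(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2], [0.01] * 2, [0.0, 0.0], [0.03] * 2)
        est = to_odds_ratio(ivw(h))
        assert est.or_scale[0] == pytest.approx(1.0)

    def test_closed_form(self):
        from tsmr.mr_estimators import _estimate

        est = to_odds_ratio(_estimate("ivw_fixed", -0.274, 0.054, 100))
        orv, lo, hi = est.or_scale
        # independent closed form: exp(beta -/+ 1.96 * se)
        assert orv == pytest.approx(np.exp(-0.274), abs=1e-12)
        assert orv == pytest.approx(0.76, abs=0.005)
        assert lo == pytest.approx(np.exp(-0.274 - 1.959964 * 0.054), abs=1e-6)
        assert hi == pytest.approx(np.exp(-0.274 + 1.959964 * 0.054), abs=1e-6)
        assert lo == pytest.approx(0.684, abs=0.005)
        assert hi == pytest.approx(0.845, abs=0.005)

    def test_monotone_in_beta(self):
        from tsmr.mr_estimators import _estimate

        ors = [to_odds_ratio(_estimate("m", b, 0.05, 10)).or_scale[0]
               for b in np.linspace(-1, 1, 9)]
        assert all(a < b for a, b in zip(ors, ors[1:]))

    def test_ci_brackets_beta(self, h20):
        for est in estimate_all(h20, n_boot=100, seed=0):
            assert est.ci_low <= est.beta <= est.ci_high
            assert 0 < est.pval <= 1
            assert all(v > 0 for v in est.or_scale)


class TestEstimateAll:
    def test_eight_methods(self, h20):
        ests = estimate_all(h20, n_boot=100, seed=0)
        assert len(ests) == 8
        assert len({e.method for e in ests}) == 8


class TestCoverageSmall:
    def test_fixed_ivw_near_truth_on_simulated_pair(self):
        cfg = SimulationConfig(seed=1)
        exposure, outcome, truth = simulate_pair(cfg)
        est = ivw(harmonize(exposure, outcome))
        assert est.beta == pytest.approx(truth["theta"], abs=4 * est.se)
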