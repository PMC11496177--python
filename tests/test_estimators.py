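"""Estimator correctness against independent oracles and invariants."""

import numpy as np
import pytest
from scipy import stats

from mrmediate.estimators import (ivw, mode_estimate, mr_egger, to_odds_ratio,
                                  wald_ratio, weighted_median, MREstimate)
from mrmediate.instruments import HarmonizedSet, InsufficientInstrumentsError
from .conftest import random_hset


def wls_oracle(bx, by, w, intercept=False):
    """Independent weighted least squares via the lstsq route."""
    X = np.column_stack([np.ones_like(bx), bx]) if intercept else bx[:, None]
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(sw[:, None] * X, sw * by, rcond=None)
    cov_unit = np.linalg.inv((sw[:, None] * X).T @ (sw[:, None] * X))
    return coef, cov_unit


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(dict(beta_exp=0.1, se_exp=0.01, beta_out=0.05, se_out=0.01))
        assert est.beta == pytest.approx(0.5)

    def test_delta_reduces_to_scaled_outcome_se(self):
        est = wald_ratio(dict(beta_exp=0.2, se_exp=0.0, beta_out=0.1, se_out=0.04))
        assert est.se == pytest.approx(0.2)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(dict(beta_exp=0.0, se_exp=0.01, beta_out=0.1, se_out=0.04))

    def test_matches_finite_difference_delta_oracle(self, rng):
        bx, sx, by, sy = 0.23, 0.015, 0.11, 0.04
        est = wald_ratio(dict(beta_exp=bx, se_exp=sx, beta_out=by, se_out=sy))
        eps = 1e-6
        f = lambda x, y: y / x
        gx = (f(bx + eps, by) - f(bx - eps, by)) / (2 * eps)
        gy = (f(bx, by + eps) - f(bx, by - eps)) / (2 * eps)
        se_num = np.sqrt(gx ** 2 * sx ** 2 + gy ** 2 * sy ** 2)
        assert est.se == pytest.approx(se_num, rel=1e-6)


class TestIVW:
    def test_single_snp_equals_wald(self, rng):
        h = random_hset(rng, n_snp=1)
        est = ivw(h)
        wald = wald_ratio(h.rows.iloc[0])
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_homogeneous_ratios_degenerate(self):
        bx = np.array([0.2, 0.3, 0.4])
        h = HarmonizedSet.from_arrays(bx, 0 * bx + 0.01, 0.5 * bx, 0 * bx + 0.05)
        fixed = ivw(h, "fixed")
        random_ = ivw(h, "multiplicative_random")
        assert fixed.beta == pytest.approx(0.5)
        assert fixed.extra["q_stat"] == pytest.approx(0.0, abs=1e-20)
        assert random_.se == pytest.approx(fixed.se)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_wls_oracle(self, seed):
        h = random_hset(np.random.default_rng(seed), n_snp=10)
        bx, sx, by, sy = h.arrays()
        w = 1.0 / sy ** 2
        coef, cov = wls_oracle(bx, by, w)
        fixed = ivw(h, "fixed")
        assert fixed.beta == pytest.approx(coef[0], abs=1e-10)
        assert fixed.se == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-10)
        resid = by - coef[0] * bx
        scale = max(1.0, np.sqrt(np.sum(w * resid ** 2) / (len(bx) - 1)))
        rand = ivw(h, "multiplicative_random")
        assert rand.se == pytest.approx(np.sqrt(cov[0, 0]) * scale, abs=1e-10)

    def test_row_order_and_signflip_invariance(self, rng):
        h = random_hset(rng, n_snp=8)
        base = ivw(h)
        perm = h.rows.sample(frac=1, random_state=3).reset_index(drop=True)
        assert ivw(HarmonizedSet("e", "o", perm)).beta == pytest.approx(base.beta)
        flipped = h.rows.copy()
        flipped.loc[::2, ["beta_exp", "beta_out"]] *= -1
        est = ivw(HarmonizedSet("e", "o", flipped))
        assert est.beta == pytest.approx(base.beta)
        assert est.se == pytest.approx(base.se)


class TestEgger:
    def test_exact_linear_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.02 + 0.4 * bx
        h = HarmonizedSet.from_arrays(bx, 0 * bx + 0.01, by, 0 * bx + 0.05)
        est = mr_egger(h)
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert est.extra["egger_intercept"] == pytest.approx(0.02, abs=1e-12)
        assert est.extra["residual_scale2"] == pytest.approx(0.0, abs=1e-16)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_wls_oracle(self, seed):
        h = random_hset(np.random.default_rng(seed + 50), n_snp=12)
        bx, sx, by, sy = h.arrays()
        flip = np.sign(bx)
        bx, by = bx * flip, by * flip
        w = 1.0 / sy ** 2
        coef, cov = wls_oracle(bx, by, w, intercept=True)
        est = mr_egger(h)
        assert est.beta == pytest.approx(coef[1], abs=1e-10)
        assert est.extra["egger_intercept"] == pytest.approx(coef[0], abs=1e-10)
        resid = by - coef[0] - coef[1] * bx
        scale2 = max(1.0, np.sum(w * resid ** 2) / (len(bx) - 2))
        assert est.se == pytest.approx(np.sqrt(scale2 * cov[1, 1]), abs=1e-10)

    def test_requires_three_snps(self, rng):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(random_hset(rng, n_snp=2))

    def test_statsmodels_crosscheck(self, rng):
        import statsmodels.api as sm
        h = random_hset(rng, n_snp=15)
        bx, sx, by, sy = h.arrays()
        flip = np.sign(bx)
        bx, by = bx * flip, by * flip
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy ** 2).fit()
        est = mr_egger(h)
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.extra["egger_intercept"] == pytest.approx(fit.params[0], abs=1e-10)


class TestWeightedMedian:
    def test_equal_weight_median(self):
        bx = np.ones(3)
        by = np.array([1.0, 2.0, 3.0])
        h = HarmonizedSet.from_arrays(bx, 0 * bx + 1e-9, by, np.ones(3))
        est = weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_breakdown_robustness(self, rng):
        bx = np.ones(10)
        by = np.concatenate([rng.normal(0.5, 0.01, 9), [40.0]])
        h = HarmonizedSet.from_arrays(bx, 0 * bx + 1e-6, by, np.ones(10) * 0.05)
        est = weighted_median(h, n_boot=50, seed=1)
        assert abs(est.beta - 0.5) < 0.1

    def test_matches_interpolation_oracle_and_is_deterministic(self, rng):
        h = random_hset(rng, n_snp=20)
        est1 = weighted_median(h, n_boot=200, seed=99)
        est2 = weighted_median(h, n_boot=200, seed=99)
        assert est1.beta == est2.beta and est1.se == est2.se
        bx, sx, by, sy = h.arrays()
        ratio = by / bx
        var = sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4
        w = (1 / var)
        order = np.argsort(ratio)
        r, wgt = ratio[order], w[order] / w.sum()
        cum = np.cumsum(wgt) - wgt / 2
        below = np.where(cum < 0.5)[0][-1]
        r0, r1 = r[below], r[below + 1]
        c0, c1 = cum[below], cum[below + 1]
        want = r0 + (0.5 - c0) / (c1 - c0) * (r1 - r0)
        assert est1.beta == pytest.approx(want, abs=1e-12)


class TestMode:
    def test_point_mass(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = HarmonizedSet.from_arrays(bx, 0 * bx, 0.7 * bx, np.ones(3) * 0.05)
        est = mode_estimate(h, weighted=False, n_boot=10, seed=1)
        assert est.beta == pytest.approx(0.7)

    def test_plurality_cluster(self, rng):
        ratios = np.concatenate([rng.normal(0.5, 0.02, 7), rng.normal(3.0, 0.02, 3)])
        bx = np.ones(10)
        h = HarmonizedSet.from_arrays(bx, 0 * bx + 1e-6, ratios, np.ones(10) * 0.05)
        est = mode_estimate(h, weighted=False, n_boot=20, seed=2)
        assert abs(est.beta - 0.5) < 0.2

    def test_matches_dense_grid_oracle(self, rng):
        from mrmediate.estimators import _mode_bandwidth
        h = random_hset(rng, n_snp=15)
        est = mode_estimate(h, weighted=True, n_boot=10, seed=3)
        bx, sx, by, sy = h.arrays()
        ratio = by / bx
        var = sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4
        w = 1 / var
        hbw = _mode_bandwidth(ratio, np.sqrt(var), 1.0)
        grid = np.linspace(ratio.min() - 3 * hbw, ratio.max() + 3 * hbw, 200001)
        dens = np.zeros_like(grid)
        for r, wi in zip(ratio, w):  # independent direct-loop density
            dens += wi * np.exp(-0.5 * ((grid - r) / hbw) ** 2)
        assert est.beta == pytest.approx(grid[dens.argmax()], abs=2 * (grid[1] - grid[0]) + 1e-3)


class TestOddsRatioScale:
    def test_null_effect(self):
        est = to_odds_ratio(MREstimate("ivw", 0.0, 0.1, 1.0, 5))
        assert est.or_ == pytest.approx(1.0)
        assert est.ci_low == pytest.approx(np.exp(-1.959963984540054 * 0.1), rel=1e-9)
        assert (est.ci_low, est.ci_high) == (pytest.approx(0.822, abs=5e-4),
                                             pytest.approx(1.217, abs=5e-4))

    def test_display_convention_matches_reported_style(self):
        # OR 1.04 with CI (1.01, 1.06): log-symmetric triple rounding to the display
        beta = np.log(np.sqrt(1.013 * 1.062))
        se = (np.log(1.062) - np.log(1.013)) / (2 * 1.959963984540054)
        est = to_odds_ratio(MREstimate("ivw", beta, se, 0.004, 10))
        assert round(est.or_, 2) == 1.04
        assert round(est.ci_low, 2) == 1.01
        assert round(est.ci_high, 2) == 1.06

    def test_monotone_and_idempotent(self, rng):
        betas = np.sort(rng.normal(0, 1, 20))
        ors = [to_odds_ratio(MREstimate("ivw", b, 0.1, 0.5, 3)).or_ for b in betas]
        assert all(a < b for a, b in zip(ors, ors[1:]))
        e1 = to_odds_ratio(MREstimate("ivw", 0.3, 0.1, 0.5, 3))
        e2 = to_odds_ratio(e1)
        assert (e1.or_, e1.ci_low, e1.ci_high) == (e2.or_, e2.ci_low, e2.ci_high)
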