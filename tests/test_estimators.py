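import numpy as np
import pytest

from mrpipe import (
    HarmonizedSet,
    ivw,
    max_likelihood,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from mrpipe.estimators import EstimationError, _profile_neg2ll

from conftest import random_harmonized


def H_from(beta_exp, se_exp, beta_out, se_out):
    return HarmonizedSet.from_arrays(beta_exp, se_exp, beta_out, se_out)


def wls_oracle(x, y, w, intercept):
    """Weighted normal equations, independent of statsmodels.

    Returns (coef vector, unit covariance (XᵀWX)⁻¹, weighted RSS)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if intercept:
        x = np.column_stack([np.ones(len(x)), x])
    xtw = x.T * w
    cov = np.linalg.inv(xtw @ x)
    coef = cov @ (xtw @ y)
    rss = float(np.sum(w * (y - x @ coef) ** 2))
    return coef, cov, rss


class TestWaldRatio:
    def test_direct_arithmetic(self):
        beta, se = wald_ratio(0.1, 0.02, 0.05, 0.02)
        assert beta == pytest.approx(0.5)
        assert se == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        beta, se = wald_ratio(0.25, 0.01, 0.0, 0.03)
        assert beta == 0.0
        assert se == pytest.approx(0.03 / 0.25)

    def test_second_order_matches_symbolic_delta_method(self):
        import sympy

        g, sg, G, sG = sympy.symbols("g sg G sG", positive=True)
        # var(G/g) to first order in both arguments
        expr = sympy.sqrt(sG**2 / g**2 + G**2 * sg**2 / g**4)
        expected = float(expr.subs({g: 0.1, sg: 0.02, G: 0.05, sG: 0.02}))
        _, se = wald_ratio(0.1, 0.02, 0.05, 0.02, second_order=True)
        assert se == pytest.approx(expected, rel=1e-12)

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(EstimationError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIvw:
    def test_single_snp_reduces_to_wald_ratio(self):
        H = H_from([0.2], [0.01], [0.04], [0.01])
        est = ivw(H)
        assert est.beta == pytest.approx(0.2)
        assert est.n_snp == 1

    def test_equal_weight_mean(self):
        H = H_from([1.0, 1.0], [0.1, 0.1], [0.1, 0.3], [1.0, 1.0])
        assert ivw(H, mode="fixed").beta == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_weighted_regression_through_origin(self, seed):
        rng = np.random.default_rng(seed)
        H = random_harmonized(rng, 50)
        w = 1.0 / H.se_out**2
        coef, cov, _ = wls_oracle(H.beta_exp, H.beta_out, w, intercept=False)
        est = ivw(H, mode="fixed")
        assert est.beta == pytest.approx(coef[0], abs=1e-10)
        assert est.se == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-10)

    def test_random_se_at_least_fixed_se(self, rng):
        H = random_harmonized(rng, 20)
        assert ivw(H, mode="random").se >= ivw(H, mode="fixed").se

    def test_outcome_rescaling_scales_estimate(self, rng):
        H = random_harmonized(rng, 20)
        c = 3.7
        H2 = HarmonizedSet.from_arrays(
            H.beta_exp, H.se_exp, c * H.beta_out, c * H.se_out
        )
        for mode in ("fixed", "random"):
            a, b = ivw(H, mode=mode), ivw(H2, mode=mode)
            assert b.beta == pytest.approx(c * a.beta, rel=1e-12)
            assert b.se == pytest.approx(c * a.se, rel=1e-12)

    def test_order_invariance(self, rng):
        H = random_harmonized(rng, 20)
        perm = rng.permutation(20)
        assert ivw(H.subset(perm)).beta == pytest.approx(ivw(H).beta, rel=1e-12)

    def test_empty_set_is_error(self):
        with pytest.raises(EstimationError):
            ivw(H_from([], [], [], []))


class TestMrEgger:
    def test_exact_line_recovered(self):
        gx = np.linspace(0.05, 0.5, 10)
        H = H_from(gx, np.full(10, 0.01), 0.05 + 0.3 * gx, np.full(10, 0.01))
        slope, intercept = mr_egger(H)
        assert slope.beta == pytest.approx(0.3, abs=1e-12)
        assert intercept.intercept == pytest.approx(0.05, abs=1e-12)

    def test_zero_intercept_construction(self, rng):
        gx = rng.uniform(0.05, 0.3, 40)
        gy = 0.2 * gx + rng.normal(0, 0.005, 40)
        H = H_from(gx, np.full(40, 0.01), gy, np.full(40, 0.005))
        _, intercept = mr_egger(H)
        assert abs(intercept.intercept) < 4 * intercept.se

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_weighted_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        H = random_harmonized(rng, 30)
        sign = np.where(H.beta_exp < 0, -1.0, 1.0)
        w = 1.0 / H.se_out**2
        coef, cov, rss = wls_oracle(
            H.beta_exp * sign, H.beta_out * sign, w, intercept=True
        )
        sigma2 = rss / (30 - 2)
        slope, intercept = mr_egger(H)
        assert slope.beta == pytest.approx(coef[1], abs=1e-10)
        assert intercept.intercept == pytest.approx(coef[0], abs=1e-10)
        assert slope.se == pytest.approx(np.sqrt(cov[1, 1] * sigma2), abs=1e-10)
        assert intercept.se == pytest.approx(np.sqrt(cov[0, 0] * sigma2), abs=1e-10)

    def test_floored_variant_never_deflates(self, rng):
        gx = rng.uniform(0.05, 0.3, 10)
        # tiny residuals relative to stated se -> underdispersion
        H = H_from(gx, np.full(10, 0.01), 0.1 * gx + rng.normal(0, 1e-4, 10), np.full(10, 0.05))
        slope_m, _ = mr_egger(H, overdispersion="multiplicative")
        slope_f, _ = mr_egger(H, overdispersion="floored")
        assert slope_f.se > slope_m.se

    def test_too_few_instruments(self):
        with pytest.raises(EstimationError):
            mr_egger(H_from([0.1, 0.2], [0.01, 0.01], [0.0, 0.0], [0.01, 0.01]))

    def test_mirrored_exposure_encoding_invariant(self, rng):
        H = random_harmonized(rng, 25)
        H2 = HarmonizedSet.from_arrays(-H.beta_exp, H.se_exp, -H.beta_out, H.se_out)
        a, _ = mr_egger(H)
        b, _ = mr_egger(H2)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        H = H_from([1.0, 1.0, 1.0], [0.1] * 3, [0.1, 0.2, 0.9], [1.0] * 3)
        assert weighted_median(H, n_boot=10, seed=0).beta == pytest.approx(0.2)

    def test_majority_weight_snp_dominates(self):
        # first SNP carries ~90% of total weight (se_out tiny)
        H = H_from(
            [1.0, 1.0, 1.0], [0.01] * 3, [0.4, 0.9, 0.1], [0.1, 0.9, 0.9]
        )
        est = weighted_median(H, n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.4, abs=0.02)

    def test_estimate_within_ratio_range(self, rng):
        H = random_harmonized(rng, 15)
        ratios = H.beta_out / H.beta_exp
        est = weighted_median(H, n_boot=10, seed=1)
        assert ratios.min() <= est.beta <= ratios.max()

    def test_bootstrap_se_reproducible_by_seed(self, rng):
        H = random_harmonized(rng, 15)
        a = weighted_median(H, n_boot=200, seed=11)
        b = weighted_median(H, n_boot=200, seed=11)
        c = weighted_median(H, n_boot=200, seed=12)
        assert a.se == b.se
        assert a.se != c.se


class TestMaxLikelihood:
    def test_noiseless_proportional_data(self):
        gx = np.linspace(0.05, 0.4, 8)
        H = H_from(gx, np.full(8, 0.01), 0.3 * gx, np.full(8, 0.01))
        assert max_likelihood(H).beta == pytest.approx(0.3, abs=1e-8)

    def test_limit_of_precise_exposure_equals_ivw(self, rng):
        H = random_harmonized(rng, 25)
        H_precise = HarmonizedSet.from_arrays(
            H.beta_exp, np.full(25, 1e-10), H.beta_out, H.se_out
        )
        ml = max_likelihood(H_precise)
        fixed = ivw(H_precise, mode="fixed")
        assert ml.beta == pytest.approx(fixed.beta, abs=1e-6)
        assert ml.se == pytest.approx(fixed.se, rel=1e-4)

    def test_optimum_beats_grid_search(self, rng):
        H = random_harmonized(rng, 10)
        est = max_likelihood(H)
        grid = np.linspace(est.beta - 2, est.beta + 2, 10_000)
        grid_vals = [_profile_neg2ll(float(b), H) for b in grid]
        assert _profile_neg2ll(est.beta, H) <= min(grid_vals) + 1e-9
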