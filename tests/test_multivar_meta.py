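import numpy as np
import pytest

from mrpipe import HarmonizedSet, MvmrInput, ivw, meta_pool, mvmr_ivw, or_ci_to_beta_se
from mrpipe.estimators import EstimationError, Z95
from mrpipe.multivar_meta import CollinearityError, meta_table

from test_estimators import wls_oracle


def mvmr_input(beta_exp, se_exp, beta_out, se_out, names=None):
    beta_exp = np.atleast_2d(beta_exp)
    j, k = beta_exp.shape
    return MvmrInput(
        snp_ids=tuple(f"rs{i}" for i in range(j)),
        exposure_names=tuple(names or [f"x{c}" for c in range(k)]),
        beta_exp=beta_exp,
        se_exp=np.atleast_2d(se_exp),
        beta_out=beta_out,
        se_out=se_out,
    )


class TestMvmr:
    def test_k1_reduces_to_univariable_ivw(self, rng):
        j = 20
        gx = rng.uniform(0.05, 0.3, j)
        gy = 0.1 * gx + rng.normal(0, 0.01, j)
        se_out = rng.uniform(0.005, 0.02, j)
        data = mvmr_input(gx[:, None], np.full((j, 1), 0.01), gy, se_out)
        est = mvmr_ivw(data)[0]
        H = HarmonizedSet.from_arrays(gx, np.full(j, 0.01), gy, se_out)
        uni = ivw(H, mode="random")
        assert est.beta == pytest.approx(uni.beta, rel=1e-12)
        assert est.se == pytest.approx(uni.se, rel=1e-12)

    def test_noiseless_two_exposure_recovery(self, rng):
        j = 25
        x = rng.normal(0, 0.1, (j, 2))
        y = 0.08 * x[:, 0] + 0.2 * x[:, 1]
        data = mvmr_input(x, np.full((j, 2), 0.01), y, np.full(j, 0.01))
        betas = [e.beta for e in mvmr_ivw(data)]
        np.testing.assert_allclose(betas, [0.08, 0.2], atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_weighted_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        j, k = 40, 4
        x = rng.normal(0, 0.1, (j, k))
        y = x @ rng.normal(0, 0.2, k) + rng.normal(0, 0.02, j)
        se_out = rng.uniform(0.005, 0.03, j)
        w = 1.0 / se_out**2
        coef, cov, rss = wls_oracle(x, y, w, intercept=False)
        infl = max(rss / (j - k), 1.0)
        ests = mvmr_ivw(mvmr_input(x, np.full((j, k), 0.01), y, se_out))
        for idx, est in enumerate(ests):
            assert est.beta == pytest.approx(coef[idx], abs=1e-10)
            assert est.se == pytest.approx(np.sqrt(cov[idx, idx] * infl), abs=1e-10)

    def test_orthogonal_noiseless_exposures_match_univariable(self, rng):
        j = 30
        x = np.zeros((j, 2))
        x[: j // 2, 0] = rng.uniform(0.1, 0.3, j // 2)
        x[j // 2 :, 1] = rng.uniform(0.1, 0.3, j - j // 2)
        y = 0.1 * x[:, 0] + 0.3 * x[:, 1]
        ests = mvmr_ivw(mvmr_input(x, np.full((j, 2), 0.01), y, np.full(j, 0.01)))
        np.testing.assert_allclose([e.beta for e in ests], [0.1, 0.3], atol=1e-12)

    def test_collinear_exposures_raise_naming_pair(self, rng):
        j = 10
        x0 = rng.uniform(0.1, 0.3, j)
        x = np.column_stack([x0, 2.0 * x0])
        with pytest.raises(CollinearityError, match="x0.*x1"):
            mvmr_ivw(mvmr_input(x, np.full((j, 2), 0.01), x0, np.full(j, 0.01)))

    def test_too_few_snps(self):
        x = np.array([[0.1, 0.2], [0.2, 0.1]])
        with pytest.raises(EstimationError):
            mvmr_ivw(mvmr_input(x, np.full((2, 2), 0.01), np.array([0.1, 0.2]), np.full(2, 0.01)))


class TestMetaPool:
    def test_identical_studies_pool_to_same(self):
        res = meta_pool([(0.07, 0.03)] * 3, model="auto")
        assert res.pooled_beta == pytest.approx(0.07)
        assert res.q == pytest.approx(0.0, abs=1e-20)
        assert res.i2 == 0.0
        assert res.tau2 == 0.0
        assert res.model == "fixed"

    def test_hand_computed_dersimonian_laird(self):
        res_fixed = meta_pool([(0.0, 1.0), (2.0, 1.0)], model="fixed")
        assert res_fixed.pooled_beta == pytest.approx(1.0)
        assert res_fixed.pooled_se == pytest.approx(1 / np.sqrt(2))
        assert res_fixed.q == pytest.approx(2.0)
        res_rand = meta_pool([(0.0, 1.0), (2.0, 1.0)], model="random")
        assert res_rand.tau2 == pytest.approx(1.0)  # (2-1)/(2-2²/2... ) = 1/(2-1)
        assert res_rand.pooled_se == pytest.approx(1.0)  # w = 1/(1+1) each

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_dl_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = 5
        beta = rng.normal(0.1, 0.2, k)
        se = rng.uniform(0.05, 0.3, k)
        w = 1.0 / se**2
        mu_f = np.sum(w * beta) / np.sum(w)
        q = np.sum(w * (beta - mu_f) ** 2)
        tau2 = max(0.0, (q - (k - 1)) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
        wr = 1.0 / (se**2 + tau2)
        res = meta_pool(list(zip(beta, se)), model="random")
        assert res.pooled_beta == pytest.approx(np.sum(wr * beta) / np.sum(wr), abs=1e-10)
        assert res.pooled_se == pytest.approx(np.sqrt(1 / np.sum(wr)), abs=1e-10)
        assert res.tau2 == pytest.approx(tau2, abs=1e-10)

    def test_permutation_invariance_and_fixed_variance_bound(self, rng):
        pairs = [(float(b), float(s)) for b, s in zip(rng.normal(0, 0.1, 6), rng.uniform(0.02, 0.2, 6))]
        a = meta_pool(pairs, model="fixed")
        b = meta_pool(pairs[::-1], model="fixed")
        assert a.pooled_beta == pytest.approx(b.pooled_beta, rel=1e-12)
        assert a.pooled_se**2 <= min(s**2 for _, s in pairs)
        assert min(x for x, _ in pairs) <= a.pooled_beta <= max(x for x, _ in pairs)

    def test_i2_zero_when_q_below_df(self):
        res = meta_pool([(0.1, 0.5), (0.12, 0.5), (0.11, 0.5)], model="fixed")
        assert res.q <= 2
        assert res.i2 == 0.0

    def test_insufficient_studies(self):
        with pytest.raises(EstimationError):
            meta_pool([(0.1, 0.05)])


class TestOrConversion:
    def test_round_trip_with_symmetric_ci(self):
        beta, se = 0.077, 0.028
        or_, lo, hi = np.exp(beta), np.exp(beta - Z95 * se), np.exp(beta + Z95 * se)
        b2, s2 = or_ci_to_beta_se(or_, lo, hi)
        assert b2 == pytest.approx(beta, rel=1e-12)
        assert s2 == pytest.approx(se, rel=1e-12)

    def test_meta_table_has_pooled_row(self):
        pairs = [(0.05, 0.02), (0.09, 0.03)]
        res = meta_pool(pairs, model="fixed")
        table = meta_table(res, ["a", "b"], pairs)
        assert len(table) == 3
        assert table.study.iloc[-1].startswith("pooled")
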