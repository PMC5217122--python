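import numpy as np
import pytest
from scipy import stats

import kernelgxe as kg
from kernelgxe.bayes_core import (
    McmcConfig,
    PhenotypeTable,
    PriorSpec,
    default_multi_prior,
    default_single_prior,
    effective_sample_size,
    fit_multi,
    fit_single,
    sample_inv_wishart,
    sample_scaled_inv_chi2,
    successive_conditional_check,
)
from kernelgxe.synthetic_data import corr_to_cov

from conftest import make_identity_kernel


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class TestPhenotypeTable:
    def test_nan_marks_unobserved(self):
        vals = np.array([[1.0, np.nan], [2.0, 3.0]])
        t = PhenotypeTable(["a", "b"], ["E1", "E2"], vals)
        assert t.observed.tolist() == [[True, False], [True, True]]

    def test_standardize_full(self, toy_table):
        s = toy_table.standardize()
        for j in range(s.m):
            col = s.values[s.observed[:, j], j]
            assert abs(col.mean()) < 1e-8
            assert abs(col.std(ddof=1) - 1.0) < 1e-8
        assert s.standardization is not None

    def test_standardize_on_train_ignores_test_values(self, toy_table, rng):
        mask = rng.random(toy_table.values.shape) < 0.7
        mask[:, 0] = True  # keep things well-populated
        a = toy_table.standardize(on="train", train_mask=mask)
        poked = PhenotypeTable(toy_table.line_ids, toy_table.env_ids,
                               np.where(mask, toy_table.values, 99.0))
        b = poked.standardize(on="train", train_mask=mask)
        np.testing.assert_array_equal(a.values[mask], b.values[mask])

    def test_duplicate_lines_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            PhenotypeTable(["a", "a"], ["E1"], np.zeros((2, 1)))


class TestMcmcConfig:
    def test_default_schedule_retains_5000(self):
        cfg = McmcConfig(iterations=30_000, burn_in=5_000, thin=5, seed=0)
        assert cfg.retained == 5_000

    def test_retained_formula(self):
        cfg = McmcConfig(iterations=103, burn_in=3, thin=7, seed=0)
        assert cfg.retained == (103 - 3) // 7

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(iterations=100, burn_in=100, thin=1)
        with pytest.raises(ValueError):
            McmcConfig(iterations=100, burn_in=10, thin=0)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

class TestDefaultPriors:
    def test_single_prior_standardized_y(self, linear_K, rng):
        y = rng.standard_normal(40)
        y = (y - y.mean()) / y.std(ddof=1)
        prior = default_single_prior(y, linear_K)
        assert prior.df_eps == 5.0 and prior.df_u == 5.0
        assert abs(prior.S_eps - 3.5) < 1e-8
        # mean diag of the linear kernel is exactly 1
        assert abs(prior.S_u - 3.5) < 1e-8

    def test_single_prior_plugin_arithmetic(self):
        K = make_identity_kernel(4)
        K.values *= 2.0  # mean diag 2
        K = kg.KernelMatrix(K.line_ids, K.values, kind="custom")
        y = np.array([0.0, 2.0, 4.0, 2.0])  # var (ddof=1) = 8/3
        v = np.var(y, ddof=1)
        prior = default_single_prior(y, K)
        assert abs(prior.S_eps - 0.5 * v * 7) < 1e-12
        assert abs(prior.S_u - 0.5 * v * 7 / 2.0) < 1e-12

    def test_prior_mode_identity(self, linear_K, rng):
        y = rng.standard_normal(40) * 3.0
        prior = default_single_prior(y, linear_K)
        v = np.var(y, ddof=1)
        assert abs(prior.S_eps / (prior.df_eps + 2) - 0.5 * v) < 1e-10

    def test_zero_variance_rejected(self, linear_K):
        with pytest.raises(ValueError, match="variance"):
            default_single_prior(np.ones(40), linear_K)

    def test_multi_prior_shapes(self):
        prior = default_multi_prior(4)
        np.testing.assert_array_equal(prior.S0, np.eye(4))
        assert prior.df0 == 4.0
        df, S = prior.eps_params(4)
        assert np.all(df == 1.0) and np.all(S == 1.0)
        np.linalg.cholesky(prior.S0)  # PD

    def test_multi_prior_m2(self):
        assert default_multi_prior(2).df0 == 2.0

    def test_multi_prior_m1_rejected(self):
        with pytest.raises(ValueError, match="model 1"):
            default_multi_prior(1)


# ---------------------------------------------------------------------------
# elementary samplers (Monte-Carlo vs closed forms)
# ---------------------------------------------------------------------------

class TestScaledInvChi2:
    def test_mean_matches_closed_form(self):
        rng = np.random.default_rng(7)
        draws = np.array([sample_scaled_inv_chi2(10.0, 8.0, rng)
                          for _ in range(100_000)])
        # mean S/(df-2) = 1, var of draws 2S^2/((df-2)^2 (df-4))
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 1.0) < 3 * se

    def test_mode_matches_closed_form(self):
        rng = np.random.default_rng(8)
        draws = np.array([sample_scaled_inv_chi2(10.0, 8.0, rng)
                          for _ in range(50_000)])
        kde = stats.gaussian_kde(draws[draws < 4.0])
        grid = np.linspace(0.2, 2.0, 400)
        mode = grid[np.argmax(kde(grid))]
        assert abs(mode - 8.0 / 12.0) < 0.07

    def test_strictly_positive(self):
        rng = np.random.default_rng(9)
        draws = [sample_scaled_inv_chi2(1.0, 1.0, rng) for _ in range(1000)]
        assert min(draws) > 0.0

    def test_invalid_params(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_scaled_inv_chi2(0.0, 1.0, rng)


class TestInvWishart:
    def test_mean_matches_closed_form(self):
        rng = np.random.default_rng(10)
        draws = stats.invwishart.rvs(df=7, scale=np.eye(2), size=100_000,
                                     random_state=np.random.default_rng(10))
        # use our wrapper on a subsample to confirm identical convention
        ours = np.array([sample_inv_wishart(np.eye(2), 7.0, rng)
                         for _ in range(20_000)])
        target = np.eye(2) / 4.0  # S0/(df0-m-1)
        for idx in [(0, 0), (0, 1), (1, 1)]:
            x = ours[:, idx[0], idx[1]]
            se = x.std(ddof=1) / np.sqrt(x.size)
            assert abs(x.mean() - target[idx]) < 3 * se

    def test_m1_reduces_to_scaled_inv_chi2(self):
        rng = np.random.default_rng(11)
        a = np.array([sample_inv_wishart(np.array([[2.0]]), 6.0, rng)[0, 0]
                      for _ in range(10_000)])
        b = 2.0 / np.random.default_rng(12).chisquare(6.0, 10_000)
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_draws_are_spd(self):
        rng = np.random.default_rng(13)
        S0 = np.array([[2.0, 0.5], [0.5, 1.0]])
        for _ in range(200):
            W = sample_inv_wishart(S0, 3.0, rng)
            np.testing.assert_allclose(W, W.T)
            assert np.linalg.eigvalsh(W).min() > 0

    def test_non_pd_scale_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_inv_wishart(np.array([[1.0, 2.0], [2.0, 1.0]]), 5.0, rng)


# ---------------------------------------------------------------------------
# fit_single
# ---------------------------------------------------------------------------

def _single_instance(n=50, seed=2, mu=0.3):
    rng = np.random.default_rng(seed)
    raw = kg.simulate_markers(n, 200, (0.1, 0.5), seed=seed)
    X, _ = kg.standardize_markers(raw, 0.0, seed=seed)
    K = kg.linear_kernel(X)
    L = np.linalg.cholesky(K.values + 1e-8 * np.eye(n))
    u = L @ rng.standard_normal(n)
    y = mu + u + rng.standard_normal(n)
    table = PhenotypeTable(K.line_ids, ["E1"], y[:, None])
    return table, K, y


class TestFitSingle:
    def test_conjugate_oracle(self):
        table, K, y = _single_instance()
        prior = default_single_prior(y, K)
        mcmc = McmcConfig(iterations=30_000, burn_in=2_000, thin=1, seed=5)
        chain = fit_single(table, K, prior, mcmc,
                           fix_sigma_u2=1.0, fix_sigma_eps2=1.0)
        mu_bar = float(chain.mu.mean())
        oracle = K.values @ np.linalg.solve(K.values + np.eye(50), y - mu_bar)
        assert np.max(np.abs(chain.u_mean[:, 0] - oracle)) < 0.02

    def test_constant_y_gives_zero_u(self):
        n = 30
        K = make_identity_kernel(n)
        table = PhenotypeTable(K.line_ids, ["E1"], np.full((n, 1), 2.5))
        prior = PriorSpec(df_eps=5, S_eps=0.5, df_u=5, S_u=0.5)
        mcmc = McmcConfig(iterations=4_000, burn_in=1_000, thin=1, seed=3)
        chain = fit_single(table, K, prior, mcmc)
        assert abs(chain.mu.mean() - 2.5) < 0.05
        assert np.max(np.abs(chain.u_mean)) < 0.05

    def test_default_schedule_retained_count(self):
        table, K, y = _single_instance(n=12, seed=4)
        prior = default_single_prior(y, K)
        mcmc = McmcConfig(iterations=30_000, burn_in=5_000, thin=5, seed=1)
        chain = fit_single(table, K, prior, mcmc)
        assert chain.retained == 5_000
        assert chain.mu.shape == (5_000, 1)

    def test_deterministic_given_seed(self):
        table, K, y = _single_instance(n=15, seed=6)
        prior = default_single_prior(y, K)
        mcmc = McmcConfig(iterations=500, burn_in=100, thin=2, seed=42)
        a = fit_single(table, K, prior, mcmc)
        b = fit_single(table, K, prior, mcmc)
        np.testing.assert_array_equal(a.sigma_u2, b.sigma_u2)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.u_mean, b.u_mean)

    def test_observed_cells_never_modified(self):
        table, K, y = _single_instance(n=20, seed=7)
        table.observed[::3, 0] = False
        before = table.values.copy()
        prior = default_single_prior(y[table.observed[:, 0]], K)
        fit_single(table, K, prior, McmcConfig(400, 100, 1, seed=0))
        np.testing.assert_array_equal(table.values, before)

    def test_imputed_mean_tracks_prediction(self):
        table, K, y = _single_instance(n=40, seed=8)
        table.observed[:10, 0] = False
        prior = default_single_prior(y[10:], K)
        chain = fit_single(table, K, prior, McmcConfig(4_000, 1_000, 1, seed=0))
        assert chain.imputed_mean is not None
        # imputed mean approx equals prediction at missing cells
        miss = ~table.observed
        assert np.max(np.abs(chain.imputed_mean[miss] - chain.predicted[miss])) < 0.15

    def test_too_few_observations_rejected(self):
        K = make_identity_kernel(5)
        table = PhenotypeTable(K.line_ids, ["E1"], np.ones((5, 1)))
        with pytest.raises(ValueError, match="10 observed"):
            fit_single(table, K, PriorSpec(), McmcConfig(100, 10, 1))

    def test_nonfinite_y_rejected(self):
        K = make_identity_kernel(12)
        vals = np.ones((12, 1))
        vals[0, 0] = np.inf
        table = PhenotypeTable(K.line_ids, ["E1"], vals)
        with pytest.raises(ValueError, match="non-finite"):
            fit_single(table, K, PriorSpec(), McmcConfig(100, 10, 1))

    def test_multienv_table_rejected(self, toy_table):
        K = make_identity_kernel(30)
        with pytest.raises(ValueError, match="single-environment"):
            fit_single(toy_table, K, PriorSpec(), McmcConfig(100, 10, 1))


# ---------------------------------------------------------------------------
# fit_multi
# ---------------------------------------------------------------------------

class TestFitMulti:
    def test_decoupled_oracle_identity_covariances(self):
        # UE = Sigma = I, K = I: environments decouple; posterior mean of u
        # is the per-environment ridge (y - mu)/2.
        n, m = 40, 2
        rng = np.random.default_rng(5)
        K = make_identity_kernel(n)
        Y = rng.standard_normal((n, m)) * 1.2 + np.array([0.2, -0.4])
        table = PhenotypeTable(K.line_ids, ["E1", "E2"], Y)
        chain = fit_multi(table, K, include_f=False,
                          prior=default_multi_prior(m),
                          mcmc=McmcConfig(30_000, 2_000, 1, seed=3),
                          fix_UE=np.eye(m), fix_Sigma=np.ones(m))
        mu_bar = chain.mu.mean(axis=0)
        for j in range(m):
            oracle = (Y[:, j] - mu_bar[j]) / 2.0
            assert np.max(np.abs(chain.u_mean[:, j] - oracle)) < 0.02

    def test_ue_correlation_recovery_small(self):
        # quick sanity recovery; the full-scale version is an acceptance test
        n, m = 150, 2
        UE = corr_to_cov(np.array([[1.0, 0.7], [0.7, 1.0]]), [0.7, 0.7])
        scen = kg.SimulationScenario(n=n, m=m, p=400, UE_true=UE,
                                     Sigma_true=[0.3, 0.3], seed=21)
        raw = kg.simulate_markers(n, 400, (0.05, 0.5), seed=21)
        X, _ = kg.standardize_markers(raw, 0.0, seed=21)
        K = kg.linear_kernel(X)
        table, _ = kg.simulate_multienv_phenotypes(scen, K)
        chain = fit_multi(table.standardize(), K, include_f=False,
                          prior=default_multi_prior(m),
                          mcmc=McmcConfig(3_000, 600, 3, seed=2))
        UEm = chain.UE.mean(axis=0)
        corr = UEm[0, 1] / np.sqrt(UEm[0, 0] * UEm[1, 1])
        assert abs(corr - 0.7) < 0.25

    def test_every_retained_cov_draw_is_spd(self):
        n, m = 30, 2
        rng = np.random.default_rng(9)
        K = make_identity_kernel(n)
        Y = rng.standard_normal((n, m))
        table = PhenotypeTable(K.line_ids, ["E1", "E2"], Y)
        chain = fit_multi(table, K, include_f=True,
                          prior=default_multi_prior(m),
                          mcmc=McmcConfig(600, 100, 1, seed=4))
        for arr in (chain.UE, chain.FE):
            for W in arr:
                np.testing.assert_allclose(W, W.T, atol=1e-12)
                assert np.linalg.eigvalsh(W).min() > 0
        assert np.all(chain.Sigma > 0)

    def test_deterministic_given_seed(self, toy_table):
        K = make_identity_kernel(30)
        mc = McmcConfig(300, 50, 1, seed=8)
        a = fit_multi(toy_table, K, False, default_multi_prior(3), mc)
        b = fit_multi(toy_table, K, False, default_multi_prior(3), mc)
        np.testing.assert_array_equal(a.UE, b.UE)
        np.testing.assert_array_equal(a.predicted, b.predicted)

    def test_missing_cells_augmented_not_modified(self, toy_table):
        K = make_identity_kernel(30)
        toy_table.observed[0, 1:] = False
        before = toy_table.values.copy()
        chain = fit_multi(toy_table, K, False, default_multi_prior(3),
                          McmcConfig(300, 50, 1, seed=8))
        np.testing.assert_array_equal(toy_table.values, before)
        assert chain.imputed_mean is not None
        assert np.isnan(chain.imputed_mean[toy_table.observed]).all()
        assert np.isfinite(chain.imputed_mean[~toy_table.observed]).all()

    def test_empty_environment_rejected(self, toy_table):
        K = make_identity_kernel(30)
        toy_table.observed[:, 2] = False
        with pytest.raises(ValueError, match="no observed cells"):
            fit_multi(toy_table, K, False, default_multi_prior(3),
                      McmcConfig(100, 10, 1))

    def test_uncovered_line_rejected(self, toy_table):
        K = make_identity_kernel(30)
        toy_table.observed[5, :] = False
        with pytest.raises(ValueError, match="L5"):
            fit_multi(toy_table, K, False, default_multi_prior(3),
                      McmcConfig(100, 10, 1))

    def test_single_env_rejected(self):
        K = make_identity_kernel(12)
        table = PhenotypeTable(K.line_ids, ["E1"], np.ones((12, 1)))
        with pytest.raises(ValueError, match="m >= 2"):
            fit_multi(table, K, False, default_multi_prior(2),
                      McmcConfig(100, 10, 1))

    def test_env_covariance_accessor(self, toy_table):
        K = make_identity_kernel(30)
        chain = fit_multi(toy_table, K, True, default_multi_prior(3),
                          McmcConfig(300, 100, 2, seed=2))
        ec = chain.env_covariance()
        assert ec.m == 3
        np.testing.assert_allclose(ec.UE, chain.UE.mean(axis=0), atol=1e-12)
        assert np.all(ec.Sigma > 0)
        assert ec.FE is not None

    def test_store_effects_shapes(self, toy_table):
        K = make_identity_kernel(30)
        mc = McmcConfig(200, 100, 2, seed=1, store_effects=True)
        chain = fit_multi(toy_table, K, True, default_multi_prior(3), mc)
        assert chain.u_draws.shape == (mc.retained, 30, 3)
        assert chain.f_draws.shape == (mc.retained, 30, 3)


# ---------------------------------------------------------------------------
# successive-conditional harness
# ---------------------------------------------------------------------------

CHECK_PRIOR_1 = PriorSpec(df_eps=8.0, S_eps=6.0, df_u=8.0, S_u=6.0)


def check_prior_multi(m):
    return PriorSpec(df_eps=8.0, S_eps=6.0, df_u=8.0, S_u=6.0,
                     S0=np.eye(m), df0=float(m + 6))


class TestSuccessiveConditional:
    def test_single_model_passes(self):
        rep = successive_conditional_check("single", {"n": 10}, CHECK_PRIOR_1,
                                           cycles=12_000, seed=1)
        assert rep.passed, str(rep)
        # sigma_eps2 prior mean S/(df-2) = 1.0
        row = next(r for r in rep.rows if r["param"] == "sigma_eps2")
        assert abs(row["chain_mean"] - 6.0 / 6.0) < 4 * row["se"] + 0.05

    def test_corrupted_conditional_fails(self):
        rep = successive_conditional_check("single", {"n": 10}, CHECK_PRIOR_1,
                                           cycles=6_000, seed=4, _corrupt=1.25)
        assert not rep.passed

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            successive_conditional_check("modelx", {"n": 5}, CHECK_PRIOR_1)


def test_effective_sample_size_iid(rng):
    x = rng.standard_normal(2_000)
    ess = effective_sample_size(x)
    assert 1_000 < ess <= 2_000


def test_effective_sample_size_correlated(rng):
    x = np.cumsum(rng.standard_normal(2_000))  # random walk, tiny ESS
    assert effective_sample_size(x) < 300
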