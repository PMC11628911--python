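import numpy as np
import pytest

from graphblup import (
    BayesKernelBLUP,
    REMLKernelBLUP,
    fit_bayes,
    fit_reml_oracle,
    pearson,
    vanraden_g,
)


def ridge_blup(K, y, s2g, s2e, mu):
    """Closed-form BLUP g = s2g K (s2g K + s2e I)^-1 (y - mu)."""
    n = y.size
    return s2g * K @ np.linalg.solve(s2g * K + s2e * np.eye(n), y - mu)


@pytest.fixture(scope="module")
def identity_problem():
    rng = np.random.default_rng(8)
    n = 50
    y = 3.0 + rng.normal(scale=1.0, size=n) + rng.normal(scale=1.0, size=n)
    return np.eye(n), y


class TestBayesSampler:
    def test_negligible_kernel_collapses_to_intercept(self, sim_dataset):
        m, ph, y, _ = sim_dataset
        G = vanraden_g(m).K * 1e-12
        y_masked = y.copy()
        y_masked[:30] = np.nan
        fm = fit_bayes(y_masked, [G], n_iter=2000, burn_in=500, seed=0)
        train_mean = np.nanmean(y_masked)
        np.testing.assert_allclose(fm.predict(np.arange(30)), train_mean, atol=0.15)

    def test_identity_kernel_matches_ridge_within_mc_error(self, identity_problem):
        K, y = identity_problem
        est = BayesKernelBLUP(n_iter=8000, burn_in=2000, thin=2, random_state=1, keep_effects=True)
        est.fit(K, y)
        s2g = est.var_components_["kernel_0"]
        s2e = est.var_components_["residual"]
        expected = ridge_blup(K, y, s2g, s2e, est.mu_)
        draws = est.chains_["effects"][:, 0, :]
        mc_se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0] / 4)  # autocorr margin
        assert np.all(np.abs(est.blups_[0] - expected) <= 3 * mc_se + 0.02)

    def test_duplicate_kernels_sum_to_single_kernel_blup(self, sim_dataset):
        m, ph, y, _ = sim_dataset
        G = vanraden_g(m).K
        one = fit_bayes(y, [G], n_iter=6000, burn_in=1500, seed=3)
        two = fit_bayes(y, [G, G], n_iter=6000, burn_in=1500, seed=4)
        combined = two.blups_[0] + two.blups_[1]
        # the summed process equals a single kernel with summed variance,
        # up to Monte-Carlo error and the split prior elicitation
        assert pearson(one.blups_[0], combined) > 0.99
        np.testing.assert_allclose(combined, one.blups_[0], atol=0.4)

    def test_yhat_is_intercept_plus_blups(self, identity_problem):
        K, y = identity_problem
        est = BayesKernelBLUP(n_iter=2000, burn_in=500, random_state=5).fit(K, y)
        np.testing.assert_allclose(est.yhat_, est.mu_ + est.blups_[0], atol=1e-10)

    def test_variance_estimates_positive_and_chain_stationary(self, identity_problem):
        K, y = identity_problem
        est = BayesKernelBLUP(n_iter=6000, burn_in=2000, random_state=6).fit(K, y)
        assert all(v > 0 for v in est.var_components_.values())
        chain = est.chains_["residual"]
        half = chain.size // 2
        a, b = chain[:half], chain[half:]
        se = np.sqrt(a.var(ddof=1) / half + b.var(ddof=1) / half)
        # crude split-half stationarity check, generous for autocorrelation
        assert abs(a.mean() - b.mean()) < 3 * se * 3

    def test_zero_second_kernel_reduces_to_single_kernel_model(self, sim_dataset):
        m, ph, y, _ = sim_dataset
        G = vanraden_g(m).K
        y_masked = y.copy()
        y_masked[:30] = np.nan
        one = fit_bayes(y_masked, [G], n_iter=5000, burn_in=1500, seed=7)
        two = fit_bayes(y_masked, [G, np.zeros_like(G)], n_iter=5000, burn_in=1500, seed=8)
        np.testing.assert_allclose(
            two.predict(np.arange(30)), one.predict(np.arange(30)), atol=0.35
        )

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="observed"):
            fit_bayes(np.full(5, np.nan), [np.eye(5)])

    def test_non_psd_kernel_errors(self):
        K = np.diag([1.0, 1.0, -0.5])
        with pytest.raises(ValueError, match="PSD"):
            fit_bayes(np.array([1.0, 2.0, 3.0]), [K])


class TestRemlOracle:
    def test_blup_matches_generalized_ridge_closed_form(self, sim_dataset):
        m, ph, y, _ = sim_dataset
        G = vanraden_g(m).K
        fm = fit_reml_oracle(y, [G])
        s2g = fm.var_components_["kernel_0"]
        s2e = fm.var_components_["residual"]
        expected = ridge_blup(G, y, s2g, s2e, fm.mu_)
        np.testing.assert_allclose(fm.blups_[0], expected, atol=1e-6)

    def test_constant_phenotype_collapses_to_intercept(self):
        y = np.full(20, 4.2)
        fm = fit_reml_oracle(y, [np.eye(20)])
        assert fm.var_components_["kernel_0"] <= 1e-10
        np.testing.assert_allclose(fm.predict(), 4.2, atol=1e-10)

    def test_h2_recovery_on_simulated_data(self, sim_dataset):
        m, ph, y, truth = sim_dataset
        G = vanraden_g(m)
        fm = fit_reml_oracle(y, [G])
        assert abs(fm.h2_ - truth["h2_g"]) < 0.25  # single replicate, loose


class TestPrediction:
    def test_duplicate_line_predicted_like_its_twin(self):
        rng = np.random.default_rng(12)
        n = 40
        L = rng.normal(size=(n, n))
        K = L @ L.T / n
        # line 0 duplicated as line n-1 (identical kernel row/col)
        K[n - 1] = K[0]
        K[:, n - 1] = K[:, 0]
        K[n - 1, n - 1] = K[0, 0]
        g = np.linalg.cholesky(K + 1e-8 * np.eye(n)) @ rng.standard_normal(n)
        y = 1.0 + g + 0.3 * rng.standard_normal(n)
        y_masked = y.copy()
        y_masked[n - 1] = np.nan
        fm = fit_reml_oracle(y_masked, [K])
        assert fm.predict([n - 1])[0] == pytest.approx(
            fm.mu_ + fm.blups_[0][0], abs=1e-8
        )

    def test_disconnected_test_line_predicted_at_intercept(self):
        rng = np.random.default_rng(13)
        n = 30
        K = np.eye(n)
        K[:20, :20] += 0.5  # training block; line 29 has zero cross-covariance
        K[29, :29] = 0.0
        K[:29, 29] = 0.0
        y = 2.0 + rng.normal(size=n)
        y_masked = y.copy()
        y_masked[29] = np.nan
        fm = fit_reml_oracle(y_masked, [K])
        assert fm.predict([29])[0] == pytest.approx(fm.mu_, abs=1e-8)

    def test_prediction_equivariant_under_joint_permutation(self, sim_dataset):
        m, ph, y, _ = sim_dataset
        G = vanraden_g(m).K
        y_masked = y.copy()
        y_masked[:20] = np.nan
        fm = fit_reml_oracle(y_masked, [G])
        rng = np.random.default_rng(14)
        perm = rng.permutation(y.size)
        fm_p = fit_reml_oracle(y_masked[perm], [G[np.ix_(perm, perm)]])
        np.testing.assert_allclose(fm_p.yhat_, fm.yhat_[perm], atol=1e-5)

    def test_unknown_line_id_errors(self):
        fm = fit_reml_oracle(np.array([1.0, 2.0, 3.0]), [np.eye(3)])
        with pytest.raises(KeyError):
            fm.predict([7])

    def test_all_lines_request_returns_full_yhat(self, identity_problem=None):
        fm = fit_reml_oracle(np.array([1.0, 2.0, 3.0, 4.0]), [np.eye(4)])
        np.testing.assert_array_equal(fm.predict(), fm.yhat_)


def test_sklearn_params_round_trip():
    est = BayesKernelBLUP(n_iter=123, random_state=9)
    params = est.get_params()
    clone = BayesKernelBLUP(**params)
    assert clone.get_params() == params
    est2 = REMLKernelBLUP().set_params(max_iter=77)
    assert est2.get_params()["max_iter"] == 77
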