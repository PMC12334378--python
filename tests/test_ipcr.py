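import warnings
from types import SimpleNamespace

import numpy as np
import pytest
import statsmodels.api as sm

from modinvar import fit_ml
from modinvar.ipcr import (
    casewise_scores,
    compute_ipcs,
    ipc_regression,
    iterated_ipcr,
    run_ipcr,
    sample_hessian,
    sandwich_covariance,
)
from modinvar.sem_core import loglik_and_scores, total_loglik_and_grad


@pytest.fixture(scope="module")
def pipeline(spec, med_fit, med_data):
    y, z = med_data
    scores = casewise_scores(med_fit, y)
    hess = sample_hessian(med_fit, y)
    ipcs = compute_ipcs(med_fit, scores, hess)
    return y, z, scores, hess, ipcs


class TestScoresAndHessian:
    def test_first_order_condition(self, pipeline):
        _, _, scores, _, _ = pipeline
        assert np.abs(scores.values.mean(axis=0)).max() < 1e-6

    def test_casewise_scores_match_finite_differences(self, spec, med_fit, med_data):
        y, _ = med_data
        x = med_fit.theta_hat.to_array()
        rows = [0, 17, 311]
        for j in range(0, 30, 7):
            h = 1e-6 * max(1, abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            llp, _ = loglik_and_scores(y[rows], xp, spec, want_scores=False)
            llm, _ = loglik_and_scores(y[rows], xm, spec, want_scores=False)
            fd = (llp - llm) / (2 * h)
            _, sc = loglik_and_scores(y[rows], x, spec)
            np.testing.assert_allclose(sc[:, j], fd, rtol=1e-5, atol=1e-6)

    def test_hessian_symmetric_and_matches_second_differences(
        self, spec, med_fit, med_data, pipeline
    ):
        y, _, _, hess, _ = pipeline
        H = hess.values
        np.testing.assert_allclose(H, H.T, atol=1e-8)
        # independent oracle: second differences of the scalar log-likelihood
        x = med_fit.theta_hat.to_array()
        f0, _ = total_loglik_and_grad(x, y, spec)
        for j in (2, 11, 27):
            h = 3e-4 * max(1, abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            fp, _ = total_loglik_and_grad(xp, y, spec)
            fm, _ = total_loglik_and_grad(xm, y, spec)
            d2 = (fp - 2 * f0 + fm) / h**2
            assert H[j, j] == pytest.approx(d2, rel=1e-3)

    def test_duplicated_data_preserves_score_means(self, spec, med_fit, med_data):
        y, _ = med_data
        s1 = casewise_scores(med_fit, y)
        s2 = casewise_scores(med_fit, np.vstack([y, y]))
        assert s2.values.shape[0] == 2 * s1.values.shape[0]
        np.testing.assert_allclose(
            s1.values.mean(axis=0), s2.values.mean(axis=0), atol=1e-10
        )


class TestIPCIdentities:
    def test_ipc_means_equal_ml_estimates(self, med_fit, pipeline):
        *_, ipcs = pipeline
        np.testing.assert_allclose(
            ipcs.values.mean(axis=0), med_fit.theta_hat.to_array(), atol=1e-8
        )

    def test_ipc_covariance_equals_sandwich(self, pipeline):
        _, _, scores, hess, ipcs = pipeline
        sw = sandwich_covariance(scores, hess)
        cov = np.cov(ipcs.values, rowvar=False, bias=True)
        assert np.abs(cov - sw).max() / np.abs(sw).max() < 1e-6

    def test_univariate_mean_ipcs_are_the_observations(self):
        """Normal-mean model: score_i = (x_i - m)/s2, H = -N/s2, so
        IPC_i = m - (H/N)^{-1} S_i = x_i exactly."""
        rng = np.random.default_rng(3)
        x = rng.normal(2.0, 1.5, 50)
        m, s2 = x.mean(), x.var()
        scores = SimpleNamespace(
            values=((x - m) / s2)[:, None], parameter_names=["mean"]
        )
        hess = SimpleNamespace(values=np.array([[-len(x) / s2]]))
        fake_fit = SimpleNamespace(
            theta_hat=SimpleNamespace(to_array=lambda: np.array([m]))
        )
        ipcs = compute_ipcs(fake_fit, scores, hess)
        np.testing.assert_allclose(ipcs.values[:, 0], x, atol=1e-12)


class TestIPCRegression:
    def test_matches_statsmodels_ols(self, pipeline):
        _, z, _, _, ipcs = pipeline
        table = ipc_regression(ipcs, z).table
        for j in (0, 12, 29):
            ols = sm.OLS(ipcs.values[:, j], sm.add_constant(z)).fit()
            row = table.iloc[j]
            np.testing.assert_allclose(
                [row["gamma0"], row["gamma1"]], ols.params, rtol=1e-10
            )
            np.testing.assert_allclose([row["se0"], row["se1"]], ols.bse, rtol=1e-10)
            ci = ols.conf_int()
            np.testing.assert_allclose(
                [row["ci1_low"], row["ci1_high"]], ci[1], rtol=1e-8
            )

    def test_degrees_of_freedom_are_n_minus_2(self, spec, true_theta):
        from modinvar.sem_core import implied_moments

        rng = np.random.default_rng(44)
        mu, sigma = implied_moments(true_theta, spec)
        y = rng.multivariate_normal(mu, sigma, size=399)
        z = rng.standard_normal(399)
        z = (z - z.mean()) / z.std()
        fit = fit_ml(y, spec)
        assert run_ipcr(fit, y, z).df_resid == 397

    def test_exactly_linear_column_recovered_without_residual(self, pipeline):
        _, z, _, _, _ = pipeline
        fake = np.column_stack([1.0 + 0.5 * z, 2.0 - 0.3 * z])
        tab = ipc_regression(fake, z, ["p0", "p1"]).table
        np.testing.assert_allclose(tab["gamma0"], [1.0, 2.0], atol=1e-10)
        np.testing.assert_allclose(tab["gamma1"], [0.5, -0.3], atol=1e-10)
        np.testing.assert_allclose(tab["se1"], 0.0, atol=1e-10)

    def test_constant_moderator_rejected(self, pipeline):
        *_, ipcs = pipeline
        with pytest.raises(ValueError, match="constant"):
            ipc_regression(ipcs, np.ones(ipcs.values.shape[0]))

    def test_replication_invariance(self, spec, med_fit, med_data):
        """Doubling the dataset leaves coefficients unchanged and scales the
        t statistics by ~sqrt((2N-2)/(N-2))."""
        y, z = med_data
        t1 = run_ipcr(med_fit, y, z).table
        y2, z2 = np.vstack([y, y]), np.r_[z, z]
        fit2 = fit_ml(y2, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t2 = run_ipcr(fit2, y2, z2).table
        np.testing.assert_allclose(
            t2[["gamma0", "gamma1"]], t1[["gamma0", "gamma1"]], rtol=1e-4, atol=1e-6
        )
        N = len(z)
        expected = np.sqrt((2 * N - 2) / (N - 2))
        ratio = (t2["t1"] / t1["t1"]).to_numpy()
        np.testing.assert_allclose(ratio, expected, rtol=0.02)


class TestIteratedIPCR:
    def test_null_dgp_converges_close_to_standard(self, spec, med_fit, med_data):
        y, z = med_data
        std = run_ipcr(med_fit, y, z).table
        res = iterated_ipcr(med_fit, y, spec, z)
        assert res.converged
        diff = np.abs(
            res.table[["gamma0", "gamma1"]].values - std[["gamma0", "gamma1"]].values
        )
        assert np.median(diff) < 0.05
        assert diff.max() < 0.5

    def test_group_loading_difference_bias_corrected(self, onefac_spec):
        """Iterated slope closer to the two-group ML loading difference."""
        rng = np.random.default_rng(7)
        Ng = 300

        def gen(lam2):
            eta = rng.standard_normal(Ng)[:, None]
            lam = np.array([1.0, lam2, 1.0])
            return 2.0 + eta * lam + rng.standard_normal((Ng, 3)) * 0.6

        g0, g1 = gen(0.6), gen(1.4)
        y = np.vstack([g0, g1])
        z = np.r_[np.full(Ng, -1.0), np.full(Ng, 1.0)]
        fit = fit_ml(y, onefac_spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            std = run_ipcr(fit, y, z)
            it = iterated_ipcr(fit, y, onefac_spec, z)
        assert it.converged
        fa, fb = fit_ml(g0, onefac_spec), fit_ml(g1, onefac_spec)
        ml_slope = (fb.estimates["lambda_b"] - fa.estimates["lambda_b"]) / 2.0
        e_std = abs(std.table.loc["lambda_b", "gamma1"] - ml_slope)
        e_it = abs(it.table.loc["lambda_b", "gamma1"] - ml_slope)
        assert e_it < e_std

    def test_extreme_effects_flag_nonconvergence_without_raising(
        self, spec, med_fit, med_data
    ):
        y, z = med_data
        res = iterated_ipcr(med_fit, y, spec, z, max_iter=1, tol=1e-12)
        assert res.converged in (True, False)  # no exception, honest flag
        assert res.n_iter >= 1
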