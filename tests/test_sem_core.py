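import warnings

import numpy as np
import pytest
from scipy import stats

from modinvar import (
    ModelSpecError,
    ParameterVector,
    build_model_spec,
    fit_indices,
    fit_ml,
    implied_moments,
    mediation_spec,
)
from modinvar.sem_core import (
    ModelSpec,
    loglik_and_scores,
    saturated_loglik,
    total_loglik_and_grad,
)


class TestModelSpec:
    def test_mediation_model_has_30_parameters_and_df_24(self, spec):
        assert spec.n_free == 30
        assert spec.df == 24

    def test_single_factor_three_indicators_is_just_identified(self, onefac_spec):
        # 3 intercepts + 2 loadings + 3 residual variances + 1 factor variance
        assert onefac_spec.n_free == 9
        assert onefac_spec.df == 0

    def test_duplicate_indicator_rejected(self):
        with pytest.raises(ModelSpecError, match="exactly one factor"):
            build_model_spec(
                {
                    "factors": ["A", "B"],
                    "indicators": {"A": ["i1", "i2", "i3"], "B": ["i1", "i4", "i5"]},
                }
            )

    def test_cyclic_paths_rejected(self):
        with pytest.raises(ModelSpecError, match="cycle"):
            build_model_spec(
                {
                    "factors": ["A", "B"],
                    "indicators": {"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]},
                    "paths": [["A", "B"], ["B", "A"]],
                }
            )

    def test_too_few_indicators_rejected(self):
        with pytest.raises(ModelSpecError, match="need >= 2"):
            build_model_spec({"factors": ["A"], "indicators": {"A": ["a1"]}})


class TestImpliedMoments:
    def test_hand_built_single_factor_covariance(self):
        # lambda = [1, 0.5], psi = 2, Theta = I  =>  [[3, 1], [1, 1.5]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = ModelSpec(factors=("F",), indicators={"F": ("a", "b")})
        pv = ParameterVector(
            alpha=[0, 0], lam=[0.5], theta=[1, 1], psi=[2], beta=[]
        )
        mu, sigma = implied_moments(pv, s)
        np.testing.assert_allclose(sigma, [[3.0, 1.0], [1.0, 1.5]])
        np.testing.assert_allclose(mu, 0.0)

    def test_zero_paths_give_block_diagonal_covariance(self, spec, true_theta):
        pv = ParameterVector(
            alpha=true_theta.alpha,
            lam=np.zeros(6),
            theta=true_theta.theta,
            psi=true_theta.psi,
            beta=np.zeros(3),
        )
        _, sigma = implied_moments(pv, spec)
        # only the fixed-loading indicators (one per factor) carry factor
        # variance; all cross-construct covariances vanish
        off_blocks = sigma[:3, 3:]
        np.testing.assert_allclose(off_blocks, 0.0, atol=1e-12)
        first = [0, 3, 6]
        for k, j in enumerate(first):
            assert sigma[j, j] == pytest.approx(
                true_theta.psi[k] + true_theta.theta[j]
            )

    def test_negative_residual_variance_rejected(self, spec, true_theta):
        bad = true_theta.to_array().copy()
        bad[15] = -0.1  # a theta entry
        with pytest.raises(ValueError, match="strictly positive"):
            implied_moments(bad, spec)

    def test_indicator_permutation_equivariance(self, spec, true_theta):
        """Reordering indicators permutes rows/columns of the implied moments."""
        perm_spec = mediation_spec(
            {
                "X": ["x2", "x1", "x3"],
                "M": ["m1", "m2", "m3"],
                "Y": ["y1", "y2", "y3"],
            }
        )
        # same model with x1/x2 swapped: x2 now carries the unit loading, so
        # express the original parameters in the rescaled metric
        lam_x2 = true_theta.lam[0]
        scale = lam_x2  # new fixed indicator x2 has old loading lam_x2
        pv = ParameterVector(
            alpha=true_theta.alpha[[1, 0, 2, 3, 4, 5, 6, 7, 8]],
            lam=np.r_[1.0 / scale, true_theta.lam[1] / scale, true_theta.lam[2:]],
            theta=true_theta.theta[[1, 0, 2, 3, 4, 5, 6, 7, 8]],
            psi=np.r_[true_theta.psi[0] * scale**2, true_theta.psi[1:]],
            beta=true_theta.beta * [1.0 / scale, 1.0 / scale, 1.0],
        )
        mu0, sig0 = implied_moments(true_theta, spec)
        mu1, sig1 = implied_moments(pv, perm_spec)
        p = [1, 0, 2, 3, 4, 5, 6, 7, 8]
        np.testing.assert_allclose(mu1, mu0[p], rtol=1e-10)
        np.testing.assert_allclose(sig1, sig0[np.ix_(p, p)], rtol=1e-9)


class TestLikelihood:
    def test_analytic_gradient_matches_finite_differences(self, spec, med_data):
        y, _ = med_data
        rng = np.random.default_rng(5)
        x = ParameterVector(
            alpha=rng.normal(3, 0.4, 9),
            lam=rng.uniform(0.8, 1.2, 6),
            theta=rng.uniform(0.5, 0.8, 9),
            psi=[0.5, 0.5, 0.4],
            beta=[0.2, 0.0, -0.1],
        ).to_array()
        _, g = total_loglik_and_grad(x, y[:150], spec)
        for j in range(0, 30, 4):
            h = 1e-6 * max(1.0, abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            fd = (
                total_loglik_and_grad(xp, y[:150], spec)[0]
                - total_loglik_and_grad(xm, y[:150], spec)[0]
            ) / (2 * h)
            assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-5)

    def test_casewise_loglik_sums_match_mvn(self, spec, true_theta, med_data):
        y, _ = med_data
        mu, sigma = implied_moments(true_theta, spec)
        ll, _ = loglik_and_scores(y, true_theta, spec, want_scores=False)
        ref = stats.multivariate_normal(mu, sigma).logpdf(y)
        np.testing.assert_allclose(ll, ref, rtol=1e-10)


class TestFitML:
    def test_recovers_truth_at_large_n(self, spec, true_theta):
        rng = np.random.default_rng(99)
        mu, sigma = implied_moments(true_theta, spec)
        y = rng.multivariate_normal(mu, sigma, size=100_000)
        fit = fit_ml(y, spec)
        assert fit.converged
        est, tru = fit.theta_hat.to_array(), true_theta.to_array()
        se = fit.se.to_numpy()
        # consistency: within 2% of truth up to residual sampling error
        tol = np.maximum(0.02 * np.abs(tru), 3.0 * se)
        assert np.all(np.abs(est - tru) < tol)

    def test_gradient_norm_contract(self, med_fit):
        assert med_fit.converged
        assert med_fit.grad_norm < 1e-6

    def test_too_small_sample_rejected(self, spec):
        with pytest.raises(ValueError, match="cannot identify"):
            fit_ml(np.zeros((10, 9)), spec)

    def test_missing_values_rejected(self, spec, med_data):
        y, _ = med_data
        y = y.copy()
        y[3, 4] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_ml(y, spec)


@pytest.fixture(scope="module")
def exact_fit(spec, true_theta):
    """Data whose sample moments equal the implied moments exactly."""
    rng = np.random.default_rng(21)
    mu, sigma = implied_moments(true_theta, spec)
    x = rng.standard_normal((400, 9))
    x -= x.mean(axis=0)
    S = np.cov(x, rowvar=False, bias=True)
    x = x @ np.linalg.inv(np.linalg.cholesky(S)).T
    y = mu + x @ np.linalg.cholesky(sigma).T
    fit = fit_ml(y, spec)
    return fit, y


class TestFitIndices:
    def test_perfect_fit_limit(self, exact_fit):
        fit, y = exact_fit
        idx = fit_indices(fit, y)
        assert idx.chisq == pytest.approx(0.0, abs=1e-4)
        assert idx.cfi == 1.0
        assert idx.rmsea == pytest.approx(0.0, abs=1e-4)
        assert idx.df == 24

    def test_saturated_loglik_closed_form(self, med_data):
        y, _ = med_data
        N, p = y.shape
        S = np.cov(y, rowvar=False, bias=True)
        ref = stats.multivariate_normal(y.mean(0), S).logpdf(y).sum()
        assert saturated_loglik(y) == pytest.approx(ref, rel=1e-10)

    def test_rmsea_ci_inverts_noncentral_chisq(self, spec, med_fit, med_data):
        y, _ = med_data
        idx = fit_indices(med_fit, y)
        N = y.shape[0]
        lo, hi = idx.rmsea_ci90
        # the bounds must satisfy the defining noncentral quantile equations
        if lo > 0:
            lam = lo**2 * idx.df * N
            assert stats.ncx2.cdf(idx.chisq, idx.df, lam) == pytest.approx(
                0.95, abs=1e-6
            )
        if hi > 0:
            lam = hi**2 * idx.df * N
            assert stats.ncx2.cdf(idx.chisq, idx.df, lam) == pytest.approx(
                0.05, abs=1e-6
            )
        assert lo <= idx.rmsea <= hi + 1e-12
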