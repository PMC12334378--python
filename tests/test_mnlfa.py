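import numpy as np
import pytest
from scipy import stats

from modinvar.hmc import MCMCConfig
from modinvar.mnlfa import (
    ModerationSpec,
    ParamModeration,
    Prior,
    PriorSpec,
    build_moderated_model,
    marginal_loglik_person,
    prior_predictive,
    sample_posterior,
)
from modinvar.sem_core import implied_moments, loglik_and_scores, split_blocks


@pytest.fixture(scope="module")
def onefac_moderated_data(onefac_spec):
    """Single-factor data with known deterministic moderation."""
    rng = np.random.default_rng(11)
    N = 500
    z = rng.standard_normal(N)
    z = (z - z.mean()) / z.std()
    names = onefac_spec.param_names
    g0 = {
        "alpha_a": 2.0, "alpha_b": 2.5, "alpha_c": 3.0,
        "lambda_b": 0.8, "lambda_c": 1.1,
        "theta_a": np.log(0.5), "theta_b": np.log(0.6), "theta_c": np.log(0.4),
        "psi_F": np.log(0.8),
    }
    g1 = {"alpha_a": 0.3, "alpha_b": 0.3, "alpha_c": 0.3, "lambda_b": 0.2,
          "theta_a": 0.3}
    eta = np.array([[g0[n] + g1.get(n, 0.0) * zz for n in names] for zz in z])
    theta = eta.copy()
    vm = np.array([n.startswith(("theta_", "psi_")) for n in names])
    theta[:, vm] = np.exp(eta[:, vm])
    mu, sigma = implied_moments(split_blocks(theta, onefac_spec), onefac_spec)
    L = np.linalg.cholesky(sigma)
    y = mu + np.einsum("njk,nk->nj", L, rng.standard_normal((N, 3)))
    return y, z, g0, g1


class TestModerationSpec:
    def test_default_mcmc_settings_are_four_chains_6000_iterations(self):
        cfg = MCMCConfig()
        assert cfg.chains == 4
        assert cfg.iterations == 6000

    def test_exponential_link_assigned_to_variances(self, spec):
        mod = ModerationSpec.configural(spec)
        assert mod.link("theta_x1") == "exp"
        assert mod.link("psi_X") == "exp"
        assert mod.link("lambda_x2") == "identity"
        assert mod.link("beta_X_M") == "identity"

    def test_moderating_fixed_loading_rejected(self, spec):
        mod = ModerationSpec.configural(spec)
        mod.params["lambda_x1"] = ParamModeration(True, False)  # fixed at 1
        with pytest.raises(ValueError, match="fixed or unknown"):
            build_moderated_model(spec, mod)

    def test_prior_scale_must_be_positive(self):
        with pytest.raises(ValueError, match="strictly positive"):
            Prior("normal", 0.0, 0.0)


class TestModeratedMapping:
    def test_unmoderated_limit_is_constant(self, onefac_spec):
        mod = ModerationSpec.configural(onefac_spec, stochastic=False)
        model = build_moderated_model(onefac_spec, mod)
        z = np.linspace(-2, 2, 7)
        U = np.zeros(model.dim(7))
        U[: onefac_spec.n_free] = [2.0, 2.5, 3.0, 0.8, 1.1, -0.5, -0.5, -0.5, 0.0]
        # gamma1 entries stay 0 -> person parameters constant in z
        blocks, _ = model(U, z)
        for key in ("alpha", "lam"):
            assert np.ptp(blocks[key], axis=0).max() == 0.0
        np.testing.assert_allclose(blocks["theta"], np.exp(-0.5), rtol=1e-12)
        np.testing.assert_allclose(blocks["psi"], 1.0, rtol=1e-12)

    def test_exponential_link_worked_example(self, onefac_spec):
        """Variance regression gamma0=0.5, gamma1=0.3 at Z=1 -> exp(0.8)."""
        mod = ModerationSpec.configural(onefac_spec, stochastic=False)
        model = build_moderated_model(onefac_spec, mod)
        names = onefac_spec.param_names
        z = np.array([1.0])
        U = np.zeros(model.dim(1))
        j = names.index("theta_a")
        U[j] = 0.5
        U[onefac_spec.n_free + model.mod_cols.tolist().index(j)] = 0.3
        blocks, _ = model(U, z)
        assert blocks["theta"][0, 0] == pytest.approx(np.exp(0.8), rel=1e-12)


class TestMarginalLikelihood:
    def test_unmoderated_limit_matches_casewise_loglik(
        self, spec, true_theta, med_data
    ):
        y, _ = med_data
        ll_ref, _ = loglik_and_scores(y[:50], true_theta, spec, want_scores=False)
        blocks = {
            "alpha": true_theta.alpha, "lam": true_theta.lam,
            "theta": true_theta.theta, "psi": true_theta.psi,
            "beta": true_theta.beta,
        }
        ll = marginal_loglik_person(blocks, y[:50], spec)
        np.testing.assert_allclose(ll, ll_ref, atol=1e-10)

    def test_matches_monte_carlo_latent_integration(self, onefac_spec):
        """Integrating the latent factor by brute-force simulation."""
        rng = np.random.default_rng(8)
        alpha = np.array([1.0, 2.0, 1.5])
        lam_free = np.array([0.7, 1.2])
        th = np.array([0.5, 0.4, 0.6])
        psi = np.array([0.9])
        y_i = np.array([1.4, 2.9, 1.0])
        blocks = {"alpha": alpha, "lam": lam_free, "theta": th, "psi": psi,
                  "beta": np.zeros(0)}
        ll = marginal_loglik_person(blocks, y_i, onefac_spec)[0]
        S = 100_000
        x = rng.normal(0.0, np.sqrt(psi[0]), S)
        lam = np.array([1.0, 0.7, 1.2])
        dens = np.exp(
            np.sum(stats.norm.logpdf(y_i[None, :], alpha + np.outer(x, lam),
                                     np.sqrt(th)), axis=1)
        )
        mc = np.log(dens.mean())
        mc_se = dens.std() / dens.mean() / np.sqrt(S)
        assert abs(ll - mc) < 3 * mc_se

    def test_mean_shift_follows_mvn_quadratic_form(self, onefac_spec):
        alpha = np.array([1.0, 2.0, 1.5])
        blocks = {"alpha": alpha, "lam": np.array([0.7, 1.2]),
                  "theta": np.array([0.5, 0.4, 0.6]), "psi": np.array([0.9]),
                  "beta": np.zeros(0)}
        mu, sigma = implied_moments(split_blocks(
            np.r_[alpha, 0.7, 1.2, 0.5, 0.4, 0.6, 0.9], onefac_spec), onefac_spec)
        y_i = np.array([1.4, 2.9, 1.0])
        delta = 0.37
        P = np.linalg.inv(sigma)
        r = y_i - mu
        d1 = np.ones(3) * delta
        expected_change = -(d1 @ P @ r) - 0.5 * d1 @ P @ d1
        ll0 = marginal_loglik_person(blocks, y_i, onefac_spec)[0]
        ll1 = marginal_loglik_person(blocks, y_i + delta, onefac_spec)[0]
        assert ll1 - ll0 == pytest.approx(expected_change, rel=1e-10)


class TestPosterior:
    def test_parameter_recovery_deterministic(self, onefac_spec, onefac_moderated_data):
        y, z, g0, g1 = onefac_moderated_data
        mod = ModerationSpec.configural(onefac_spec, stochastic=False)
        model = build_moderated_model(onefac_spec, mod)
        cfg = MCMCConfig(chains=2, iterations=1000, seed=5)
        post = sample_posterior(model, y, z, cfg)
        assert post.divergence_fraction < 0.01
        # intercept regressions recover within 10% relative
        for n in ("alpha_a", "alpha_b", "alpha_c"):
            est = post.get(f"gamma0[{n}]").mean()
            assert est == pytest.approx(g0[n], rel=0.10)
        slope = np.mean([post.get(f"gamma1[alpha_{i}]").mean() for i in "abc"])
        assert slope == pytest.approx(0.3, rel=0.25)

    def test_seed_reproducibility(self, onefac_spec, onefac_moderated_data):
        y, z, *_ = onefac_moderated_data
        mod = ModerationSpec.configural(onefac_spec, stochastic=False)
        model = build_moderated_model(onefac_spec, mod)
        cfg = MCMCConfig(chains=2, iterations=200, seed=3)
        a = sample_posterior(model, y[:80], z[:80], cfg)
        b = sample_posterior(model, y[:80], z[:80], cfg)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_approximate_invariance_priors_shrink_null_slopes(
        self, onefac_spec, med_data, spec
    ):
        """N(0, .01) slope priors dominate a null likelihood."""
        y, z = med_data
        y3 = y[:250, :3]  # X-construct indicators, homogeneous truth
        mod = ModerationSpec.configural(onefac_spec, stochastic=False)
        priors = PriorSpec.default(onefac_spec).with_approximate_invariance(
            [n for n in onefac_spec.param_names if n.startswith("lambda_")]
        )
        model = build_moderated_model(onefac_spec, mod, priors)
        post = sample_posterior(
            model, y3, z[:250], MCMCConfig(chains=2, iterations=600, seed=2)
        )
        for n in ("lambda_b", "lambda_c"):
            draws = post.get(f"gamma1[{n}]")
            assert np.mean(np.abs(draws) < 0.05) > 0.95

    def test_stochastic_with_vanishing_heterogeneity_matches_deterministic(
        self, onefac_spec, onefac_moderated_data
    ):
        y, z, *_ = onefac_moderated_data
        y, z = y[:200], z[:200]
        cfg = MCMCConfig(chains=2, iterations=800, seed=7)
        det = build_moderated_model(
            onefac_spec, ModerationSpec.configural(onefac_spec, stochastic=False)
        )
        post_det = sample_posterior(det, y, z, cfg)
        tight = PriorSpec.default(onefac_spec)
        tight.sigma_het = {
            n: Prior("half_normal", 0.0, 0.005) for n in tight.sigma_het
        }
        sto = build_moderated_model(
            onefac_spec, ModerationSpec.configural(onefac_spec, stochastic=True),
            tight,
        )
        post_sto = sample_posterior(sto, y, z, cfg)
        for n in ("gamma0[alpha_a]", "gamma1[alpha_a]", "gamma0[lambda_b]",
                  "gamma0[theta_b]"):
            m_det, m_sto = post_det.get(n).mean(), post_sto.get(n).mean()
            sd = post_det.get(n).std()
            assert abs(m_det - m_sto) < 4 * sd / np.sqrt(50) + 0.05


class TestPriorPredictive:
    def test_deterministic_given_seed(self, onefac_spec):
        model = build_moderated_model(
            onefac_spec, ModerationSpec.configural(onefac_spec, stochastic=True)
        )
        z = np.linspace(-2, 2, 40)
        a = prior_predictive(model, z, n_draws=5, seed=42)
        b = prior_predictive(model, z, n_draws=5, seed=42)
        np.testing.assert_array_equal(a["datasets"], b["datasets"])

    def test_default_priors_give_plausible_scale_range(self, onefac_spec):
        model = build_moderated_model(
            onefac_spec, ModerationSpec.configural(onefac_spec, stochastic=True)
        )
        z = np.linspace(-2, 2, 60)
        out = prior_predictive(model, z, n_draws=60, seed=1)
        med = out["summary"]["median"]
        # bulk of prior mass near Likert-like scale values
        assert (med.abs() < 15).all()
        q25, q75 = out["summary"]["q25"], out["summary"]["q75"]
        assert ((q75 - q25) < 30).all()

    def test_point_mass_priors_collapse_to_measurement_error(self, onefac_spec):
        tiny = PriorSpec(
            gamma0={n: Prior("normal", v, 1e-9) for n, v in zip(
                onefac_spec.param_names,
                [2.0, 2.5, 3.0, 0.8, 1.1, -0.5, -0.5, -0.5, 0.0])},
            gamma1={n: Prior("normal", 0.0, 1e-9) for n in onefac_spec.param_names},
            sigma_het={n: Prior("half_normal", 0.0, 1e-9) for n in onefac_spec.param_names},
        )
        model = build_moderated_model(
            onefac_spec, ModerationSpec.configural(onefac_spec, stochastic=True),
            tiny,
        )
        z = np.zeros(200) + np.linspace(-1, 1, 200)
        out = prior_predictive(model, z, n_draws=30, seed=3)
        # dataset-level means agree across draws up to measurement error
        means = out["datasets"].mean(axis=1)  # (draws, p)
        assert means.std(axis=0).max() < 4.0 / np.sqrt(200)
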