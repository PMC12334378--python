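"""Bayesian moderated nonlinear factor analysis (MNLFA).

Every free parameter of the latent mediation (or factor) model is regressed
on a continuous moderator Z,

    theta_p(v)   = gamma0_p + gamma1_p Z_v  (+ eps_v_p)          (identity)
    variance_p(v) = exp[gamma0_p + gamma1_p Z_v (+ eps_v_p)]     (exp link)

with the exponential link on every variance-type parameter.  Including the
residual eps_v makes the moderation *stochastic*; the residual is indexed by
moderator value v, not by person, so observations sharing a Z value share
residuals.  Estimation is by Hamiltonian Monte Carlo on the latent-marginal
likelihood (latent variables integrated analytically; the conditional model
is linear-Gaussian throughout) with a non-centered parameterisation of the
heterogeneity residuals.

Priors follow the package defaults: loading intercepts N(1, .5) to pin the
reflection mode, indicator-intercept gamma0 ~ N(3, 2), every moderation
slope N(0, .5), variance-regression intercepts N(0, .5) on the log scale,
and heterogeneity SDs half-Cauchy(0, .1).  Approximate invariance replaces
selected slope priors by N(0, .01) and heterogeneity-SD priors by
half-normal(.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hmc import HMCResult, MCMCConfig, ess_bulk, sample_hmc, split_rhat
from .sem_core import (
    ModelSpec,
    _coerce_data,
    implied_moments,
    loglik_and_scores,
    split_blocks,
    start_values,
)

VAR_PREFIXES = ("theta_", "psi_")


def is_variance_param(name: str) -> bool:
    return name.startswith(VAR_PREFIXES)


# ---------------------------------------------------------------------------
# Moderation specification
# ---------------------------------------------------------------------------


@dataclass
class ParamModeration:
    moderated: bool = True
    stochastic: bool = True


@dataclass
class ModerationSpec:
    """Which parameters are moderated, and whether stochastically.

    ``moderate_latent_means`` switches on the latent-mean moderation used at
    the strong-invariance step: latent means stay fixed at zero at Z = 0
    (identification) but acquire a free slope in Z.
    """

    params: dict[str, ParamModeration] = field(default_factory=dict)
    moderate_latent_means: bool = False

    @classmethod
    def configural(cls, spec: ModelSpec, stochastic: bool = True) -> "ModerationSpec":
        """All free parameters moderated (the configural MNLFA model)."""
        return cls(
            params={
                n: ParamModeration(True, stochastic) for n in spec.param_names
            }
        )

    @classmethod
    def none(cls, spec: ModelSpec) -> "ModerationSpec":
        return cls(
            params={n: ParamModeration(False, False) for n in spec.param_names}
        )

    def validate(self, spec: ModelSpec) -> None:
        unknown = set(self.params) - set(spec.param_names)
        if unknown:
            raise ValueError(
                f"moderation requested for non-free (fixed or unknown) "
                f"parameters: {sorted(unknown)}"
            )

    def link(self, name: str) -> str:
        return "exp" if is_variance_param(name) else "identity"

    def moderated_names(self, spec: ModelSpec) -> list[str]:
        return [
            n
            for n in spec.param_names
            if self.params.get(n, ParamModeration(False, False)).moderated
        ]

    def stochastic_names(self, spec: ModelSpec) -> list[str]:
        return [
            n
            for n in spec.param_names
            if self.params.get(n, ParamModeration(False, False)).stochastic
        ]


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Prior:
    dist: str  # "normal" | "half_cauchy" | "half_normal"
    loc: float
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("prior scale must be strictly positive")
        if self.dist in ("half_cauchy", "half_normal") and self.loc != 0.0:
            raise ValueError("half distributions have location fixed at 0")


APPROX_INVARIANCE_SLOPE = Prior("normal", 0.0, 0.01)
APPROX_INVARIANCE_SD = Prior("half_normal", 0.0, 0.01)


@dataclass
class PriorSpec:
    gamma0: dict[str, Prior]
    gamma1: dict[str, Prior]
    sigma_het: dict[str, Prior]
    latent_mean_slope: Prior = Prior("normal", 0.0, 0.5)

    @classmethod
    def default(cls, spec: ModelSpec) -> "PriorSpec":
        g0, g1, sd = {}, {}, {}
        for n in spec.param_names:
            if n.startswith("lambda_"):
                g0[n] = Prior("normal", 1.0, 0.5)
            elif n.startswith("alpha_"):
                g0[n] = Prior("normal", 3.0, 2.0)
            else:  # beta and (log-scale) variance regressions
                g0[n] = Prior("normal", 0.0, 0.5)
            g1[n] = Prior("normal", 0.0, 0.5)
            sd[n] = Prior("half_cauchy", 0.0, 0.1)
        return cls(gamma0=g0, gamma1=g1, sigma_het=sd)

    @classmethod
    def diffuse(cls, spec: ModelSpec, scale: float = 10.0) -> "PriorSpec":
        base = cls.default(spec)
        g0 = {n: Prior("normal", 0.0, scale) for n in base.gamma0}
        g1 = {n: Prior("normal", 0.0, scale) for n in base.gamma1}
        sd = {n: Prior("half_cauchy", 0.0, 1.0) for n in base.sigma_het}
        return cls(gamma0=g0, gamma1=g1, sigma_het=sd,
                   latent_mean_slope=Prior("normal", 0.0, scale))

    def with_approximate_invariance(self, params: list[str]) -> "PriorSpec":
        """Tight zero-centered priors on the named parameters' moderation
        slopes and heterogeneity SDs (the Bayesian 'wiggle room')."""
        g1 = dict(self.gamma1)
        sd = dict(self.sigma_het)
        for n in params:
            if n not in g1:
                raise ValueError(f"unknown parameter {n!r} for invariance prior")
            g1[n] = APPROX_INVARIANCE_SLOPE
            sd[n] = APPROX_INVARIANCE_SD
        return replace(self, gamma1=g1, sigma_het=sd)


def _prior_logpdf_grad(prior: Prior, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log density and gradient for an unconstrained coordinate.

    half distributions are parameterised through x = log(sd); the returned
    density includes the Jacobian term."""
    if prior.dist == "normal":
        r = (x - prior.loc) / prior.scale
        return -0.5 * r * r, -r / prior.scale
    sd = np.exp(np.minimum(x, 30.0))
    if prior.dist == "half_cauchy":
        u = sd / prior.scale
        lp = -np.log1p(u * u) + x
        g = -2.0 * u * u / (1.0 + u * u) + 1.0
        return lp, g
    if prior.dist == "half_normal":
        u = sd / prior.scale
        lp = -0.5 * u * u + x
        return lp, -u * u + 1.0
    raise ValueError(f"unknown prior family {prior.dist!r}")


# ---------------------------------------------------------------------------
# The moderated model
# ---------------------------------------------------------------------------


class ModeratedModel:
    """Maps sampled moderation coefficients to person-specific parameters
    and exposes the batched posterior log-density and gradient."""

    def __init__(
        self,
        spec: ModelSpec,
        mod: ModerationSpec,
        priors: PriorSpec,
        marginalize_mean_heterogeneity: bool = True,
    ):
        mod.validate(spec)
        self.spec = spec
        self.mod = mod
        self.priors = priors
        q = spec.n_free
        names = spec.param_names
        self.var_cols = np.array([is_variance_param(n) for n in names])
        self.mod_cols = np.array(
            [names.index(n) for n in mod.moderated_names(spec)], dtype=int
        )
        self.stoch_cols = np.array(
            [names.index(n) for n in mod.stochastic_names(spec)], dtype=int
        )
        # Indicator-intercept heterogeneity residuals enter the mean
        # linearly, so they can be integrated analytically: each adds
        # sigma_het^2 to that indicator's residual variance.  This is exact
        # when every observation has its own moderator value (continuous Z)
        # and treats intercept residuals as person-specific when values tie;
        # disable to sample the shared residuals explicitly.
        self.marginalize_mean_heterogeneity = marginalize_mean_heterogeneity
        marg = []
        if marginalize_mean_heterogeneity:
            marg = [
                j for j in self.stoch_cols if names[j].startswith("alpha_")
            ]
        self.marg_cols = np.array(marg, dtype=int)
        self.eps_cols = np.array(
            [j for j in self.stoch_cols if j not in set(marg)], dtype=int
        )
        # residual-variance column receiving each marginalised intercept's
        # heterogeneity
        self.marg_theta_cols = np.array(
            [names.index("theta_" + names[j][len("alpha_"):]) for j in self.marg_cols],
            dtype=int,
        )
        # For stochastic variance-type parameters the likelihood constrains
        # gamma0 + sigma_het^2/2 (the log of the marginal variance), not
        # gamma0 itself; sampling that sum (delta) straightens the curved
        # (gamma0, log sigma) ridge.  gamma0 is recovered in post-processing.
        self.delta_cols = np.array(
            [j for j in self.stoch_cols if self.var_cols[j]], dtype=int
        )
        lut = {j: p for p, j in enumerate(self.stoch_cols)}
        self._delta_spos = np.array([lut[j] for j in self.delta_cols], dtype=int)
        self.n_latent_slopes = spec.n_factors if mod.moderate_latent_means else 0
        # flattened sampled-parameter layout
        self.sampled_names: list[str] = [f"gamma0[{n}]" for n in names]
        self.sampled_names += [f"gamma1[{n}]" for n in mod.moderated_names(spec)]
        self.sampled_names += [
            f"nu_slope[{f}]" for f in (spec.factors if self.n_latent_slopes else [])
        ]
        self.sampled_names += [f"log_sigma[{n}]" for n in mod.stochastic_names(spec)]
        self._q = q
        self._head = q + len(self.mod_cols) + self.n_latent_slopes + len(self.stoch_cols)

    # -- layout helpers ----------------------------------------------------
    @property
    def _marg_pos(self) -> np.ndarray:
        lut = {j: p for p, j in enumerate(self.stoch_cols)}
        return np.array([lut[j] for j in self.marg_cols], dtype=int)

    @property
    def _eps_pos(self) -> np.ndarray:
        lut = {j: p for p, j in enumerate(self.stoch_cols)}
        return np.array([lut[j] for j in self.eps_cols], dtype=int)

    def dim(self, n_unique_z: int) -> int:
        return self._head + len(self.eps_cols) * n_unique_z

    def eps_names(self, n_unique_z: int) -> list[str]:
        return [
            f"eps[{self.spec.param_names[j]},{v}]"
            for j in self.eps_cols
            for v in range(n_unique_z)
        ]

    def _slices(self, V: int):
        q, nm, nl, ns = (
            self._q,
            len(self.mod_cols),
            self.n_latent_slopes,
            len(self.stoch_cols),
        )
        ne = len(self.eps_cols)
        i0 = 0
        sl_g0 = slice(i0, i0 + q); i0 += q
        sl_g1 = slice(i0, i0 + nm); i0 += nm
        sl_nu = slice(i0, i0 + nl); i0 += nl
        sl_s = slice(i0, i0 + ns); i0 += ns
        sl_eps = slice(i0, i0 + ne * V)
        return sl_g0, sl_g1, sl_nu, sl_s, sl_eps

    # -- person-specific parameters ----------------------------------------
    def person_params(
        self, U: np.ndarray, z: np.ndarray, v_idx: np.ndarray
    ) -> tuple[dict[str, np.ndarray], np.ndarray | None, np.ndarray, np.ndarray]:
        """Person-specific parameter blocks for sampled vectors ``U``.

        Returns ``(blocks, nu, theta_flat, linkd)`` where ``theta_flat`` is
        (..., N, q) on the natural scale and ``linkd`` the link derivative
        d(theta)/d(eta)."""
        U = np.asarray(U, dtype=float)
        squeeze = U.ndim == 1
        if squeeze:
            U = U[None, :]
        N = z.shape[0]
        V = int(v_idx.max()) + 1 if len(v_idx) else 0
        sl_g0, sl_g1, sl_nu, sl_s, sl_eps = self._slices(V)
        C = U.shape[0]
        g0 = U[:, sl_g0].copy()
        if len(self.delta_cols):
            sd_all = np.exp(np.minimum(U[:, sl_s], 30.0))
            g0[:, self.delta_cols] -= 0.5 * sd_all[:, self._delta_spos] ** 2
        eta = np.broadcast_to(g0[:, None, :], (C, N, self._q)).copy()
        if len(self.mod_cols):
            g1 = U[:, sl_g1]
            eta[:, :, self.mod_cols] += g1[:, None, :] * z[None, :, None]
        sd = np.exp(np.minimum(U[:, sl_s], 30.0)) if len(self.stoch_cols) else None
        if len(self.eps_cols):
            eps = U[:, sl_eps].reshape(C, len(self.eps_cols), V)
            eta[:, :, self.eps_cols] += (
                np.swapaxes(eps[:, :, v_idx], 1, 2) * sd[:, self._eps_pos][:, None, :]
            )
        theta = eta.copy()
        own_var = np.exp(np.clip(eta[:, :, self.var_cols], -30.0, 30.0))
        theta[:, :, self.var_cols] = own_var
        linkd = np.ones_like(theta)
        linkd[:, :, self.var_cols] = own_var
        if len(self.marg_cols):
            # analytically integrated intercept heterogeneity inflates the
            # corresponding residual variances
            theta[:, :, self.marg_theta_cols] += (
                sd[:, self._marg_pos] ** 2
            )[:, None, :]
        nu = None
        if self.n_latent_slopes:
            nu = U[:, sl_nu][:, None, :] * z[None, :, None]
        blocks = split_blocks(theta, self.spec)
        if squeeze:
            blocks = {k: v[0] for k, v in blocks.items()}
            theta, linkd = theta[0], linkd[0]
            nu = None if nu is None else nu[0]
        return blocks, nu, theta, linkd

    def __call__(self, U: np.ndarray, z: np.ndarray):
        """Evaluate the moderation mapping: person-specific parameters for
        moderator values ``z`` (unique values indexed in sorted order)."""
        _, v_idx = np.unique(z, return_inverse=True)
        blocks, nu, theta, _ = self.person_params(U, z, v_idx)
        return blocks, nu

    # -- posterior log density ----------------------------------------------
    def make_logp(self, data, z: np.ndarray):
        """Batched posterior log-density/gradient closure for HMC."""
        y = _coerce_data(data, self.spec)
        z = np.asarray(z, dtype=float)
        N = y.shape[0]
        if z.shape != (N,):
            raise ValueError("moderator length does not match data")
        if not np.all(np.isfinite(z)) or np.isnan(y).any():
            raise ValueError("data and moderator must be complete and finite")
        _, v_idx = np.unique(z, return_inverse=True)
        V = int(v_idx.max()) + 1
        sl_g0, sl_g1, sl_nu, sl_s, sl_eps = self._slices(V)
        ns = len(self.stoch_cols)
        # contiguous groups of shared moderator values for segment sums
        perm = np.argsort(v_idx, kind="stable")
        bounds = np.searchsorted(v_idx[perm], np.arange(V))
        names = self.spec.param_names

        g0_priors = [self.priors.gamma0[n] for n in names]
        g1_priors = [self.priors.gamma1[names[j]] for j in self.mod_cols]
        sd_priors = [self.priors.sigma_het[names[j]] for j in self.stoch_cols]

        def logp_and_grad(U: np.ndarray):
            U = np.atleast_2d(U)
            C = U.shape[0]
            grad = np.zeros_like(U)
            try:
                blocks, nu, theta, linkd = self.person_params(U, z, v_idx)
                ll, sc = loglik_and_scores(y, blocks, self.spec, nu=nu)
            except np.linalg.LinAlgError:
                return np.full(C, -np.inf), grad
            lp = ll.sum(axis=1)
            q = self._q
            w = sc[:, :, :q] * linkd  # d loglik / d eta
            wsum = w.sum(axis=1)
            grad[:, sl_g0] = wsum
            if len(self.delta_cols):
                sd_all = np.exp(np.minimum(U[:, sl_s], 30.0))
                sd_d = sd_all[:, self._delta_spos]
                # eta = delta - sd^2/2 + ...: extra -sd^2 term toward log sd
                grad[:, sl_s.start + self._delta_spos] += (
                    wsum[:, self.delta_cols] * (-(sd_d**2))
                )
            if len(self.mod_cols):
                grad[:, sl_g1] = np.einsum("cnj,n->cj", w[:, :, self.mod_cols], z)
            if self.n_latent_slopes:
                grad[:, sl_nu] = np.einsum("cnk,n->ck", sc[:, :, q:], z)
            if ns:
                sd = np.exp(np.minimum(U[:, sl_s], 30.0))
                if len(self.eps_cols):
                    ne = len(self.eps_cols)
                    eps = U[:, sl_eps].reshape(C, ne, V)
                    ws = w[:, :, self.eps_cols]  # (C, N, ne)
                    # gradient wrt eps_raw: segment-sum over shared z values
                    seg = np.add.reduceat(ws[:, perm, :], bounds, axis=1)
                    sde = sd[:, self._eps_pos]
                    grad[:, sl_eps] = (
                        np.swapaxes(seg, 1, 2) * sde[:, :, None]
                    ).reshape(C, ne * V)
                    eps_of_person = np.swapaxes(eps[:, :, v_idx], 1, 2)
                    grad[:, sl_s.start + self._eps_pos] += (
                        np.einsum("cnj,cnj->cj", ws, eps_of_person) * sde
                    )
                if len(self.marg_cols):
                    # marginalised intercept heterogeneity: d theta_jj/ds = 2 sd^2
                    sdm = sd[:, self._marg_pos]
                    grad[:, sl_s.start + self._marg_pos] += (
                        sc[:, :, self.marg_theta_cols].sum(axis=1) * 2.0 * sdm * sdm
                    )

            # priors (gamma0 priors act on the back-transformed gamma0)
            delta_lut = {int(j): p for j, p in zip(self.delta_cols, self._delta_spos)}
            for j, pr in enumerate(g0_priors):
                xj = U[:, j]
                if j in delta_lut:
                    sdj = np.exp(np.minimum(U[:, sl_s.start + delta_lut[j]], 30.0))
                    xj = xj - 0.5 * sdj**2
                lpj, gj = _prior_logpdf_grad(pr, xj)
                lp += lpj
                grad[:, j] += gj
                if j in delta_lut:
                    grad[:, sl_s.start + delta_lut[j]] += gj * (-(sdj**2))
            off = sl_g1.start
            for j, pr in enumerate(g1_priors):
                lpj, gj = _prior_logpdf_grad(pr, U[:, off + j])
                lp += lpj
                grad[:, off + j] += gj
            if self.n_latent_slopes:
                lpj, gj = _prior_logpdf_grad(
                    self.priors.latent_mean_slope, U[:, sl_nu]
                )
                lp += lpj.sum(axis=1)
                grad[:, sl_nu] += gj
            if ns:
                off = sl_s.start
                for j, pr in enumerate(sd_priors):
                    lpj, gj = _prior_logpdf_grad(pr, U[:, off + j])
                    lp += lpj
                    grad[:, off + j] += gj
                e = U[:, sl_eps]
                lp += -0.5 * np.sum(e * e, axis=1)
                grad[:, sl_eps] += -e
            return lp, grad

        logp_and_grad.n_obs = N
        logp_and_grad.v_idx = v_idx
        logp_and_grad.V = V
        return logp_and_grad

    def initial_positions(self, data, z, cfg: MCMCConfig) -> np.ndarray:
        """Deterministic data-driven start (moment heuristics on the log
        scale for variances) with per-chain jitter."""
        y = _coerce_data(data, self.spec)
        rng = np.random.default_rng(cfg.seed + 1_000_003)
        _, v_idx = np.unique(np.asarray(z, float), return_inverse=True)
        V = int(v_idx.max()) + 1
        d = self.dim(V)
        sv = start_values(y, self.spec).to_array()
        sv[self.var_cols] = np.log(sv[self.var_cols])
        base = np.zeros(d)
        sl_g0, sl_g1, sl_nu, sl_s, sl_eps = self._slices(V)
        base[sl_g0] = sv
        base[sl_s] = np.log(0.05)
        U0 = base[None, :] + rng.normal(0.0, 0.05, size=(cfg.chains, d))
        U0[:, sl_eps] = rng.normal(0.0, 0.01, size=(cfg.chains, sl_eps.stop - sl_eps.start))
        return U0


def build_moderated_model(
    spec: ModelSpec, mod: ModerationSpec, priors: PriorSpec | None = None
) -> ModeratedModel:
    """Validate and assemble the moderated model."""
    return ModeratedModel(spec, mod, priors or PriorSpec.default(spec))


def marginal_loglik_person(
    blocks, y_i: np.ndarray, spec: ModelSpec, nu: np.ndarray | None = None
) -> np.ndarray:
    """Latent-marginal MVN log density of observation(s) at person-specific
    parameter blocks (latent variables integrated analytically)."""
    y_i = np.atleast_2d(np.asarray(y_i, dtype=float))
    ll, _ = loglik_and_scores(y_i, blocks, spec, nu=nu, want_scores=False)
    return ll


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus diagnostics for a moderated model."""

    model: ModeratedModel | object
    sampled_names: list[str]
    draws: np.ndarray  # (chains, kept, d)
    divergent: np.ndarray
    accept_rate: float
    data_fingerprint: tuple
    z: np.ndarray
    reported: list[str]  # names diagnosed/reported (gamma, sigma, nu)

    def get(self, name: str) -> np.ndarray:
        """Draws for a reported parameter (back-transforming the sampled
        delta coordinate to gamma0 for stochastic variance parameters)."""
        j = self.sampled_names.index(name)
        x = self.draws[:, :, j]
        model = self.model
        if name.startswith("gamma0[") and getattr(model, "delta_cols", None) is not None:
            pname = name[len("gamma0[") : -1]
            col = model.spec.param_names.index(pname)
            if col in model.delta_cols:
                s_name = f"log_sigma[{pname}]"
                s = self.draws[:, :, self.sampled_names.index(s_name)]
                x = x - 0.5 * np.exp(2.0 * s)
        return x

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def divergence_fraction(self) -> float:
        return float(self.divergent.mean())

    def posterior_mean(self, name: str) -> float:
        x = self.get(name)
        if name.startswith("log_sigma["):
            x = np.exp(x)
        return float(x.mean())

    def summary(self, names: list[str] | None = None) -> pd.DataFrame:
        names = names or self.reported
        rows = []
        for n in names:
            x = self.get(n)
            nat = np.exp(x) if n.startswith("log_sigma[") else x
            rows.append(
                {
                    "parameter": n.replace("log_sigma[", "sigma["),
                    "mean": nat.mean(),
                    "sd": nat.std(ddof=1),
                    "q2.5": np.quantile(nat, 0.025),
                    "q97.5": np.quantile(nat, 0.975),
                    "rhat": split_rhat(x),
                    "ess": ess_bulk(x),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def max_rhat(self) -> float:
        return float(
            np.nanmax([split_rhat(self.get(n)) for n in self.reported])
        )

    def converged(self, rhat_threshold: float = 1.05, max_div_frac: float = 0.01) -> bool:
        """The simulation-harness convergence rule: split-R-hat below the
        threshold on all reported parameters and a small divergence share."""
        return bool(
            self.max_rhat() < rhat_threshold
            and self.divergence_fraction < max_div_frac
        )

    def pointwise_loglik(self, data, max_draws: int = 1000, chunk: int = 16) -> np.ndarray:
        """Matrix (draws, N) of per-observation latent-marginal log
        likelihoods, thinned evenly to at most ``max_draws`` retained draws."""
        y = _coerce_data(data, self.model.spec)
        z = self.z
        _, v_idx = np.unique(z, return_inverse=True)
        C, S, d = self.draws.shape
        total = C * S
        flat = self.draws.reshape(total, d)
        if total > max_draws:
            idx = np.linspace(0, total - 1, max_draws).astype(int)
            flat = flat[idx]
        out = []
        for i0 in range(0, flat.shape[0], chunk):
            blocks, nu, _, _ = self.model.person_params(flat[i0 : i0 + chunk], z, v_idx)
            ll, _ = loglik_and_scores(y, blocks, self.model.spec, nu=nu, want_scores=False)
            out.append(ll)
        return np.concatenate(out, axis=0)


def sample_posterior(
    model: ModeratedModel,
    data,
    z: np.ndarray,
    cfg: MCMCConfig | None = None,
    init: np.ndarray | None = None,
) -> PosteriorDraws:
    """Sample the moderated model's posterior by vectorised-chain HMC."""
    cfg = cfg or MCMCConfig()
    y = _coerce_data(data, model.spec)
    z = np.asarray(z, dtype=float)
    logp = model.make_logp(y, z)
    d = model.dim(logp.V)
    if init is None:
        init = model.initial_positions(y, z, cfg)
    if cfg.dense_head == 0:
        # moderation coefficients and heterogeneity scales correlate; give
        # the head block a dense metric (eps coordinates stay diagonal)
        cfg = replace(cfg, dense_head=model._head)
    res: HMCResult = sample_hmc(logp, d, init, cfg)
    reported = [
        n
        for n in model.sampled_names
        if n.startswith(("gamma0[", "gamma1[", "nu_slope[", "log_sigma["))
    ]
    names = model.sampled_names + model.eps_names(logp.V)
    return PosteriorDraws(
        model=model,
        sampled_names=names,
        draws=res.draws,
        divergent=res.divergent,
        accept_rate=res.accept_rate,
        data_fingerprint=(y.shape, float(np.sum(y)), float(np.sum(z))),
        z=z,
        reported=reported,
    )


# ---------------------------------------------------------------------------
# Prior predictive
# ---------------------------------------------------------------------------


def _sample_prior(prior: Prior, size, rng: np.random.Generator) -> np.ndarray:
    if prior.dist == "normal":
        return rng.normal(prior.loc, prior.scale, size)
    if prior.dist == "half_cauchy":
        return np.abs(rng.standard_cauchy(size)) * prior.scale
    if prior.dist == "half_normal":
        return np.abs(rng.normal(0.0, prior.scale, size))
    raise ValueError(prior.dist)


def prior_predictive(
    model: ModeratedModel,
    z: np.ndarray,
    n_draws: int = 100,
    seed: int = 0,
) -> dict:
    """Ancestral simulation from the prior: draw moderation coefficients,
    heterogeneity residuals, latent variables and measurement errors, and
    return simulated indicator tables with a range summary."""
    rng = np.random.default_rng(seed)
    z = np.asarray(z, dtype=float)
    N = z.shape[0]
    spec = model.spec
    names = spec.param_names
    _, v_idx = np.unique(z, return_inverse=True)
    V = int(v_idx.max()) + 1
    datasets = np.empty((n_draws, N, spec.n_indicators))
    for r in range(n_draws):
        eta = np.empty((N, len(names)))
        for j, n in enumerate(names):
            val = _sample_prior(model.priors.gamma0[n], None, rng)
            row = np.full(N, val)
            if j in model.mod_cols:
                row = row + _sample_prior(model.priors.gamma1[n], None, rng) * z
            if j in model.stoch_cols:
                sd = _sample_prior(model.priors.sigma_het[n], None, rng)
                row = row + (sd * rng.standard_normal(V))[v_idx]
            eta[:, j] = row
        theta = eta.copy()
        theta[:, model.var_cols] = np.exp(np.clip(eta[:, model.var_cols], -30, 30))
        nu = None
        if model.n_latent_slopes:
            slopes = _sample_prior(
                model.priors.latent_mean_slope, spec.n_factors, rng
            )
            nu = z[:, None] * slopes[None, :]
        mu, sigma = implied_moments(split_blocks(theta, spec), spec, nu=nu)
        L = np.linalg.cholesky(sigma)
        e = rng.standard_normal((N, spec.n_indicators))
        datasets[r] = mu + np.einsum("njk,nk->nj", L, e)
    flat = datasets.reshape(-1, spec.n_indicators)
    summary = pd.DataFrame(
        {
            "indicator": spec.indicator_names,
            "q1": np.quantile(flat, 0.01, axis=0),
            "q25": np.quantile(flat, 0.25, axis=0),
            "median": np.quantile(flat, 0.5, axis=0),
            "q75": np.quantile(flat, 0.75, axis=0),
            "q99": np.quantile(flat, 0.99, axis=0),
        }
    ).set_index("indicator")
    return {"datasets": datasets, "summary": summary}
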