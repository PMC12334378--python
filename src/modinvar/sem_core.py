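"""Unmoderated latent mediation model: specification, moments, ML estimation.

The measurement model for each indicator j loading on factor k is

    y_j = alpha_j + lambda_j eta_k + eps_j,      eps_j ~ N(0, theta_j),

and the structural model is a recursive system eta = B eta + zeta with
acyclic path matrix B (for the mediation model: X -> M, X -> Y, M -> Y).
Latent variables are identified by fixing their means to zero and the first
loading per factor to one.  The casewise multivariate-normal log-likelihood
and its analytic gradient (the casewise *score*) are implemented in batched
form so that the same code serves maximum-likelihood fitting, individual
parameter contributions, and person-specific (moderated) parameter values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

LOG2PI = np.log(2.0 * np.pi)

# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


class ModelSpecError(ValueError):
    """Invalid model configuration (duplicate indicators, cycles, ...)."""


@dataclass(frozen=True)
class ModelSpec:
    """Confirmatory factor/mediation model layout.

    Parameters
    ----------
    factors
        Ordered construct labels, e.g. ``["X", "M", "Y"]``.
    indicators
        Mapping construct -> ordered indicator (column) labels.  The first
        indicator of each construct carries the fixed unit loading.
    paths
        Ordered ``(source, target)`` pairs of structural regressions.
    """

    factors: tuple[str, ...]
    indicators: dict[str, tuple[str, ...]] = field(hash=False)
    paths: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.factors) < 1:
            raise ModelSpecError("at least one factor is required")
        if set(self.indicators) != set(self.factors):
            raise ModelSpecError("indicators must be given for every factor")
        flat = [i for f in self.factors for i in self.indicators[f]]
        if len(set(flat)) != len(flat):
            raise ModelSpecError("an indicator may load on exactly one factor")
        for f in self.factors:
            n = len(self.indicators[f])
            if n < 2:
                raise ModelSpecError(f"factor {f!r} has {n} indicator(s); need >= 2")
            if n < 3:
                warnings.warn(
                    f"factor {f!r} has only {n} indicators; the single-factor "
                    "model is not identified in isolation",
                    stacklevel=3,
                )
        known = set(self.factors)
        for s, t in self.paths:
            if s not in known or t not in known:
                raise ModelSpecError(f"structural path ({s}, {t}) names unknown factor")
            if s == t:
                raise ModelSpecError("self-loop in structural paths")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        order: list[str] = []
        perm: set[str] = set()
        temp: set[str] = set()
        out = {f: [t for s, t in self.paths if s == f] for f in self.factors}

        def visit(node: str) -> None:
            if node in perm:
                return
            if node in temp:
                raise ModelSpecError("structural paths contain a cycle")
            temp.add(node)
            for nxt in out[node]:
                visit(nxt)
            temp.discard(node)
            perm.add(node)
            order.append(node)

        for f in self.factors:
            visit(f)

    # -- derived layout ----------------------------------------------------
    @property
    def indicator_names(self) -> list[str]:
        return [i for f in self.factors for i in self.indicators[f]]

    @property
    def n_indicators(self) -> int:
        return len(self.indicator_names)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def factor_of(self) -> np.ndarray:
        """Factor index (into ``factors``) of every indicator."""
        idx = []
        for k, f in enumerate(self.factors):
            idx.extend([k] * len(self.indicators[f]))
        return np.asarray(idx, dtype=int)

    @property
    def free_loading_idx(self) -> np.ndarray:
        """Indicator indices whose loading is free (all but each first)."""
        out, pos = [], 0
        for f in self.factors:
            n = len(self.indicators[f])
            out.extend(range(pos + 1, pos + n))
            pos += n
        return np.asarray(out, dtype=int)

    @property
    def path_idx(self) -> list[tuple[int, int]]:
        fi = {f: k for k, f in enumerate(self.factors)}
        return [(fi[s], fi[t]) for s, t in self.paths]

    @property
    def block_sizes(self) -> dict[str, int]:
        p, k = self.n_indicators, self.n_factors
        return {
            "alpha": p,
            "lambda": p - k,
            "theta": p,
            "psi": k,
            "beta": len(self.paths),
        }

    @property
    def n_free(self) -> int:
        return sum(self.block_sizes.values())

    @property
    def param_names(self) -> list[str]:
        ind = self.indicator_names
        names = [f"alpha_{i}" for i in ind]
        names += [f"lambda_{ind[j]}" for j in self.free_loading_idx]
        names += [f"theta_{i}" for i in ind]
        names += [f"psi_{f}" for f in self.factors]
        names += [f"beta_{s}_{t}" for s, t in self.paths]
        return names

    @property
    def df(self) -> int:
        """Model degrees of freedom against the saturated mean+cov structure."""
        p = self.n_indicators
        return p * (p + 3) // 2 - self.n_free


def build_model_spec(config: dict) -> ModelSpec:
    """Build and validate a :class:`ModelSpec` from a plain mapping.

    ``config`` needs keys ``factors`` (list), ``indicators`` (mapping) and
    optionally ``paths`` (list of 2-lists/tuples).
    """
    factors = tuple(config["factors"])
    indicators = {f: tuple(config["indicators"][f]) for f in factors}
    paths = tuple((s, t) for s, t in config.get("paths", []))
    return ModelSpec(factors=factors, indicators=indicators, paths=paths)


def mediation_spec(
    indicators: dict[str, list[str]] | None = None,
) -> ModelSpec:
    """The default X -> M -> Y mediation model with three indicators each."""
    if indicators is None:
        indicators = {
            "X": ["x1", "x2", "x3"],
            "M": ["m1", "m2", "m3"],
            "Y": ["y1", "y2", "y3"],
        }
    return ModelSpec(
        factors=tuple(indicators),
        indicators={f: tuple(v) for f, v in indicators.items()},
        paths=(("X", "M"), ("X", "Y"), ("M", "Y"))
        if set(indicators) == {"X", "M", "Y"}
        else (),
    )


# ---------------------------------------------------------------------------
# Parameter vector
# ---------------------------------------------------------------------------


@dataclass
class ParameterVector:
    """Free parameters of the unmoderated model, grouped by block."""

    alpha: np.ndarray
    lam: np.ndarray
    theta: np.ndarray
    psi: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        for name in ("alpha", "lam", "theta", "psi", "beta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.theta <= 0) or np.any(self.psi <= 0):
            raise ValueError("variance parameters must be strictly positive")

    def to_array(self) -> np.ndarray:
        return np.concatenate([self.alpha, self.lam, self.theta, self.psi, self.beta])

    @classmethod
    def from_array(cls, x: np.ndarray, spec: ModelSpec) -> "ParameterVector":
        return cls(**split_blocks(np.asarray(x, dtype=float), spec))

    def __len__(self) -> int:
        return self.to_array().size


def split_blocks(x: np.ndarray, spec: ModelSpec) -> dict[str, np.ndarray]:
    """Split a flat (..., q) parameter array into named blocks."""
    sizes = spec.block_sizes
    out, pos = {}, 0
    for name, n in sizes.items():
        out["lam" if name == "lambda" else name] = x[..., pos : pos + n]
        pos += n
    return out


# ---------------------------------------------------------------------------
# Implied moments and casewise likelihood / scores (batched)
# ---------------------------------------------------------------------------


def _build_lambda(spec: ModelSpec, lam: np.ndarray) -> np.ndarray:
    """Loading matrix (..., p, k): fixed unit first loadings, free elsewhere."""
    p, k = spec.n_indicators, spec.n_factors
    batch = lam.shape[:-1]
    Lam = np.zeros(batch + (p, k))
    fac = spec.factor_of
    first = np.ones(p, dtype=bool)
    first[spec.free_loading_idx] = False
    Lam[..., first, fac[first]] = 1.0
    free = spec.free_loading_idx
    Lam[..., free, fac[free]] = lam
    return Lam


def _reduced_form(
    spec: ModelSpec, psi: np.ndarray, beta: np.ndarray, nu: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (A, Phi, m): total-effect matrix, latent covariance and means.

    ``A = (I - B)^{-1}`` where ``B`` holds the path coefficients; since the
    graph is acyclic, ``B`` is nilpotent and ``A = I + B + B^2 + ...``.
    """
    k = spec.n_factors
    batch = np.broadcast_shapes(psi.shape[:-1], beta.shape[:-1] if beta.size else ())
    B = np.zeros(batch + (k, k))
    for j, (s, t) in enumerate(spec.path_idx):
        B[..., t, s] = beta[..., j]
    A = np.zeros_like(B)
    A[...] = np.eye(k)
    term = np.eye(k)
    for _ in range(k - 1):
        term = B @ term if term.ndim == B.ndim else np.einsum("...ij,jk->...ik", B, term)
        A = A + term
    Phi = A * psi[..., None, :] @ np.swapaxes(A, -1, -2)
    if nu is None:
        m = np.zeros(batch + (k,))
    else:
        m = np.einsum("...ij,...j->...i", A, np.broadcast_to(nu, batch + (k,)))
    return A, Phi, m


def implied_moments(
    theta: ParameterVector | dict | np.ndarray,
    spec: ModelSpec,
    nu: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix.

    Accepts a :class:`ParameterVector`, a dict of blocks, or a flat array;
    blocks may carry arbitrary leading batch dimensions (e.g. one parameter
    set per person).  Returns ``(mu, sigma)``.
    """
    b = _as_blocks(theta, spec)
    if np.any(b["theta"] <= 0) or np.any(b["psi"] <= 0):
        raise ValueError("variance parameters must be strictly positive")
    Lam = _build_lambda(spec, b["lam"])
    _, Phi, m = _reduced_form(spec, b["psi"], b["beta"], nu)
    sigma = Lam @ Phi @ np.swapaxes(Lam, -1, -2)
    p = spec.n_indicators
    idx = np.arange(p)
    sigma[..., idx, idx] += b["theta"]
    mu = b["alpha"] + np.einsum("...jk,...k->...j", Lam, m)
    return mu, sigma


def _as_blocks(theta, spec: ModelSpec) -> dict[str, np.ndarray]:
    if isinstance(theta, ParameterVector):
        return {
            "alpha": theta.alpha,
            "lam": theta.lam,
            "theta": theta.theta,
            "psi": theta.psi,
            "beta": theta.beta,
        }
    if isinstance(theta, dict):
        return {k: np.asarray(v, dtype=float) for k, v in theta.items()}
    return split_blocks(np.asarray(theta, dtype=float), spec)


def loglik_and_scores(
    y: np.ndarray,
    theta,
    spec: ModelSpec,
    nu: np.ndarray | None = None,
    want_scores: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Casewise MVN log-likelihood and its analytic gradient.

    Parameters
    ----------
    y
        Data, shape ``(N, p)``.
    theta
        Parameter blocks; each block broadcasts against ``(..., N, block)``,
        so shared parameters of shape ``(block,)``, person-specific of shape
        ``(N, block)``, and chain-batched of shape ``(C, N, block)`` all work.
    nu
        Optional latent-mean intercepts (identification default: zero).

    Returns
    -------
    ll : (..., N) casewise log-likelihoods.
    scores : (..., N, q) casewise gradients on the natural parameter scale,
        columns ordered like ``spec.param_names`` (``None`` if not requested).
        When latent means are supplied, ``k`` extra trailing columns hold the
        gradient with respect to ``nu``.
    """
    b = _as_blocks(theta, spec)
    y = np.asarray(y, dtype=float)
    N, p = y.shape
    k = spec.n_factors

    Lam = _build_lambda(spec, b["lam"])
    A, Phi, m = _reduced_form(spec, b["psi"], b["beta"], nu)
    batch = np.broadcast_shapes(
        b["alpha"].shape[:-1], Lam.shape[:-2], Phi.shape[:-2], b["theta"].shape[:-1]
    )
    # ensure the person axis exists so casewise quantities line up with y
    if len(batch) == 0 or batch[-1] != N:
        batch = batch + (N,)
    Lam = np.broadcast_to(Lam, batch + (p, k))
    Phi = np.broadcast_to(Phi, batch + (k, k))
    A = np.broadcast_to(A, batch + (k, k))
    m = np.broadcast_to(m, batch + (k,))
    alpha = np.broadcast_to(b["alpha"], batch + (p,))
    th = np.broadcast_to(b["theta"], batch + (p,))

    with np.errstate(over="ignore"):
        sigma = Lam @ Phi @ np.swapaxes(Lam, -1, -2)
    sigma = sigma + th[..., None] * np.eye(p)
    mu = alpha + np.einsum("...jk,...k->...j", Lam, m)

    L = np.linalg.cholesky(sigma)  # raises LinAlgError if not PD
    logdet = 2.0 * np.log(np.diagonal(L, axis1=-2, axis2=-1)).sum(axis=-1)
    P = np.linalg.inv(sigma)
    r = y - mu
    q = np.einsum("...ij,...j->...i", P, r)
    quad = np.einsum("...j,...j->...", r, q)
    ll = -0.5 * (p * LOG2PI + logdet + quad)

    if not want_scores:
        return ll, None

    G = 0.5 * (q[..., :, None] * q[..., None, :] - P)
    s_alpha = q
    LamPhi = Lam @ Phi
    GLamPhi = G @ LamPhi
    s_lam_full = 2.0 * GLamPhi + q[..., :, None] * m[..., None, :]
    free = spec.free_loading_idx
    s_lam = s_lam_full[..., free, spec.factor_of[free]]
    s_theta = np.diagonal(G, axis1=-2, axis2=-1)
    W = np.swapaxes(Lam, -1, -2) @ G @ Lam
    AtWA = np.swapaxes(A, -1, -2) @ W @ A
    s_psi = np.diagonal(AtWA, axis1=-2, axis2=-1)
    pieces = [s_alpha, s_lam, s_theta, s_psi]
    if spec.paths:
        PhiWA = Phi @ W @ A
        qLamA = np.einsum("...j,...jk,...kl->...l", q, Lam, A)
        s_beta = np.stack(
            [
                2.0 * PhiWA[..., s, t] + qLamA[..., t] * m[..., s]
                for s, t in spec.path_idx
            ],
            axis=-1,
        )
        pieces.append(s_beta)
    if nu is not None:
        qLamA = np.einsum("...j,...jk,...kl->...l", q, Lam, A)
        pieces.append(qLamA)
    scores = np.concatenate(pieces, axis=-1)
    return ll, scores


def total_loglik_and_grad(
    x: np.ndarray, y: np.ndarray, spec: ModelSpec
) -> tuple[float, np.ndarray]:
    """Summed log-likelihood and gradient at a shared flat parameter vector."""
    ll, sc = loglik_and_scores(y, x, spec)
    return float(ll.sum()), sc.sum(axis=0)


def total_hessian_fd(
    x: np.ndarray, y: np.ndarray, spec: ModelSpec, rel_step: float = 1e-5
) -> np.ndarray:
    """Hessian of the total log-likelihood by central differences of the
    analytic gradient; symmetrised."""
    x = np.asarray(x, dtype=float)
    q = x.size
    H = np.empty((q, q))
    for j in range(q):
        h = rel_step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        _, gp = total_loglik_and_grad(xp, y, spec)
        _, gm = total_loglik_and_grad(xm, y, spec)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Maximum likelihood fit
# ---------------------------------------------------------------------------


@dataclass
class MLFit:
    """Result of a maximum-likelihood fit."""

    theta_hat: ParameterVector
    loglik: float
    converged: bool
    n_obs: int
    vcov: np.ndarray | None
    spec: ModelSpec
    grad_norm: float
    n_iter: int

    @property
    def estimates(self) -> pd.Series:
        return pd.Series(self.theta_hat.to_array(), index=self.spec.param_names)

    @property
    def se(self) -> pd.Series:
        if self.vcov is None:
            return pd.Series(np.nan, index=self.spec.param_names)
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.spec.param_names)

    def parameter_table(self) -> pd.DataFrame:
        est, se = self.estimates, self.se
        z = est / se
        pval = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({"estimate": est, "se": se, "z": z, "p": pval})


def _var_slice(spec: ModelSpec) -> np.ndarray:
    """Boolean mask of variance-type entries of the flat parameter vector."""
    sizes = spec.block_sizes
    mask = np.zeros(spec.n_free, dtype=bool)
    pos = 0
    for name, n in sizes.items():
        if name in ("theta", "psi"):
            mask[pos : pos + n] = True
        pos += n
    return mask


def _to_unconstrained(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    u = x.copy()
    u[mask] = np.log(x[mask])
    return u


def _to_natural(u: np.ndarray, mask: np.ndarray) -> np.ndarray:
    x = u.copy()
    x[mask] = np.exp(u[mask])
    return x


def start_values(y: np.ndarray, spec: ModelSpec) -> ParameterVector:
    """Deterministic starting values: indicator means, unit loadings, half
    variances for residuals, half the fixed-indicator variance for psi,
    zero structural coefficients."""
    y = np.asarray(y, dtype=float)
    v = y.var(axis=0)
    first = np.ones(spec.n_indicators, dtype=bool)
    first[spec.free_loading_idx] = False
    return ParameterVector(
        alpha=y.mean(axis=0),
        lam=np.ones(spec.n_indicators - spec.n_factors),
        theta=np.maximum(v / 2.0, 1e-3),
        psi=np.maximum(v[first] / 2.0, 1e-3),
        beta=np.zeros(len(spec.paths)),
    )


def fit_ml(
    data,
    spec: ModelSpec,
    start: ParameterVector | None = None,
    gtol: float = 1e-6,
    max_iter: int = 500,
) -> MLFit:
    """Fit the model by casewise multivariate-normal maximum likelihood.

    Variances are optimised on the log scale to enforce positivity; the fit
    is declared converged when the maximum absolute gradient entry (on the
    working scale) falls below ``gtol`` and no log-variance sits on the
    boundary (|log v| > 10, the Heywood analogue under this transform).
    """
    y = _coerce_data(data, spec)
    N = y.shape[0]
    if y.shape[1] != spec.n_indicators:
        raise ValueError("data has wrong number of indicator columns")
    if np.isnan(y).any():
        raise ValueError("missing values are not supported")
    if N <= spec.n_free:
        raise ValueError(
            f"N = {N} observations cannot identify {spec.n_free} free parameters"
        )
    if start is None:
        start = start_values(y, spec)
    mask = _var_slice(spec)
    u0 = _to_unconstrained(start.to_array(), mask)

    def negloglik(u):
        x = _to_natural(u, mask)
        try:
            ll, g = total_loglik_and_grad(x, y, spec)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(u)
        gu = g.copy()
        gu[mask] = g[mask] * x[mask]  # chain rule d/dlog v
        return -ll, -gu

    res = optimize.minimize(
        negloglik,
        u0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
    )
    u = res.x
    # Newton polish to drive the gradient to the contract tolerance
    n_polish = 0
    for _ in range(25):
        f, g = negloglik(u)
        if np.max(np.abs(g)) < gtol:
            break
        Hu = _fd_grad_jacobian(negloglik, u)
        try:
            step = np.linalg.solve(Hu, -g)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ in range(20):
            f2, _ = negloglik(u + t * step)
            if f2 <= f + 1e-12:
                break
            t *= 0.5
        else:
            break
        u = u + t * step
        n_polish += 1

    f, g = negloglik(u)
    grad_norm = float(np.max(np.abs(g)))
    x_hat = _to_natural(u, mask)
    boundary = bool(np.any(np.abs(u[mask]) > 10.0))
    converged = bool(grad_norm < gtol and not boundary and np.isfinite(f))

    vcov = None
    singular = False
    if np.isfinite(f):
        H = total_hessian_fd(x_hat, y, spec)
        try:
            vcov = np.linalg.inv(-H)
            if np.any(np.diag(vcov) <= 0):
                singular = True
        except np.linalg.LinAlgError:
            singular = True
    converged = converged and not singular

    return MLFit(
        theta_hat=ParameterVector.from_array(x_hat, spec),
        loglik=-f,
        converged=converged,
        n_obs=N,
        vcov=vcov,
        spec=spec,
        grad_norm=grad_norm,
        n_iter=int(res.nit) + n_polish,
    )


def _fd_grad_jacobian(fun, u, rel_step=1e-6):
    q = u.size
    J = np.empty((q, q))
    for j in range(q):
        h = rel_step * max(1.0, abs(u[j]))
        up, um = u.copy(), u.copy()
        up[j] += h
        um[j] -= h
        _, gp = fun(up)
        _, gm = fun(um)
        J[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (J + J.T)


def _coerce_data(data, spec: ModelSpec) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        cols = spec.indicator_names
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing indicator columns {missing}")
        return data[cols].to_numpy(dtype=float)
    return np.asarray(data, dtype=float)


# ---------------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------------


def saturated_loglik(y: np.ndarray) -> float:
    """Closed-form MVN log-likelihood at the sample mean and the biased
    (1/N) sample covariance."""
    y = np.asarray(y, dtype=float)
    N, p = y.shape
    S = np.cov(y, rowvar=False, bias=True)
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("sample covariance not positive definite")
    return float(-0.5 * N * (p * LOG2PI + logdet + p))


def _baseline_loglik(y: np.ndarray) -> tuple[float, int]:
    """Independence model: free means and variances, zero covariances."""
    y = np.asarray(y, dtype=float)
    N, p = y.shape
    v = y.var(axis=0)
    ll = float(-0.5 * N * (p * LOG2PI + np.log(v).sum() + p))
    df = p * (p + 3) // 2 - 2 * p
    return ll, df


@dataclass
class FitIndices:
    chisq: float
    df: int
    pvalue: float
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci90: tuple[float, float]

    def as_dict(self) -> dict:
        d = {
            "chisq": self.chisq,
            "df": self.df,
            "pvalue": self.pvalue,
            "cfi": self.cfi,
            "tli": self.tli,
            "rmsea": self.rmsea,
            "rmsea_ci90_lower": self.rmsea_ci90[0],
            "rmsea_ci90_upper": self.rmsea_ci90[1],
        }
        return d


def _ncp_bound(chisq: float, df: int, prob: float) -> float:
    """Noncentrality parameter lambda with ncx2.cdf(chisq, df, lambda)=prob."""
    if stats.chi2.cdf(chisq, df) < prob:
        return 0.0
    hi = max(chisq * 2.0, 10.0)
    while stats.ncx2.cdf(chisq, df, hi) > prob:
        hi *= 2.0
        if hi > 1e8:
            break
    return float(
        optimize.brentq(lambda l: stats.ncx2.cdf(chisq, df, l) - prob, 0.0, hi)
    )


def fit_indices(fit: MLFit, data) -> FitIndices:
    """Likelihood-ratio chi-square against the saturated model plus the
    standard incremental (CFI/TLI) and absolute (RMSEA, 90% CI) indices."""
    if not fit.converged:
        raise ValueError("fit did not converge; indices are undefined")
    y = _coerce_data(data, fit.spec)
    N = y.shape[0]
    ll_sat = saturated_loglik(y)
    chisq = max(2.0 * (ll_sat - fit.loglik), 0.0)
    df = fit.spec.df
    ll_b, df_b = _baseline_loglik(y)
    chisq_b = max(2.0 * (ll_sat - ll_b), 0.0)
    d = max(chisq - df, 0.0)
    d_b = max(chisq_b - df_b, 0.0)
    cfi = 1.0 - d / max(d, d_b, np.finfo(float).tiny)
    if df > 0 and df_b > 0 and chisq_b / df_b > 1.0:
        tli = ((chisq_b / df_b) - (chisq / df)) / ((chisq_b / df_b) - 1.0)
        tli = min(tli, 1.0)
    else:
        tli = 1.0
    if df > 0:
        pvalue = float(stats.chi2.sf(chisq, df))
        rmsea = float(np.sqrt(max(chisq - df, 0.0) / (df * N)))
        lo = np.sqrt(_ncp_bound(chisq, df, 0.95) / (df * N))
        hi = np.sqrt(_ncp_bound(chisq, df, 0.05) / (df * N))
    else:
        pvalue, rmsea, lo, hi = 1.0, 0.0, 0.0, 0.0
    return FitIndices(
        chisq=chisq,
        df=df,
        pvalue=pvalue,
        cfi=float(np.clip(cfi, 0.0, 1.0)),
        tli=float(tli),
        rmsea=rmsea,
        rmsea_ci90=(float(lo), float(hi)),
    )
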