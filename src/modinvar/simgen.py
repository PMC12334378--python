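"""Monte Carlo comparison of IPCR and Bayesian MNLFA.

The data-generating model is the stochastic moderated latent mediation
model: every free parameter of the three-construct mediation model follows
its own moderation regression gamma0 + gamma1*Z + eps_v on one standard
normal moderator, with the exponential link for variance-type parameters
and a heterogeneity residual eps_v ~ N(0, sigma_het^2) per moderator value.

The gamma0 population values are the moderated-factor-model posterior-mean
estimates of the worked example (three Likert-style indicators per
construct; see ``EMPIRICAL_GAMMA0``).  Effect size is operationalised as
the share of a parameter's total heterogeneity explained by the moderator,

    rho = Var(gamma1 Z) / (Var(gamma1 Z) + sigma_het^2),

with sigma_het fixed at the worked example's heterogeneity-SD estimates and
gamma1 = sign * sigma_het * sqrt(rho / (1 - rho)); rho = 0.2 / 0.5 / 0.8
for small / medium / large.  The exact numeric operationalisation in the
original study is not published in full; these defaults are explicit,
documented approximations and every population value can be overridden.

Estimates are always compared against the generating regression
coefficients (log scale for variance-type parameters).  Standard IPCR
reports natural-scale linear coefficients for variances, so part of its
reported bias for those parameters is the link mismatch -- deliberately so,
since that is how the three-step procedure is used in practice.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hmc import MCMCConfig
from .ipcr import iterated_ipcr, run_ipcr
from .mnlfa import (
    ModerationSpec,
    PriorSpec,
    build_moderated_model,
    is_variance_param,
    sample_posterior,
)
from .sem_core import ModelSpec, fit_ml, implied_moments, mediation_spec, split_blocks

# ---------------------------------------------------------------------------
# Population values
# ---------------------------------------------------------------------------

#: Worked-example posterior means: measurement model (moderation intercepts;
#: log scale for residual variances) and structural model.
EMPIRICAL_GAMMA0 = {
    "alpha_x1": 2.31, "alpha_x2": 2.98, "alpha_x3": 3.33,
    "alpha_m1": 1.47, "alpha_m2": 1.59, "alpha_m3": 1.52,
    "alpha_y1": 4.16, "alpha_y2": 3.76, "alpha_y3": 4.12,
    "lambda_x2": 0.85, "lambda_x3": 1.11,
    "lambda_m2": 0.72, "lambda_m3": 1.06,
    "lambda_y2": 1.18, "lambda_y3": 1.40,
    "theta_x1": 0.64, "theta_x2": 0.86, "theta_x3": 0.60,
    "theta_m1": 0.27, "theta_m2": 0.64, "theta_m3": 0.39,
    "theta_y1": 0.41, "theta_y2": 0.55, "theta_y3": 0.37,
    "psi_X": 0.52, "psi_M": 0.28, "psi_Y": 0.19,
    "beta_X_M": 0.24, "beta_X_Y": 0.11, "beta_M_Y": -0.13,
}

#: Worked-example moderation-slope posterior means (signs drive the
#: direction of the injected moderation).
EMPIRICAL_GAMMA1 = {
    "alpha_x1": 0.26, "alpha_x2": 0.25, "alpha_x3": 0.25,
    "alpha_m1": 0.24, "alpha_m2": 0.19, "alpha_m3": 0.17,
    "alpha_y1": -0.33, "alpha_y2": -0.32, "alpha_y3": -0.38,
    "lambda_x2": -0.10, "lambda_x3": -0.05,
    "lambda_m2": -0.13, "lambda_m3": 0.00,
    "lambda_y2": -0.02, "lambda_y3": -0.08,
    "theta_x1": 0.09, "theta_x2": 0.01, "theta_x3": -0.19,
    "theta_m1": 0.33, "theta_m2": 0.20, "theta_m3": 0.21,
    "theta_y1": 0.08, "theta_y2": -0.05, "theta_y3": 0.16,
    "psi_X": -0.01, "psi_M": 0.29, "psi_Y": 0.35,
    "beta_X_M": 0.09, "beta_X_Y": 0.02, "beta_M_Y": -0.06,
}

#: Worked-example heterogeneity-SD posterior means.
EMPIRICAL_SIGMA_HET = {
    "alpha_x1": 0.05, "alpha_x2": 0.05, "alpha_x3": 0.09,
    "alpha_m1": 0.04, "alpha_m2": 0.04, "alpha_m3": 0.05,
    "alpha_y1": 0.07, "alpha_y2": 0.05, "alpha_y3": 0.07,
    "lambda_x2": 0.07, "lambda_x3": 0.06,
    "lambda_m2": 0.18, "lambda_m3": 0.22,
    "lambda_y2": 0.12, "lambda_y3": 0.16,
    "theta_x1": 0.08, "theta_x2": 0.06, "theta_x3": 0.10,
    "theta_m1": 0.32, "theta_m2": 0.10, "theta_m3": 0.27,
    "theta_y1": 0.30, "theta_y2": 0.08, "theta_y3": 0.55,
    "psi_X": 0.07, "psi_M": 0.61, "psi_Y": 0.13,
    "beta_X_M": 0.05, "beta_X_Y": 0.06, "beta_M_Y": 0.07,
}

EFFECT_SHARES = {"small": 0.2, "medium": 0.5, "large": 0.8}


@dataclass
class GammaSet:
    gamma0: float
    gamma1: float
    sigma_het: float

    def __post_init__(self) -> None:
        if self.sigma_het < 0:
            raise ValueError("sigma_het must be >= 0")


@dataclass
class PopulationParameters:
    """Generating moderation regressions for every free parameter.

    Variance-type gamma0 live on the log scale (exponential link); the
    moderator is standard normal."""

    gammas: dict[str, GammaSet]
    spec: ModelSpec = field(default_factory=mediation_spec)

    def __post_init__(self) -> None:
        missing = set(self.spec.param_names) - set(self.gammas)
        if missing:
            raise ValueError(f"population misses parameters: {sorted(missing)}")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        names = self.spec.param_names
        g0 = np.array([self.gammas[n].gamma0 for n in names])
        g1 = np.array([self.gammas[n].gamma1 for n in names])
        sd = np.array([self.gammas[n].sigma_het for n in names])
        return g0, g1, sd

    def provenance(self) -> dict:
        return {
            n: {"gamma0": g.gamma0, "gamma1": g.gamma1, "sigma_het": g.sigma_het}
            for n, g in self.gammas.items()
        }


def default_population(
    effect_size: str,
    spec: ModelSpec | None = None,
    shares: dict[str, float] | None = None,
    overrides: dict | None = None,
) -> PopulationParameters:
    """Population values for a named effect size (small/medium/large).

    ``overrides`` (mapping parameter -> {gamma0, gamma1, sigma_het}) allows
    loading an external population table verbatim."""
    shares = shares or EFFECT_SHARES
    if effect_size not in shares:
        raise ValueError(
            f"unknown effect size {effect_size!r}; expected one of {sorted(shares)}"
        )
    spec = spec or mediation_spec()
    rho = shares[effect_size]
    factor = np.sqrt(rho / (1.0 - rho))
    gammas = {}
    for n in spec.param_names:
        sd = EMPIRICAL_SIGMA_HET[n]
        sign = np.sign(EMPIRICAL_GAMMA1[n]) or 1.0
        gammas[n] = GammaSet(
            gamma0=EMPIRICAL_GAMMA0[n], gamma1=float(sign * sd * factor), sigma_het=sd
        )
    for n, d in (overrides or {}).items():
        gammas[n] = GammaSet(**d)
    return PopulationParameters(gammas=gammas, spec=spec)


# ---------------------------------------------------------------------------
# Data generation
# ---------------------------------------------------------------------------


def generate_dataset(
    pop: PopulationParameters, n: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (indicators, moderator) from the stochastic moderated model.

    Draws z_i ~ N(0,1); one heterogeneity residual per parameter per unique
    moderator value (all unique with a continuous moderator); forms
    person-specific parameters through the links; then samples latent
    variables and indicators from the implied person-specific moments."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    spec = pop.spec
    g0, g1, sd = pop.arrays()
    z = rng.standard_normal(n)
    eps = rng.standard_normal((n, len(g0))) * sd[None, :]
    eta = g0[None, :] + g1[None, :] * z[:, None] + eps
    theta = eta.copy()
    var_cols = np.array([is_variance_param(nm) for nm in spec.param_names])
    theta[:, var_cols] = np.exp(eta[:, var_cols])
    assert np.all(theta[:, var_cols] > 0)
    mu, sigma = implied_moments(split_blocks(theta, spec), spec)
    L = np.linalg.cholesky(sigma)
    y = mu + np.einsum("njk,nk->nj", L, rng.standard_normal((n, spec.n_indicators)))
    return y, z


# ---------------------------------------------------------------------------
# Conditions and metrics
# ---------------------------------------------------------------------------

METHODS = (
    "ipcr_standard",
    "ipcr_iterated",
    "bmnlfa_deterministic",
    "bmnlfa_stochastic",
)

PARAM_TYPES = ("alpha", "lambda", "theta", "psi", "beta")


@dataclass
class SimCondition:
    method: str
    n: int
    effect_size: str
    prior_style: str = "weakly_informative"
    n_rep: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.prior_style not in ("weakly_informative", "diffuse"):
            raise ValueError("prior_style must be weakly_informative or diffuse")
        if self.prior_style == "diffuse" and not self.method.startswith("bmnlfa"):
            raise ValueError("diffuse priors apply to BMNLFA only")

    @property
    def label(self) -> str:
        tag = f"{self.method}_n{self.n}_{self.effect_size}"
        if self.prior_style == "diffuse":
            tag += "_diffuse"
        return tag


def condition_grid(
    n_rep: int = 200,
    include_diffuse: bool = False,
    sample_sizes=(100, 150, 200, 300, 500),
    effect_sizes=("small", "medium", "large"),
) -> list[SimCondition]:
    """The fully crossed design: 2 method families x 5 sample sizes x
    3 effect sizes x 2 variants = 60 cells (plus 30 diffuse-prior cells
    when enabled)."""
    grid = [
        SimCondition(method=m, n=n, effect_size=e, n_rep=n_rep)
        for m in METHODS
        for n in sample_sizes
        for e in effect_sizes
    ]
    if include_diffuse:
        grid += [
            SimCondition(
                method=m, n=n, effect_size=e, prior_style="diffuse", n_rep=n_rep
            )
            for m in ("bmnlfa_deterministic", "bmnlfa_stochastic")
            for n in sample_sizes
            for e in effect_sizes
        ]
    return grid


@dataclass
class SimMetrics:
    condition: SimCondition
    n_converged: int
    n_total: int
    rpeb: dict  # (type, coef) -> averaged rpeb in percent, or None
    rpeb_abs: dict  # (type, coef) -> average of |per-parameter rpeb|
    coverage: dict
    power: dict
    per_parameter: pd.DataFrame | None = None

    @property
    def convergence_rate(self) -> float:
        return self.n_converged / self.n_total

    def as_dict(self) -> dict:
        return {
            "label": self.condition.label,
            "convergence_rate": self.convergence_rate,
            "n_converged": self.n_converged,
            "rpeb": {f"{t}.{c}": v for (t, c), v in self.rpeb.items()},
            "rpeb_abs": {f"{t}.{c}": v for (t, c), v in self.rpeb_abs.items()},
            "coverage": {f"{t}.{c}": v for (t, c), v in self.coverage.items()},
            "power": {f"{t}.{c}": v for (t, c), v in self.power.items()},
        }


def _param_type(name: str) -> str:
    return name.split("_")[0]


def compute_metrics(
    truth: PopulationParameters,
    estimates: list[pd.DataFrame],
    condition: SimCondition | None = None,
    min_converged_frac: float = 0.5,
) -> SimMetrics:
    """Aggregate replication estimates into rpeb / coverage / power.

    ``estimates``: one frame per converged replication with index =
    parameter names and columns gamma0, gamma1, ci0_low/high, ci1_low/high.
    rpeb = 100 * mean((estimate - truth) / truth) per parameter, averaged
    within parameter type; parameters with zero truth are excluded from
    rpeb (logged in the per-parameter table).  Metrics require more than
    ``min_converged_frac`` of the nominal replications (the >100-of-200
    rule, scaled)."""
    condition = condition or SimCondition("ipcr_standard", 0, "small", n_rep=0)
    n_total = condition.n_rep or len(estimates)
    n_conv = len(estimates)
    names = truth.spec.param_names
    g0, g1, _sd = truth.arrays()
    truth_map = {"gamma0": dict(zip(names, g0)), "gamma1": dict(zip(names, g1))}
    rpeb, rpeb_abs, coverage, power = {}, {}, {}, {}
    per_param = None
    if n_conv > min_converged_frac * n_total:
        rows = []
        for n in names:
            for coef in ("gamma0", "gamma1"):
                tv = truth_map[coef][n]
                est = np.array([df.loc[n, coef] for df in estimates])
                lo = np.array([df.loc[n, f"ci{coef[-1]}_low"] for df in estimates])
                hi = np.array([df.loc[n, f"ci{coef[-1]}_high"] for df in estimates])
                r = 100.0 * np.mean((est - tv) / tv) if tv != 0 else np.nan
                rows.append(
                    {
                        "parameter": n,
                        "coef": coef,
                        "type": _param_type(n),
                        "truth": tv,
                        "mean_estimate": est.mean(),
                        "rpeb": r,
                        "coverage": float(np.mean((lo <= tv) & (tv <= hi))),
                        "power": float(np.mean((lo > 0) | (hi < 0)))
                        if coef == "gamma1"
                        else np.nan,
                    }
                )
        per_param = pd.DataFrame(rows)
        for t in PARAM_TYPES:
            for coef in ("gamma0", "gamma1"):
                sub = per_param[(per_param["type"] == t) & (per_param["coef"] == coef)]
                valid = sub["rpeb"].dropna()
                rpeb[(t, coef)] = float(valid.mean()) if len(valid) else None
                rpeb_abs[(t, coef)] = (
                    float(valid.abs().mean()) if len(valid) else None
                )
                coverage[(t, coef)] = float(sub["coverage"].mean())
                if coef == "gamma1":
                    power[(t, coef)] = float(sub["power"].mean())
    return SimMetrics(
        condition=condition,
        n_converged=n_conv,
        n_total=n_total,
        rpeb=rpeb,
        rpeb_abs=rpeb_abs,
        coverage=coverage,
        power=power,
        per_parameter=per_param,
    )


# ---------------------------------------------------------------------------
# Fitting one replication per method
# ---------------------------------------------------------------------------


def _ipcr_estimates(table) -> pd.DataFrame:
    return table.table[
        ["gamma0", "gamma1", "ci0_low", "ci0_high", "ci1_low", "ci1_high"]
    ].copy()


def fit_replication(
    y: np.ndarray,
    z: np.ndarray,
    spec: ModelSpec,
    method: str,
    prior_style: str = "weakly_informative",
    mcmc: MCMCConfig | None = None,
) -> tuple[bool, pd.DataFrame | None]:
    """Fit one simulated dataset with one method.

    Returns (converged, estimates); estimates carry gamma0/gamma1 point
    estimates and 95% intervals per free parameter.  IPCR convergence is
    the ML flag (plus the iteration flag for the iterated variant); BMNLFA
    convergence is the split-R-hat / divergence rule."""
    if method.startswith("ipcr"):
        try:
            fit = fit_ml(y, spec)
        except (np.linalg.LinAlgError, ValueError):
            return False, None
        if not fit.converged:
            return False, None
        try:
            with warnings.catch_warnings():
                # the simulated moderator is standard normal by design
                warnings.simplefilter("ignore", UserWarning)
                if method == "ipcr_standard":
                    table = run_ipcr(fit, y, z)
                else:
                    table = iterated_ipcr(fit, y, spec, z)
        except (np.linalg.LinAlgError, ValueError):
            return False, None
        if not table.converged:
            return False, None
        return True, _ipcr_estimates(table)

    stochastic = method == "bmnlfa_stochastic"
    mod = ModerationSpec.configural(spec, stochastic=stochastic)
    priors = (
        PriorSpec.diffuse(spec)
        if prior_style == "diffuse"
        else PriorSpec.default(spec)
    )
    model = build_moderated_model(spec, mod, priors)
    mcmc = mcmc or MCMCConfig(chains=2, iterations=1000)
    post = sample_posterior(model, y, z, mcmc)
    rows = []
    for n in spec.param_names:
        g0 = post.get(f"gamma0[{n}]").ravel()
        g1 = post.get(f"gamma1[{n}]").ravel()
        rows.append(
            pd.Series(
                {
                    "gamma0": g0.mean(),
                    "gamma1": g1.mean(),
                    "ci0_low": np.quantile(g0, 0.025),
                    "ci0_high": np.quantile(g0, 0.975),
                    "ci1_low": np.quantile(g1, 0.025),
                    "ci1_high": np.quantile(g1, 0.975),
                },
                name=n,
            )
        )
    return post.converged(), pd.DataFrame(rows)


def run_condition(
    cond: SimCondition,
    master_seed: int = 0,
    mcmc: MCMCConfig | None = None,
    pop: PopulationParameters | None = None,
) -> SimMetrics:
    """Run all replications of one condition and aggregate the metrics."""
    spec = mediation_spec()
    pop = pop or default_population(cond.effect_size, spec)
    estimates = []
    ss = np.random.SeedSequence([master_seed, zlib.crc32(cond.label.encode()) % (2**31)])
    child_seeds = ss.spawn(cond.n_rep)
    for r in range(cond.n_rep):
        rng = np.random.default_rng(child_seeds[r])
        y, z = generate_dataset(pop, cond.n, rng)
        rep_mcmc = None
        if mcmc is not None:
            rep_mcmc = MCMCConfig(
                chains=mcmc.chains,
                iterations=mcmc.iterations,
                warmup_frac=mcmc.warmup_frac,
                seed=int(rng.integers(2**31)),
                target_accept=mcmc.target_accept,
                max_leapfrog=mcmc.max_leapfrog,
            )
        ok, est = fit_replication(
            y, z, spec, cond.method, cond.prior_style, rep_mcmc
        )
        if ok and est is not None:
            estimates.append(est)
    return compute_metrics(pop, estimates, cond)


def run_study(
    grid: list[SimCondition],
    out_dir: str | Path | None = None,
    master_seed: int = 0,
    mcmc: MCMCConfig | None = None,
) -> list[SimMetrics]:
    """Run the full grid; per-condition metrics (and JSON audit files when
    ``out_dir`` is given).  Individual replication failures are recorded as
    non-convergence, never fatal."""
    results = []
    for cond in grid:
        metrics = run_condition(cond, master_seed=master_seed, mcmc=mcmc)
        results.append(metrics)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            with open(out / f"{cond.label}.json", "w") as fh:
                json.dump(metrics.as_dict(), fh, indent=1)
            if metrics.per_parameter is not None:
                metrics.per_parameter.to_csv(
                    out / f"{cond.label}_per_parameter.csv", index=False
                )
    if out_dir is not None:
        with open(Path(out_dir) / "population_provenance.json", "w") as fh:
            json.dump(
                {
                    e: default_population(e).provenance()
                    for e in ("small", "medium", "large")
                },
                fh,
                indent=1,
            )
    return results
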