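"""Sequential measurement- and structural-invariance testing.

Measurement invariance (MI) across a continuous moderator is tested per
construct on unidimensional factor models, walking the conventional ladder
configural -> weak (loadings) -> strong (intercepts) -> strict (residual
variances).  Two engines are provided:

* IPCR: all measurement parameters' IPCs are regressed on the moderator at
  once; a level fails when the relevant slopes are significant.  A common,
  equally-sized intercept drift is *not* a strong-MI violation (with latent
  means fixed at zero, a latent-mean shift expresses itself as parallel
  intercept moderation), so equality of intercept slopes is judged by the
  confidence-interval overlap heuristic.
* Bayesian MNLFA: each level applies approximate-invariance priors
  N(0, .01) to the level's moderation slopes and half-normal(.01) to their
  heterogeneity SDs; each level is checked against the moderated saturated
  model (deviance PPMC) and compared by PSIS-LOO.

After MI, structural invariance (SI) is tested by moderating the latent
regressions beta1-beta3 and the latent variances, with flagged
(non-invariant) measurement parameters kept moderated: partial invariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmc import MCMCConfig
from .ipcr import IPCRegressionTable, iterated_ipcr, run_ipcr
from .mnlfa import (
    ModerationSpec,
    PosteriorDraws,
    PriorSpec,
    build_moderated_model,
    sample_posterior,
)
from .model_eval import (
    compare_loo,
    deviance_ppmc,
    fit_moderated_saturated,
    loo_from_posterior,
)
from .sem_core import MLFit, ModelSpec, _coerce_data, fit_ml

MI_LEVELS = ("configural", "weak", "strong", "strict")


def constraint_set(level: str, spec: ModelSpec) -> list[str]:
    """Measurement parameters whose moderation is constrained at a level.

    The sets are nested: weak (loadings) < strong (+ intercepts) < strict
    (+ residual variances).  The configural model constrains nothing.
    """
    if level not in MI_LEVELS:
        raise ValueError(f"unknown MI level {level!r}")
    out: list[str] = []
    if level in ("weak", "strong", "strict"):
        out += [n for n in spec.param_names if n.startswith("lambda_")]
    if level in ("strong", "strict"):
        out += [n for n in spec.param_names if n.startswith("alpha_")]
    if level == "strict":
        out += [n for n in spec.param_names if n.startswith("theta_")]
    return out


def unidimensional_spec(spec: ModelSpec, factor: str) -> ModelSpec:
    """Single-construct measurement model derived from the full spec."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ModelSpec(
            factors=(factor,),
            indicators={factor: tuple(spec.indicators[factor])},
            paths=(),
        )


@dataclass
class ConstructVerdict:
    construct: str
    level: str
    flagged: list[str] = field(default_factory=list)
    partial_invariance: bool = False
    evidence: pd.DataFrame | None = None


@dataclass
class InvarianceVerdict:
    constructs: dict[str, ConstructVerdict]
    method: str

    def level(self, construct: str) -> str:
        return self.constructs[construct].level

    def flagged_params(self, spec: ModelSpec) -> list[str]:
        """Flagged measurement parameters mapped to full-model names."""
        out = []
        for v in self.constructs.values():
            out.extend(v.flagged)
        return [n for n in spec.param_names if n in set(out)]

    def min_level(self) -> str:
        order = {lv: i for i, lv in enumerate(MI_LEVELS)}
        return min(
            (v.level for v in self.constructs.values()), key=lambda lv: order[lv]
        )


# ---------------------------------------------------------------------------
# CI-overlap heuristic
# ---------------------------------------------------------------------------


def check_equal_intercept_moderation(
    estimates: np.ndarray, ci95: list[tuple[float, float]]
) -> tuple[bool, str]:
    """True iff every pair of 95% intervals overlaps.

    Used to decide whether significantly moderated intercepts drift
    *equally* (a latent-mean moderation, compatible with strong MI) or
    differentially (a strong-MI violation).  Returns the verdict plus a
    rationale listing non-overlapping pairs.
    """
    if len(ci95) < 2:
        raise ValueError("need at least two items to compare")
    bad = []
    for i in range(len(ci95)):
        for j in range(i + 1, len(ci95)):
            lo_i, hi_i = ci95[i]
            lo_j, hi_j = ci95[j]
            if lo_i > hi_j or lo_j > hi_i:
                bad.append((i, j))
    if bad:
        pairs = ", ".join(f"items {i} and {j}" for i, j in bad)
        return False, f"non-overlapping 95% CIs: {pairs}"
    return True, "all pairwise 95% CIs overlap"


# ---------------------------------------------------------------------------
# IPCR MI workflow
# ---------------------------------------------------------------------------


def run_ipcr_mi(
    data, z: np.ndarray, spec: ModelSpec, alpha: float = 0.05
) -> InvarianceVerdict:
    """Per-construct MI ladder from a single IPC regression each.

    Level rules: weak fails if any loading slope is significant at
    ``alpha``; strong fails if intercept slopes are significant *and*
    differ by the CI-overlap rule; strict fails if any residual-variance
    slope is significant.
    """
    data = _coerce_data(data, spec)
    verdicts: dict[str, ConstructVerdict] = {}
    for k, factor in enumerate(spec.factors):
        uspec = unidimensional_spec(spec, factor)
        cols = [spec.indicator_names.index(i) for i in uspec.indicator_names]
        y_c = data[:, cols]
        fit = fit_ml(y_c, uspec)
        if not fit.converged:
            raise RuntimeError(f"ML fit for construct {factor} did not converge")
        table = run_ipcr(fit, y_c, z).table

        level = "strict"
        flagged: list[str] = []
        lam = table[table.index.str.startswith("lambda_")]
        if (lam["p1"] < alpha).any():
            level = "configural"
            flagged += list(lam.index[lam["p1"] < alpha])
        if level != "configural":
            al = table[table.index.str.startswith("alpha_")]
            sig = al["p1"] < alpha
            if sig.any():
                ok, _why = check_equal_intercept_moderation(
                    al["gamma1"].to_numpy(),
                    list(zip(al["ci1_low"], al["ci1_high"])),
                )
                if not ok:
                    level = "weak"
                    flagged += list(al.index[sig])
        if level == "strict":
            th = table[table.index.str.startswith("theta_")]
            sig = th["p1"] < alpha
            if sig.any():
                level = "strong"
                flagged += list(th.index[sig])
        verdicts[factor] = ConstructVerdict(
            construct=factor,
            level=level,
            flagged=flagged,
            partial_invariance=bool(flagged),
            evidence=table,
        )
    return InvarianceVerdict(constructs=verdicts, method="ipcr")


# ---------------------------------------------------------------------------
# MNLFA MI workflow
# ---------------------------------------------------------------------------


def _mnlfa_level_priors(level: str, uspec: ModelSpec) -> PriorSpec:
    priors = PriorSpec.default(uspec)
    cons = constraint_set(level, uspec)
    if cons:
        priors = priors.with_approximate_invariance(cons)
    return priors


def fit_mi_level(
    y_c, z, uspec: ModelSpec, level: str, cfg: MCMCConfig, stochastic: bool = True
) -> PosteriorDraws:
    """Fit one MI level of the unidimensional MNLFA model."""
    mod = ModerationSpec.configural(uspec, stochastic=stochastic)
    # latent means join the moderation at the strong step (intercept drifts
    # are then expressed at the latent level)
    mod.moderate_latent_means = level in ("strong", "strict")
    priors = _mnlfa_level_priors(level, uspec)
    model = build_moderated_model(uspec, mod, priors)
    return sample_posterior(model, y_c, z, cfg)


def run_mnlfa_mi(
    data,
    z: np.ndarray,
    spec: ModelSpec,
    cfg: MCMCConfig | None = None,
    stochastic: bool = True,
    ppp_threshold: float = 0.95,
    max_draws: int = 600,
) -> tuple[InvarianceVerdict, pd.DataFrame]:
    """Stepwise Bayesian approximate-invariance testing per construct.

    Every level is evaluated against the moderated saturated model by the
    deviance PPMC and by PSIS-LOO; the selected level is the one with the
    highest elpd_loo unless its PPMC signals substantial misfit, in which
    case the deepest non-misfitting level is retained.  Returns the verdict
    and a level table with the evaluation columns.
    """
    cfg = cfg or MCMCConfig()
    data = _coerce_data(data, spec)
    rows = []
    verdicts: dict[str, ConstructVerdict] = {}
    for factor in spec.factors:
        uspec = unidimensional_spec(spec, factor)
        cols = [spec.indicator_names.index(i) for i in uspec.indicator_names]
        y_c = data[:, cols]
        sat = fit_moderated_saturated(y_c, z, cfg)
        sat_loo = loo_from_posterior(sat, y_c, max_draws=max_draws)
        rows.append(
            {
                "construct": factor,
                "model": "saturated",
                "loglik": np.nan,
                "delta_dev": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "ppp": np.nan,
                "elpd_loo": sat_loo.elpd_loo,
                "delta_elpd": np.nan,
                "se_elpd": np.nan,
            }
        )
        per_level: dict[str, dict] = {}
        prev_loo = sat_loo
        flagged: list[str] = []
        for level in MI_LEVELS:
            post = fit_mi_level(y_c, z, uspec, level, cfg, stochastic=stochastic)
            ppmc = deviance_ppmc(post, sat, y_c, max_draws=max_draws)
            loo = loo_from_posterior(post, y_c, max_draws=max_draws)
            comp = compare_loo(loo, prev_loo)
            prev_loo = loo
            per_level[level] = {"post": post, "ppmc": ppmc, "loo": loo}
            rows.append(
                {
                    "construct": factor,
                    "model": level,
                    "loglik": ppmc.mean_loglik_hyp,
                    "delta_dev": ppmc.mean_delta,
                    "ci_low": ppmc.ci95[0],
                    "ci_high": ppmc.ci95[1],
                    "ppp": ppmc.ppp,
                    "elpd_loo": loo.elpd_loo,
                    "delta_elpd": comp.delta_elpd,
                    "se_elpd": comp.se_delta,
                }
            )
            if level == "configural":
                # flag substantially moderated parameters (95% CrI off zero)
                for n in uspec.param_names:
                    g1 = post.get(f"gamma1[{n}]").ravel()
                    lo, hi = np.quantile(g1, [0.025, 0.975])
                    if lo > 0 or hi < 0:
                        flagged.append(n)
        elpds = {lv: per_level[lv]["loo"].elpd_loo for lv in MI_LEVELS}
        misfits = {lv: per_level[lv]["ppmc"].misfit(ppp_threshold) for lv in MI_LEVELS}
        best = max(elpds, key=elpds.get)
        if misfits[best]:
            ok_levels = [lv for lv in MI_LEVELS if not misfits[lv]]
            best = ok_levels[-1] if ok_levels else "configural"
        verdicts[factor] = ConstructVerdict(
            construct=factor,
            level=best,
            flagged=flagged,
            partial_invariance=bool(flagged),
            evidence=pd.DataFrame(
                {
                    lv: {
                        "elpd_loo": elpds[lv],
                        "ppp": per_level[lv]["ppmc"].ppp,
                        "misfit": misfits[lv],
                    }
                    for lv in MI_LEVELS
                }
            ).T,
        )
    table = pd.DataFrame(rows)
    return InvarianceVerdict(constructs=verdicts, method="mnlfa"), table


# ---------------------------------------------------------------------------
# Structural invariance
# ---------------------------------------------------------------------------


def moderated_indirect_effect(
    g0_b1: float, g1_b1: float, g0_b3: float, g1_b3: float, z_values=(-1.0, 0.0, 1.0)
) -> pd.Series:
    """Indirect effect X -> M -> Y as a function of the moderator:
    (gamma0_b1 + gamma1_b1 z) * (gamma0_b3 + gamma1_b3 z).  Derived output;
    the direct-path moderations are the primary results."""
    vals = {
        f"z={v:g}": (g0_b1 + g1_b1 * v) * (g0_b3 + g1_b3 * v) for v in z_values
    }
    return pd.Series(vals, name="indirect_effect")


@dataclass
class SIResult:
    table: pd.DataFrame
    indirect: pd.Series
    method: str
    details: object = None


def run_si(
    data,
    z: np.ndarray,
    spec: ModelSpec,
    mi_verdict: InvarianceVerdict | None = None,
    method: str = "ipcr",
    cfg: MCMCConfig | None = None,
    iterated: bool = False,
    stochastic: bool = True,
) -> SIResult:
    """Structural-invariance analysis of the full mediation model.

    Structural parameters (latent regressions and latent variances) are
    moderated; measurement parameters flagged non-invariant by the MI stage
    stay moderated (partial invariance) while invariant ones have their
    moderator effect fixed to zero.
    """
    data = _coerce_data(data, spec)
    z = np.asarray(z, dtype=float)
    order = {lv: i for i, lv in enumerate(MI_LEVELS)}
    flagged: list[str] = []
    if mi_verdict is not None:
        flagged = mi_verdict.flagged_params(spec)
        if order[mi_verdict.min_level()] < order["strong"]:
            warnings.warn(
                "MI verdict is below strong; structural comparisons may "
                "reflect measurement differences (proceeding with the "
                "partial-invariance model)",
                stacklevel=2,
            )
    structural = [
        n for n in spec.param_names if n.startswith(("beta_", "psi_"))
    ]
    keep_rows = structural

    if method == "ipcr":
        fit: MLFit = fit_ml(data, spec)
        table = (
            iterated_ipcr(fit, data, spec, z) if iterated else run_ipcr(fit, data, z)
        )
        tab = table.table.loc[keep_rows].copy()
        b1 = table.table.loc[_beta_name(spec, 0)]
        b3 = table.table.loc[_beta_name(spec, 2)]
        ind = moderated_indirect_effect(
            b1["gamma0"], b1["gamma1"], b3["gamma0"], b3["gamma1"]
        )
        return SIResult(table=tab, indirect=ind, method="ipcr", details=table)

    if method != "mnlfa":
        raise ValueError("method must be 'ipcr' or 'mnlfa'")
    cfg = cfg or MCMCConfig()
    mod = ModerationSpec.none(spec)
    for n in structural + flagged:
        mod.params[n].moderated = True
        mod.params[n].stochastic = stochastic
    model = build_moderated_model(spec, mod, PriorSpec.default(spec))
    post = sample_posterior(model, data, z, cfg)
    rows = []
    for n in structural:
        g0 = post.get(f"gamma0[{n}]").ravel()
        g1 = post.get(f"gamma1[{n}]").ravel()
        row = {
            "gamma0": g0.mean(),
            "gamma0_q2.5": np.quantile(g0, 0.025),
            "gamma0_q97.5": np.quantile(g0, 0.975),
            "gamma1": g1.mean(),
            "gamma1_q2.5": np.quantile(g1, 0.025),
            "gamma1_q97.5": np.quantile(g1, 0.975),
        }
        if stochastic:
            sd = np.exp(post.get(f"log_sigma[{n}]").ravel())
            row["sigma_het"] = sd.mean()
        rows.append(pd.Series(row, name=n))
    tab = pd.DataFrame(rows)
    b1 = tab.loc[_beta_name(spec, 0)]
    b3 = tab.loc[_beta_name(spec, 2)]
    ind = moderated_indirect_effect(
        b1["gamma0"], b1["gamma1"], b3["gamma0"], b3["gamma1"]
    )
    return SIResult(table=tab, indirect=ind, method="mnlfa", details=post)


def _beta_name(spec: ModelSpec, idx: int) -> str:
    s, t = spec.paths[idx]
    return f"beta_{s}_{t}"
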