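# Methods

`modinvar` tests measurement invariance (MI) and structural invariance (SI)
of a latent mediation model across a *continuous* moderator Z, by two
routes: individual parameter contribution regression (IPCR) and Bayesian
moderated nonlinear factor analysis (MNLFA).  This note records the models,
the estimation machinery, the numerical choices, and what the packaged
synthetic data can and cannot show.

## The base model

Three constructs X, M, Y are each measured by three continuous indicators,

    y_j = alpha_j + lambda_j eta_k + eps_j,   eps_j ~ N(0, theta_j),

with the recursive structural part M = beta1 X + zeta_M and
Y = beta2 X + beta3 M + zeta_Y.  Latent means are fixed at zero and the
first loading per construct at one, leaving q = 30 free parameters
(9 intercepts, 6 loadings, 9 residual variances, 3 latent variances,
3 regressions) against 54 saturated moments: 24 degrees of freedom.
The casewise log-likelihood is the multivariate normal density at the
model-implied moments; its analytic gradient (the casewise score) is
implemented in closed form and verified against finite differences at
1e-5 relative tolerance.  ML fitting uses L-BFGS on log-transformed
variances followed by a Newton polish; convergence requires a maximum
absolute gradient below 1e-6 on the working scale and no log-variance
beyond +-10 (the boundary analogue of a Heywood case).  Starting values
are deterministic moment heuristics (indicator means, unit loadings, half
variances, zero regressions).  Missing data are rejected; full-information
approaches are out of scope.

## IPCR

With casewise scores S_i and the sample Hessian H at the ML estimate,
individual parameter contributions are

    IPC_i = theta_hat - [H/N]^{-1} S_i .

Two algebraic identities hold exactly and are asserted in the tests: the
IPC mean equals the ML estimate, and the IPC covariance (1/N divisor)
equals the sandwich estimator (H/N)^{-1} Cov(S) (H/N)^{-1}.  Each IPC
column is regressed on [1, Z] by OLS with classical standard errors and
df = N - 2; no multiplicity correction is applied across the 30
simultaneous tests (the workflow's usual caveat about capitalising on
chance applies).  Scores and Hessians live on the natural parameter
scale, so variance-parameter IPCs are regressed linearly even though
variances are positive — that asymmetry with MNLFA's exponential link is
intentional and is part of what the simulation study measures.

### Iterated IPCR

The bias-corrected variant is specified verbally, not algebraically, in
the primary sources; this package implements it as safeguarded Newton
ascent on the fully moderated log-likelihood.  Predicting person-specific
parameters theta_i = gamma0 + gamma1 z_i, re-linearising scores and
casewise Hessians at those predictions, and re-estimating the coefficients
is exactly a Newton step on the estimating equation

    sum_i S_i(gamma0 + gamma1 z_i) (x) [1, z_i] = 0 ,

whose fixed point is the ML solution of the all-parameters-linearly-
moderated model; standard IPCR is the first such step taken with an
unweighted mean Hessian.  Numerical safeguards: linear variance
predictions pass through a smooth softplus floor at half the pooled ML
estimate (a linear prediction of a variance can turn nonpositive at
extreme moderator values); the Newton step is ridge-regularised until it
is an ascent direction and backtracked on the log-likelihood; divergence
(guard bound 1e3 x the initial coefficient norm) and stalling are
reported as honest non-convergence flags, never exceptions.  Convergence
is declared when coefficients settle below 1e-4 or the per-observation
gradient falls below 1e-3.  Under a null (homogeneous) population the
iterated and standard estimators agree up to sampling-level differences;
they are distinct estimators, so exact equality is not expected.

## Bayesian MNLFA

Every free parameter follows its own moderation regression,

    theta_p(v)    = gamma0_p + gamma1_p Z_v (+ eps_v,p)       identity link
    variance_p(v) = exp[gamma0_p + gamma1_p Z_v (+ eps_v,p)]  exponential link

with heterogeneity residuals eps_v,p ~ N(0, sigma_p^2) indexed by
moderator *value* (observations sharing a Z value share residuals; with a
continuous moderator that is one residual per person).  Including eps
makes the moderation stochastic; omitting it, deterministic.  Default
priors: loading intercepts N(1, .5) (pins the reflection mode), indicator
intercepts N(3, 2), all slopes N(0, .5), variance-regression intercepts
N(0, .5) on the log scale, heterogeneity SDs half-Cauchy(0, .1)
(implemented as a zero-located Cauchy truncated to the positive half
line).  Approximate invariance replaces selected slope priors by
N(0, .01) and the matching heterogeneity-SD priors by half-normal(.01).
Latent means are not regressed on Z in configural/weak models; a
latent-mean slope (intercept fixed at zero for identification) joins at
the strong-MI step.

Latent variables are always marginalised analytically — the conditional
model is linear-Gaussian throughout the package's scope, so the
marginal likelihood per person is an MVN density at person-specific
implied moments.  A sampled-latent fallback is therefore not provided.

### Sampling

No gradient-based probabilistic-programming sampler is assumed; the
package ships its own vectorised-chain Hamiltonian Monte Carlo driven by
the same analytic score machinery used for IPCR:

* dual-averaging step-size adaptation toward a target acceptance rate
  (default 0.8), uniformly jittered trajectory lengths, divergence
  flagged at an energy error of 1000;
* diagonal mass adaptation from warmup draws, plus a *dense* mass block
  on the moderation coefficients and heterogeneity scales, which are
  strongly correlated (heterogeneity residual coordinates stay diagonal);
* non-centered parameterisation of all heterogeneity residuals;
* two analytic reparameterisations that remove the worst posterior
  geometry: (a) intercept-heterogeneity residuals enter the mean linearly
  and are integrated out exactly (each adds sigma^2 to its indicator's
  residual variance; exact for all-unique moderator values, and a
  documented person-level approximation when values tie — set
  `marginalize_mean_heterogeneity=False` to sample the shared residuals
  explicitly); (b) for stochastic variance-type parameters the sampler
  draws delta = gamma0 + sigma^2/2 (the log marginal variance, which is
  what the likelihood constrains) and gamma0 is recovered in
  post-processing, straightening the curved (gamma0, log sigma) ridge.

Split-R-hat and bulk effective sample size are computed in-package and
cross-checked against arviz in the tests.  The convergence rule used by
the simulation harness is split-R-hat < 1.05 on all reported parameters
(moderation intercepts, slopes, heterogeneity SDs, latent-mean slopes)
and a divergent-transition fraction below 1%.  A conventional full-scale
run is four chains of 6000 iterations (the `MCMCConfig` default); the
desk-scale configurations used in tests are stated with each result.
These posteriors are genuinely hard: weakly identified heterogeneity
scales mix slowly, which is also why the original stochastic analyses
report convergence rates rather than uniform convergence.

### Model evaluation

Fit is checked against a *moderated saturated* model: indicator means
linear in Z and a covariance parameterised through a Cholesky factor with
log-linear diagonal and linear off-diagonal entries in Z — positive
definite at every moderator value by construction.  (Whether the original
formulation moderated the covariance elementwise or via a factor is not
stated; the Cholesky dialect is this package's default and is a modelling
choice, not a claim.)  Its priors are weakly informative and centered at
the sample moments, an empirical-Bayes device that shortens warmup
without constraining the posterior.  The discrepancy is the deviance
difference Delta_dev = -2(L_H - L_S) per retained draw, with draws of the
two independently fitted models paired by retained index after thinning
to the smaller count (the pairing is arbitrary; only the distribution of
the discrepancy matters).  Reported: posterior mean, central 95%
interval, and the posterior predictive p value (share of draws with
higher hypothesized deviance; ties count one half).  "Substantial
misfit" means PPp >= .95 or a 95% interval excluding zero.

Predictive accuracy uses PSIS-LOO on the latent-marginal pointwise
log-likelihood (conditioning on sampled heterogeneity residuals).  The
generalized-Pareto tail fit follows the Zhang–Stephens profile posterior
with the usual (n k + 5)/(n + 10) regularisation, tail length
min(S/5, 3 sqrt(S)), smoothed weights truncated at the raw maximum, and
k > 0.7 flagged; observations with point-mass draws contribute their
exact log density.  Model comparison reports the elpd difference and the
SE of the pointwise contrasts.

### Invariance workflow

Per construct (unidimensional model): configural -> weak (loadings) ->
strong (+ intercepts, with latent-mean moderation switched on) -> strict
(+ residual variances); constraint sets are nested by construction.  For
IPCR a level fails when the relevant slopes are significant at alpha =
.05 (two-sided, uncorrected, configurable); significantly moderated
intercepts do *not* fail strong MI when all pairwise 95% CIs of the
slopes overlap — a parallel drift is a latent-mean moderation in
disguise.  Only the CI-overlap rule is implemented; the sources alternate
between overlap and magnitude-similarity language, and the ambiguity is
resolved in favour of the explicit rule.  For MNLFA each level gets
approximate-invariance priors on its constraint set and is evaluated by
deviance PPMC and PSIS-LOO; the selected level is the one with the
highest elpd_loo unless its PPMC signals substantial misfit, in which
case the deepest non-misfitting level is retained.  "Substantial" for a
single MNLFA coefficient means a 95% credible interval excluding zero — a
decision rule, not a hypothesis test.  The SI stage moderates the latent
regressions and latent variances while keeping flagged measurement
parameters moderated (partial invariance) and fixing invariant ones'
moderator effects to zero.  The moderated indirect effect
(gamma0_b1 + gamma1_b1 z)(gamma0_b3 + gamma1_b3 z) at z in {-1, 0, 1} is
provided as derived convenience output.

## Synthetic data and the simulation study

The generator draws Z ~ N(0,1), one heterogeneity residual per parameter
per moderator value, person-specific parameters through the links, then
latents and indicators from the person-specific implied moments.  The
gamma0 population values are the worked example's posterior means
(Likert-style indicators in the 1.5–4.2 range; variance intercepts on the
log scale per the exponential-link notation).  Effect size is the share
of each parameter's total heterogeneity explained by the moderator,
rho = Var(gamma1 Z) / (Var(gamma1 Z) + sigma^2), with sigma fixed at the
worked example's heterogeneity-SD estimates, gamma1 = sign * sigma *
sqrt(rho/(1-rho)), and rho = .2/.5/.8 for small/medium/large.  The exact
numeric operationalisation used in the original study is not published in
full; these are explicit approximations, emitted in every provenance log
and fully overridable from a user table.

The comparison grid crosses {IPCR, BMNLFA} x {N = 100, 150, 200, 300,
500} x {small, medium, large} x {standard/iterated resp.
deterministic/stochastic} = 60 cells; 30 optional diffuse-prior BMNLFA
cells exist but are not defaults.  Per replication the harness records
convergence (ML flag, iteration flag, or the R-hat/divergence rule) and
the gamma0/gamma1 estimates with 95% intervals; metrics are relative
parameter estimation bias rpeb = 100 * mean((est - truth)/truth) averaged
within parameter type, 95% coverage, and power (slopes only), computed
only when more than half of the nominal replications converge (the
>100-of-200 rule, scaled).  Estimates are always compared against the
generating regression coefficients — log-scale for variance-type
parameters — so standard IPCR's natural-scale variance coefficients carry
the link mismatch as part of their reported bias, which is precisely the
three-step procedure's practical behaviour.  Parameters with zero
generating value are excluded from rpeb and noted in the per-parameter
table.

The packaged example fixture (N = 399 by default) mimics the worked
example: parallel intercept drifts per construct (+.17..+.26 for X and M,
-.32..-.38 for Y per unit Z) and one genuinely moderated residual
variance (second mediator indicator, slope .20 on the log scale), no
heterogeneity residuals.  What passing tests on these data show: the
estimators recover injected moderation patterns of realistic size under
their own distributional assumptions (normal indicators, linear
moderation, independent persons).  What they do not show: robustness to
ordinal/Likert discreteness, non-normal errors, nonlinear moderation,
dependent (dyadic) observations, or missing data — all outside the
generator's scope.

## Problem sizes used in the shipped checks

Chosen as desk-scale replications of the study conditions: the
standard-IPCR convergence count uses the full 200 replications at
N = 300 (small effect); the residual-variance bias check uses 100
replications at N = 300 (medium effect); the stochastic-BMNLFA
convergence check uses N = 500 (small effect) with few replications and
shortened chains, stated alongside the result; calibration checks
(deviance-PPMC coverage, IPCR null rejection rate, simulation-based
calibration of the sampler) use single-construct models at N = 40–250.

## Known limitations

* Continuous-indicator MVN likelihood only; no ordinal or missing data.
* The iterated-IPCR update is this package's reading of a verbally
  described algorithm; its fixed point (moderated ML) is well defined,
  but other readings exist.
* The moderated saturated model is one dialect of "moderated mean and
  covariance"; elementwise-linear covariance moderation would differ.
* HMC convergence for stochastic MNLFA at small N or short chains is
  genuinely marginal; treat single-fit non-convergence as information,
  not failure of the method.
* The deterministic MNLFA equivalence to product-term moderation
  regressions holds for the structural part under flat priors; with the
  shipped priors small shrinkage differences remain.
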