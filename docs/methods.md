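# Methods

## The estimation problem

Cross-sectional studies measure a binary outcome (disease, behaviour,
status) and a binary exposure on each subject at one point in time.  The
effect measure of interest is the **prevalence ratio** PR = p1/p2, the
outcome prevalence among exposed over unexposed.  Logistic regression —
the reflex choice for binary outcomes — estimates the **odds ratio**
instead, and the identity

    OR = PR * (1 - p2) / (1 - p1)

shows the OR overstates the PR by a factor that grows with prevalence:
negligible below ~10% prevalence, severalfold at 85–96%.  The package
therefore centres on log-link models whose exponentiated coefficients are
PRs, with the **negative log-binomial** (NLB) model as the lead estimator.

## Models

All four regression models share the systematic component
`ln mu_i = x_i' beta` (intercept, binary exposure, covariates), so
`exp(beta_exposure)` is an adjusted PR (the logistic model, with a logit
link, gives an adjusted OR).  They differ in the working variance:

| family | working likelihood | Var(Y) | notes |
|---|---|---|---|
| `log_binomial` | Bernoulli | mu(1-mu) | exact likelihood; fitted mu must stay < 1 |
| `log_poisson` | Poisson | mu | valid point estimates; model SEs conservative for binary y |
| `cox_constant_time` | — | — | alias of `log_poisson`: a Cox model with all follow-up times equal yields the identical estimator, and the two are reported as one row |
| `negative_log_binomial` | NB2 negative binomial | mu + alpha mu^2 | dispersion alpha >= 0 estimated by ML; alpha = 0 collapses continuously to Poisson |
| `logistic` | Bernoulli (logit) | mu(1-mu) | OR benchmark |

The NB2 parameterization (variance mu + alpha mu^2, the convention of
mainstream ML software) is used for the NLB model.  The classical
negative-binomial pmf in r (number of successes) and p exposition is
equivalent but is not the regression family; the regression is
parameterized directly in (mu, alpha), Y|x ~ NB(1/alpha, 1/(1 + alpha mu)).

For binary outcomes the Poisson and NB likelihoods are *working*
likelihoods: y! = 1 and the reported log-likelihoods are exact as written.
On binary data the NB dispersion MLE is alpha = 0 (the profile score at
alpha -> 0+ is negative for any cell-mean fit), so the NLB point estimates
equal the Poisson ones there; alpha becomes informative for overdispersed
counts and for frailty-contaminated designs.  Inference never relies on the
working variance: the robust (sandwich) covariance is the default.

## Fitting

Maximum likelihood by iteratively reweighted least squares (Fisher
scoring) with monotone step-halving: a proposed step is halved until the
log-likelihood does not decrease and, for the log-link binomial family,
until every fitted mu <= 1 - 1e-10.  Convergence requires all of

* max |Delta beta| < epsilon,
* relative log-likelihood change < epsilon,
* max |score| <= max(100 epsilon, epsilon n),

with epsilon = 1e-6 and at most 100 iterations by default.  The score
condition matters: near the mu < 1 boundary the feasibility constraint
shrinks steps below any parameter-change threshold while the gradient is
still large, and without it a pinned log-binomial fit would masquerade as
converged.  Non-convergence is data, not an exception: the fit reports
`no_boundary` (iterates pinned at the mu bound, i.e. fitted mu above
1 - 1e-6 with a non-vanishing score) or `no_maxiter`, and comparison
reports render such rows as "No converge".

The NB fit alternates IRLS for beta at fixed alpha with a bounded 1-D
maximization of the exact NB2 profile likelihood in ln alpha (alpha
constrained to [0, 1e6]; estimates below 1e-10, or profiles maximized at
the lower bound, collapse to alpha = 0 / Poisson).  For integer y the
gammaln difference in the NB likelihood is evaluated as
`sum_{j<y} ln(1 + j alpha)`, which is numerically stable arbitrarily close
to alpha = 0 where the naive gammaln form cancels catastrophically.
Starting values: least squares on the linearized response, falling back to
an intercept-only start if the log-link start is infeasible; alpha starts
at 0.01.

BIC = -2 loglik + k ln n, with alpha counted in k for the NB family (how
the original analysis counted it is unknowable; counting the estimated
parameter is the conservative choice).  BIC is reported as missing for
non-converged fits.

## Variance estimation

Model-based covariance is the inverse expected information (X'WX)^-1 from
the final IRLS weights; for the NB family alpha is held at its estimate
(profile covariance), which matches what a GLM with fixed alpha reports.

The robust (sandwich) covariance is A^-1 B A^-1 with A the **observed**
information at the MLE (equal to the expected information for the
canonical logistic/Poisson families; family-specific analytic weights for
the log-binomial and NB families) and B the sum of per-subject score outer
products.  A finite-sample factor n/(n-1) is applied by default — the
convention of the major commercial packages, selectable off via
`scaling="none"` (HC0) — because the source tables were produced under
that convention; the package documents rather than hides the choice.

Two exact identities anchor the implementation and are enforced in tests:

* For the saturated exposure-only model, the unscaled robust SE of the
  log-PR equals the 2x2 delta-method SE, sqrt(1/a - 1/n1 + 1/c - 1/n0),
  for the Poisson, NB (any alpha) and log-binomial fits alike — the
  "robust model equals the crude values" observation.
* Toggling the finite-sample factor changes every SE by exactly
  sqrt(n/(n-1)).

## Mantel–Haenszel reference

The confounding-adjusted reference is the MH pooled PR
`sum_i(a_i n0_i / n_i) / sum_i(c_i n1_i / n_i)` with the Greenland–Robins
(1985) variance for the log-PR — the estimator's variance was not stated
in the source tables, and Greenland–Robins is the standard implemented by
mainstream software.  On one stratum it reduces exactly to the crude
estimator.  No continuity corrections are applied by default; a +0.5
correction is available behind an explicit flag.

Three scale-free percentages compare models against this reference:
PR precision |PR_MH - PR_model|/PR_model * 100, the signed confounding
percentage (PR_crude - PR_adj)/PR_adj * 100, and SE precision
|SE_MH - SE_model|/SE_model * 100 on log-scale SEs.  (In the source the
printed precision series is labelled with the confounding equation's
number, but the values arithmetically match the precision formula; the
binding here follows the arithmetic.)

## Reconstruction of 2x2 tables from printed summaries

The motivating survey's subject-level records are confidential, so worked
examples are made testable by exhaustive search: enumerate every integer
table (a, b, c, d) with the stated total whose case total, crude PR and
log-scale SE round (half-even) to the printed values, optionally filtered
by a printed OR.  The search is the oracle — if it returns nothing, no
such table exists.

Running it on the published rows shows the 9.6%-, 85.7%- and
96.1%-prevalence rows are exactly consistent with integer tables, while
the 1.8%- and 21.3%-prevalence rows are **not** consistent with any table
at n = 5810 at printed rounding (closest misses are a few units off in the
SE's fourth decimal).  The likely causes are design-weighted published
prevalences alongside crude-count effect statistics, and per-outcome item
non-response shifting the effective n.  A `tol_units` parameter (matching
half-width in units of the last printed digit; default 0.5 = exact
rounding) lets callers retrieve nearest approximants for such internally
inconsistent rows; the acceptance script does this for the 1.8% outcome
and reports the approximant's statistics as computed.

## Synthetic cohorts

The generator draws cohorts from exactly the model class the estimators
assume, so every true effect is known:

* **Age**: a group label from the configured shares (study preset:
  41.9/24.0/14.0/20.2%, renormalized from their printed sum of 100.1%),
  then a continuous age from the study-wide truncated normal
  (mean 28.2, SD 7.1, range 18–56) restricted to the group's interval.
  The preset reproduces the group shares exactly in expectation; the
  resulting mixture's overall mean/SD (~28.5/6.6) only approximate the
  published moments, a documented compromise in favour of the shares.
* **Exposure** ("depression"): Bernoulli with age-group-dependent
  log-odds calibrated so the marginal hits the target (preset: 30%, a
  realistic screening-positive share; the survey did not publish it).
  The age–exposure association is what induces confounding.
* **Outcomes**: Bernoulli(exp(b0 + b1 exposure + age effect [+ frailty])),
  with b0 calibrated in closed form so the marginal prevalence equals its
  target.  Configurations implying a probability above 1 at any (age
  group, exposure) support point are refused before any draw — the
  generating model is always exactly the fitted model.  The optional
  frailty is a mean-one log-normal multiplier (off by default) inducing
  extra-binomial variation for overdispersion experiments.

Study-preset effect sizes: true PRs equal the published age-adjusted
estimates where representable (2.931, 3.444, 2.175, 1.243).  At 96.1%
marginal prevalence the published 1.086 is not representable at 30%
exposure (it implies an exposed-cell probability above 1), so that preset
uses the representability cap 1.0585, placing the exposed-cell probability
at 0.9997; consistent with the published tables, this outcome carries no
age confounding.  That near-saturation is precisely the regime in which
log-binomial fitting pins at the boundary while the Poisson/NB fits are
untroubled — the package's qualitative twin of the survey's "No converge"
row.  True age effects in the survey are unpublished; preset values are
chosen only to reproduce the published marginals and the sign of the
confounding, and nothing downstream interprets them as estimates.

What the generator does *not* emulate: the survey's stratified sampling
design and weights, instrument measurement error, item non-response, and
any covariate structure beyond age.  Tests passing on generator output
therefore validate the estimators under a correctly specified log-link
model with a single confounder — not the full messiness of the field data.

## Problem sizes and numerical choices

Repeated-sampling checks use 500 replicates of n = 2000 for the
recovery/coverage benchmark (true PR 2 at 10% prevalence; Monte-Carlo SE
of the mean PR about 0.013) and 5 replicates of n = 5810 for the
non-convergence contrast; the oracle-equivalence suite uses 50 datasets of
n <= 500 per family at agreement 1e-6; dispersion recovery uses
n = 20,000 count datasets.  The bootstrap check of the delta-method SE
uses a large-count table (200,000 multinomial replicates): the
delta/bootstrap comparison is made in the regime where the first-order
approximation is valid — at cell counts as small as 5 the bootstrap SD of
the log-PR visibly exceeds the delta SE, which is a property of the
approximation, not an implementation error.

95% intervals use the exact normal quantile 1.959964..., never 1.96.
Printed published values are matched at +-1 in the last printed digit,
because the inputs they were computed from are themselves rounded.

## What is, and is not, reproducible without the confidential data

The survey's subject-level records ("available under request") are
confidential and no accession exists; nothing in this package requires
them.  The crude rows of the published tables are reproducible here
through table reconstruction and refitting (exactly where the printed
numbers are self-consistent, to the nearest approximant where they are
not).  The **age-adjusted PRs, SEs and BIC values of the published
adjusted-model tables are NOT reproducible** from printed information:
they depend on the joint age-exposure-outcome distribution of the
confidential records.  They are covered instead by structural and
qualitative checks — metric arithmetic on the printed values, confounding
of the correct sign on emulated cohorts, the non-convergence contrast, and
NB-vs-Poisson BIC ordering under overdispersion.  Known further
limitations: the MH variance formula and the robust-variance finite-sample
scaling used by the original analysis are undocumented (standard choices
are made and stated); survey weights are ignored (none appear in the
published formulas); and the logistic rows are benchmarks, not estimators
of the PR.
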