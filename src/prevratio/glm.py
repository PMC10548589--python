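"""Maximum-likelihood GLM fitting for prevalence-ratio estimation.

Implements the four working models compared throughout the package, all by
iteratively reweighted least squares (Fisher scoring) with step-halving:

``logistic``
    binomial family, logit link; exp(coefficient) is an odds ratio.
``log_binomial``
    binomial family, log link; exp(coefficient) is a prevalence ratio, but
    the fitted means must stay below 1, which makes the model prone to
    boundary non-convergence at high prevalence.
``log_poisson`` (alias ``cox_constant_time``)
    Poisson working likelihood with log link applied to binary outcomes;
    the Cox model with constant follow-up time yields the identical
    estimator, so the alias resolves to the same code path bit-for-bit.
``negative_log_binomial``
    NB2 negative binomial (Var = mu + alpha mu^2) with log link, the
    dispersion alpha estimated jointly by alternating maximization; at
    alpha = 0 it collapses continuously to the Poisson fit.

For the Poisson/NB working likelihoods on binary y the y! terms vanish, so
the reported log-likelihoods are exact for 0/1 data and remain the full
count-data likelihoods for integer y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.optimize import minimize_scalar

from .errors import RankDeficiencyError, ValidationError

__all__ = [
    "SubjectData",
    "Term",
    "ModelSpec",
    "FitResult",
    "FAMILIES",
    "resolve_family",
    "build_design",
    "fit_glm",
    "fit_negbin",
    "fit_model",
    "bic",
    "extract_effect",
]

FAMILIES = ("logistic", "log_binomial", "log_poisson", "cox_constant_time",
            "negative_log_binomial")

_MU_MAX = 1.0 - 1e-10  # upper bound on fitted probabilities, log-link binomial


def resolve_family(name: str) -> str:
    """Resolve family aliases; ``cox_constant_time`` is ``log_poisson``."""
    if name not in FAMILIES:
        raise ValidationError(f"unknown family {name!r}; choose from {FAMILIES}")
    return "log_poisson" if name == "cox_constant_time" else name


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    """Subject-level records: one row per subject, binary outcome/exposure."""

    frame: pd.DataFrame
    outcome: str = "outcome"
    exposure: str = "exposure"

    def __post_init__(self) -> None:
        for col in (self.outcome, self.exposure):
            if col not in self.frame.columns:
                raise ValidationError(f"column {col!r} not in data")
            vals = self.frame[col]
            if vals.isna().any():
                raise ValidationError(f"column {col!r} has missing values")
            if not set(np.unique(vals)) <= {0, 1}:
                raise ValidationError(f"column {col!r} must be binary 0/1")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class Term:
    """One covariate in the systematic component.

    ``kind`` is "numeric" (single untransformed column) or "categorical"
    (dummy coding dropping the stated ``reference`` level).
    """

    name: str
    kind: str = "numeric"
    reference: Optional[str] = None
    levels: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise ValidationError(f"term kind must be numeric|categorical, got {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValidationError(f"categorical term {self.name!r} needs a reference level")


@dataclass(frozen=True)
class ModelSpec:
    """Family + covariate terms + variance flavour for one fitted model."""

    family: str
    terms: tuple = ()
    variance: str = "model_based"

    def __post_init__(self) -> None:
        resolve_family(self.family)
        if self.variance not in ("model_based", "robust"):
            raise ValidationError("variance must be model_based|robust")


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    family: str
    names: list
    beta: np.ndarray
    cov_model: np.ndarray
    loglik: float
    bic: float
    alpha: Optional[float]  # NB dispersion; None for other families
    converged: str  # "yes" | "no_boundary" | "no_maxiter"
    n_obs: int
    n_params: int  # counts alpha for the NB family
    iterations: int
    grad_norm: float = math.nan

    def se(self, cov: Optional[np.ndarray] = None) -> np.ndarray:
        c = self.cov_model if cov is None else cov
        return np.sqrt(np.diag(c))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "names": list(self.names),
            "beta": [float(b) for b in self.beta],
            "se_model": [float(s) for s in self.se()],
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "alpha": None if self.alpha is None else float(self.alpha),
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "iterations": self.iterations,
        }


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def build_design(data: SubjectData, spec: ModelSpec):
    """Build (y, X, names): intercept, exposure, then terms in spec order.

    Categorical terms are dummy-coded with the declared reference level
    dropped; an unseen level in the data is a validation error.
    """
    df = data.frame
    y = df[data.outcome].to_numpy(dtype=float)
    cols = [np.ones(len(df)), df[data.exposure].to_numpy(dtype=float)]
    names = ["intercept", data.exposure]
    for term in spec.terms:
        if term.name not in df.columns:
            raise ValidationError(f"covariate {term.name!r} not in data")
        col = df[term.name]
        if col.isna().any():
            raise ValidationError(f"covariate {term.name!r} has missing values")
        if term.kind == "numeric":
            cols.append(col.to_numpy(dtype=float))
            names.append(term.name)
        else:
            declared = list(term.levels) if term.levels is not None else sorted(
                col.astype(str).unique()
            )
            if term.reference not in declared:
                declared = [term.reference] + declared
            seen = set(col.astype(str).unique())
            unknown = seen - set(map(str, declared))
            if unknown:
                raise ValidationError(
                    f"covariate {term.name!r} has undeclared level(s): {sorted(unknown)}"
                )
            svals = col.astype(str).to_numpy()
            for lev in declared:
                if str(lev) == str(term.reference):
                    continue
                cols.append((svals == str(lev)).astype(float))
                names.append(f"{term.name}[{lev}]")
    X = np.column_stack(cols)
    return y, X, names


# ---------------------------------------------------------------------------
# Family internals: log-likelihood, IRLS weights, scores
# ---------------------------------------------------------------------------


def _log_factorial(y: np.ndarray) -> np.ndarray:
    return gammaln(y + 1.0)


def _nb_gammaln_ratio(y: np.ndarray, alpha: float) -> float:
    """sum_i [gammaln(y_i + 1/alpha) - gammaln(1/alpha) + y_i ln alpha].

    For integer y this equals sum_i sum_{j=0}^{y_i-1} ln(1 + j alpha),
    which is evaluated directly — stable for alpha arbitrarily close to 0
    where the gammaln difference would cancel catastrophically.
    """
    ymax = int(y.max()) if len(y) else 0
    total = 0.0
    for j in range(1, ymax):  # j = 0 contributes ln(1) = 0
        total += math.log1p(j * alpha) * int((y > j).sum())
    return total


def family_loglik(family: str, y: np.ndarray, mu: np.ndarray,
                  alpha: float | None = None) -> float:
    """Exact log-likelihood of the working model at fitted means ``mu``."""
    from scipy.special import xlogy

    family = resolve_family(family)
    if family in ("logistic", "log_binomial"):
        return float(np.sum(xlogy(y, mu) + xlogy(1 - y, 1 - mu)))
    if family == "log_poisson" or (family == "negative_log_binomial" and not alpha):
        return float(np.sum(xlogy(y, mu) - mu - _log_factorial(y)))
    # NB2 with alpha > 0, integer y
    a = float(alpha)
    core = np.sum(xlogy(y, mu) - (y + 1.0 / a) * np.log1p(a * mu) - _log_factorial(y))
    return float(core + _nb_gammaln_ratio(y, a))


def _irls_weights(family: str, y, mu, alpha):
    """Expected-information (Fisher scoring) weights for eta-scale IRLS."""
    if family == "logistic":
        return mu * (1 - mu)
    if family == "log_binomial":
        return mu / (1 - mu)
    if family == "log_poisson":
        return mu
    return mu / (1 + alpha * mu)  # NB2, alpha fixed


def _score_factor(family: str, y, mu, alpha):
    """s_i = score_factor_i * x_i; the per-subject score in eta."""
    if family == "logistic":
        return y - mu
    if family == "log_binomial":
        return (y - mu) / (1 - mu)
    if family == "log_poisson":
        return y - mu
    return (y - mu) / (1 + alpha * mu)


def _obs_info_weight(family: str, y, mu, alpha):
    """Observed-information weights -d^2 l_i / d eta_i^2."""
    if family == "logistic":
        return mu * (1 - mu)  # canonical: observed = expected
    if family == "log_binomial":
        return (1 - y) * mu / (1 - mu) ** 2
    if family == "log_poisson":
        return mu
    return (1 + alpha * y) * mu / (1 + alpha * mu) ** 2


def _working_response(family: str, y, mu, eta):
    if family == "logistic":
        return eta + (y - mu) / (mu * (1 - mu))
    return eta + (y - mu) / mu  # log link families


def _eta_feasible(family: str, eta: np.ndarray) -> bool:
    if family in ("log_binomial",):
        return bool(np.max(eta) <= math.log(_MU_MAX))
    return True


def _inv_link(family: str, eta: np.ndarray) -> np.ndarray:
    if family == "logistic":
        return 1.0 / (1.0 + np.exp(-eta))
    # keep mu strictly positive: degenerate cells drive eta -> -inf
    return np.exp(np.clip(eta, -300.0, 300.0))


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            f"design matrix has rank < {X.shape[1]} columns; drop collinear terms"
        )


def _initial_beta(family: str, y, X) -> np.ndarray:
    """Least squares on the linearized response, falling back to the
    feasible intercept-only start when the log-link mean would exceed 1."""
    ybar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    mu0 = np.clip((y + ybar) / 2.0, 1e-6, 1 - 1e-6)
    eta0 = np.log(mu0 / (1 - mu0)) if family == "logistic" else np.log(mu0)
    beta, *_ = np.linalg.lstsq(X, eta0, rcond=None)
    eta = X @ beta
    if not _eta_feasible(family, eta):
        beta = np.zeros(X.shape[1])
        beta[0] = math.log(ybar / (1 - ybar)) if family == "logistic" else math.log(ybar)
    return beta


def _irls(family: str, y, X, alpha=None, beta0=None, tol=1e-6, max_iter=100):
    """Fisher-scoring IRLS with monotone step-halving.

    Returns (beta, loglik, converged, iterations, mu). ``converged`` is one
    of "yes", "no_boundary", "no_maxiter". Accepted steps never decrease
    the log-likelihood.
    """
    beta = _initial_beta(family, y, X) if beta0 is None else np.asarray(beta0, float)
    eta = X @ beta
    if not _eta_feasible(family, eta):
        eta = np.minimum(eta, math.log(_MU_MAX))
        beta, *_ = np.linalg.lstsq(X, eta, rcond=None)
        eta = X @ beta
    mu = _inv_link(family, eta)
    ll = family_loglik(family, y, mu, alpha)
    converged = "no_maxiter"
    it = 0
    for it in range(1, max_iter + 1):
        W = _irls_weights(family, y, mu, alpha)
        z = _working_response(family, y, mu, eta)
        WX = X * W[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        delta = beta_new - beta
        # step-halve until feasible and non-decreasing log-likelihood
        step = 1.0
        accepted = False
        while step > 1e-12:
            cand = beta + step * delta
            eta_c = X @ cand
            if _eta_feasible(family, eta_c):
                mu_c = _inv_link(family, np.clip(eta_c, -700, 700))
                if family == "logistic":
                    mu_c = np.clip(mu_c, 1e-300, 1 - 1e-16)
                ll_c = family_loglik(family, y, mu_c, alpha)
                if np.isfinite(ll_c) and ll_c >= ll - 1e-13 * (abs(ll) + 1):
                    accepted = True
                    break
            step /= 2.0
        if not accepted:
            break
        moved = np.max(np.abs(step * delta))
        rel_ll = abs(ll_c - ll) / (abs(ll_c) + 0.1)
        beta, eta, mu, ll = cand, eta_c, mu_c, ll_c
        if moved < tol and rel_ll < tol:
            break
    # classify: "yes" means a genuinely stationary point.  Boundary-pinned
    # iterates also show tiny steps, so the score must be small as well.
    grad = X.T @ _score_factor(family, y, mu, alpha)
    if np.max(np.abs(grad)) <= max(100 * tol, tol * len(y)):
        converged = "yes"
    else:
        pinned = family == "log_binomial" and bool(np.max(X @ beta) > math.log(1 - 1e-6))
        converged = "no_boundary" if pinned else "no_maxiter"
    return beta, ll, converged, it, mu


def _model_cov(family: str, y, X, mu, alpha) -> np.ndarray:
    from .errors import PrevRatioError

    W = _irls_weights(family, y, mu, alpha)
    info = X.T @ (X * W[:, None])
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise PrevRatioError(
            "expected information is singular at the fitted coefficients "
            "(degenerate data, e.g. an empty or outcome-free exposure cell)"
        ) from exc


def fit_glm(y, X, family: str, *, names: Sequence[str] | None = None,
            tol: float = 1e-6, max_iter: int = 100,
            beta0=None) -> FitResult:
    """Fit one GLM by IRLS. ``family`` may be any name in :data:`FAMILIES`;
    the NB family dispatches to :func:`fit_negbin`.

    Convergence requires both max |Delta beta| < tol and the relative
    log-likelihood change < tol (default 1e-6). Non-convergence is reported
    in ``FitResult.converged``, never raised.
    """
    fam = resolve_family(family)
    if fam == "negative_log_binomial":
        return fit_negbin(y, X, names=names, tol=tol, max_iter=max_iter)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_rank(X)
    beta, ll, converged, it, mu = _irls(fam, y, X, None, beta0, tol, max_iter)
    cov = _model_cov(fam, y, X, mu, None)
    k = X.shape[1]
    grad = X.T @ _score_factor(fam, y, mu, None)
    bic_val = -2.0 * ll + k * math.log(len(y))
    return FitResult(family=family, names=list(names) if names else
                     [f"x{i}" for i in range(k)],
                     beta=beta, cov_model=cov, loglik=ll, bic=bic_val,
                     alpha=None, converged=converged, n_obs=len(y),
                     n_params=k, iterations=it,
                     grad_norm=float(np.max(np.abs(grad))))


def _profile_alpha(y, mu, alpha_cap: float) -> float:
    """Maximize the NB2 log-likelihood over alpha >= 0 at fixed means."""
    def negll(log_a):
        return -family_loglik("negative_log_binomial", y, mu, math.exp(log_a))
    ll0 = family_loglik("negative_log_binomial", y, mu, 0.0)
    res = minimize_scalar(negll, bounds=(-30.0, math.log(alpha_cap)),
                          method="bounded", options={"xatol": 1e-12})
    if not res.success or -res.fun <= ll0 + 1e-12:
        return 0.0
    a = math.exp(res.x)
    return 0.0 if a < 1e-10 else a


def fit_negbin(y, X, *, names: Sequence[str] | None = None, tol: float = 1e-6,
               max_iter: int = 100, alpha0: float = 0.01,
               alpha_cap: float = 1e6) -> FitResult:
    """Joint ML fit of the NB2 log-link model by alternating maximization.

    IRLS updates beta at fixed alpha; a bounded 1-D search updates alpha at
    fixed beta on the exact NB2 log-likelihood.  alpha is constrained to
    [0, alpha_cap]; the likelihood is continuous at alpha = 0 where the fit
    collapses to Poisson.  alpha counts as a parameter in the BIC.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(np.abs(y - np.round(y)) > 1e-9):
        raise ValidationError("NB likelihood requires integer-valued outcomes")
    _check_rank(X)
    alpha = alpha0
    beta = None
    total_it = 0
    converged = "no_maxiter"
    for _outer in range(200):
        beta_new, ll, conv_b, it, mu = _irls(
            "negative_log_binomial", y, X, alpha, beta, tol=min(tol, 1e-8),
            max_iter=max_iter)
        total_it += it
        alpha_new = _profile_alpha(y, mu, alpha_cap)
        db = np.inf if beta is None else float(np.max(np.abs(beta_new - beta)))
        da = abs(alpha_new - alpha) / (1.0 + abs(alpha))
        beta, alpha = beta_new, alpha_new
        if db < tol and da < tol and conv_b == "yes":
            converged = "yes"
            break
        if alpha >= alpha_cap * (1 - 1e-9):
            converged = "no_boundary"
            break
    mu = np.exp(X @ beta)
    ll = family_loglik("negative_log_binomial", y, mu, alpha)
    cov = _model_cov("negative_log_binomial", y, X, mu, alpha)
    k = X.shape[1] + 1  # alpha counted
    grad = X.T @ _score_factor("negative_log_binomial", y, mu, alpha)
    return FitResult(family="negative_log_binomial",
                     names=list(names) if names else
                     [f"x{i}" for i in range(X.shape[1])],
                     beta=beta, cov_model=cov, loglik=ll,
                     bic=-2.0 * ll + k * math.log(len(y)),
                     alpha=alpha, converged=converged, n_obs=len(y),
                     n_params=k, iterations=total_it,
                     grad_norm=float(np.max(np.abs(grad))))


def fit_model(data: SubjectData, spec: ModelSpec, **kwargs) -> FitResult:
    """Convenience: build the design from a :class:`ModelSpec` and fit."""
    y, X, names = build_design(data, spec)
    return fit_glm(y, X, spec.family, names=names, **kwargs)


def bic(fit: FitResult) -> float:
    """Bayesian information criterion, -2 loglik + k ln n (lower is better).

    Undefined for a non-converged fit: returns NaN, which comparison
    reports render as missing.
    """
    if fit.converged != "yes":
        return math.nan
    return -2.0 * fit.loglik + fit.n_params * math.log(fit.n_obs)


def extract_effect(fit: FitResult, term: str, cov: Optional[np.ndarray] = None,
                   level: float = 0.95):
    """Ratio effect for one coefficient: exp(beta) with Wald CI.

    ``measure`` is OR for the logistic family and PR otherwise. ``cov``
    selects the covariance (model-based by default; pass a robust matrix
    to get sandwich-based intervals).
    """
    from .tables import EffectEstimate, wald_ci  # local import: avoid cycle

    if term not in fit.names:
        raise ValidationError(f"term {term!r} not among fitted columns {fit.names}")
    j = fit.names.index(term)
    c = fit.cov_model if cov is None else np.asarray(cov)
    point = math.exp(fit.beta[j])
    se = math.sqrt(c[j, j])
    lo, hi = wald_ci(point, se, level)
    measure = "OR" if resolve_family(fit.family) == "logistic" else "PR"
    return EffectEstimate(measure, point, se, lo, hi, level)
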