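"""Sandwich (Huber-White / Lin-Wei) covariance for fitted GLMs.

The robust covariance is ``A^{-1} B A^{-1}`` with ``A`` the observed
information at the ML estimate and ``B`` the sum of per-subject score outer
products.  It is consistent for the variance of the coefficient estimates
even when the working variance function is misspecified — the reason the
Poisson and negative-binomial working models give valid inference for
binary outcomes.

By default a finite-sample factor n/(n-1) multiplies the sandwich, the
convention of the major commercial survey/biostat packages; ``scaling="none"``
gives the plain HC0 estimator.  For the NB family the dispersion alpha is
held fixed at its estimate (profile sandwich), so the matrix has one row
per regression coefficient only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PrevRatioError, ValidationError
from .glm import FitResult, _obs_info_weight, _score_factor, resolve_family

__all__ = ["RobustCovariance", "sandwich", "effect_with_robust"]

_SCALINGS = ("stata", "none")


@dataclass
class RobustCovariance:
    """Sandwich covariance of the regression coefficients (log scale)."""

    matrix: np.ndarray
    scaling: str  # "stata" (n/(n-1)) or "none" (HC0)
    source_fit: FitResult

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.matrix))


def sandwich(fit: FitResult, y, X, scaling: str = "stata") -> RobustCovariance:
    """Compute A^{-1} B A^{-1} at the fitted coefficients.

    ``A`` uses the observed information (for the canonical logistic and
    log-Poisson families this coincides with the expected information);
    ``B = sum_i s_i s_i'`` from the per-subject scores.  ``scaling`` applies
    the n/(n-1) finite-sample factor ("stata", default) or nothing ("none").
    """
    if scaling not in _SCALINGS:
        raise ValidationError(f"scaling must be one of {_SCALINGS}")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    fam = resolve_family(fit.family)
    eta = X @ fit.beta
    mu = 1 / (1 + np.exp(-eta)) if fam == "logistic" else np.exp(eta)
    w_info = _obs_info_weight(fam, y, mu, fit.alpha)
    A = X.T @ (X * w_info[:, None])
    s = _score_factor(fam, y, mu, fit.alpha)
    Xs = X * s[:, None]
    B = Xs.T @ Xs
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise PrevRatioError("observed information matrix is singular") from exc
    V = Ainv @ B @ Ainv
    n = len(y)
    if scaling == "stata":
        V = V * (n / (n - 1))
    return RobustCovariance(matrix=V, scaling=scaling, source_fit=fit)


def effect_with_robust(fit: FitResult, y, X, term: str, level: float = 0.95,
                       scaling: str = "stata"):
    """Ratio effect for one term using the sandwich covariance."""
    from .glm import extract_effect

    rc = sandwich(fit, y, X, scaling=scaling)
    return extract_effect(fit, term, cov=rc.matrix, level=level)
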