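"""Order-restricted estimates and the fit term of the criterion.

Under the multivariate-normal approximation eta_hat ~ N(eta, Sigma_hat), the
order-restricted MLE under hypothesis H is the point satisfying the
constraints that is closest to eta_hat in the Mahalanobis metric,

    eta_tilde = argmin (eta - eta_hat)' Sigma^{-1} (eta - eta_hat)
                s.t.  S eta = s, R eta >= r,

and the restricted maximum log-likelihood is the normal log-density

    L = -(K/2) ln(2 pi) - (1/2) ln|Sigma| - (1/2) quad_form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from ._qp import solve_restricted
from .bootstrap import EstimationResult
from .hypotheses import LinearHypothesis

__all__ = ["RestrictedFit", "restricted_mle", "unconstrained_loglik"]

ACTIVE_TOL = 1e-8


@dataclass
class RestrictedFit:
    """The restricted estimate with its fit diagnostics."""

    eta_tilde: np.ndarray
    loglik: float
    quad_form: float
    active_eq: list[int] = field(default_factory=list)
    active_ineq: list[int] = field(default_factory=list)


def _logdet_cholesky(sigma: np.ndarray) -> float:
    try:
        c = linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance matrix is not positive definite") from exc
    return 2.0 * float(np.sum(np.log(np.diag(c))))


def unconstrained_loglik(est) -> float:
    """Normal log-density at its own mean: -(K/2) ln(2 pi) - (1/2) ln|Sigma|."""
    sigma = est.sigma_hat if isinstance(est, EstimationResult) else np.asarray(est)
    k = sigma.shape[0]
    return -0.5 * k * np.log(2 * np.pi) - 0.5 * _logdet_cholesky(sigma)


def restricted_mle(est, h: LinearHypothesis,
                   tol: float = ACTIVE_TOL) -> RestrictedFit:
    """Project eta_hat onto the constraint set of ``h`` and score the fit.

    ``est`` is an :class:`EstimationResult` (or any object with ``eta_hat``
    values and a positive-definite ``sigma_hat``).
    """
    if isinstance(est, EstimationResult):
        eta_hat = est.eta_hat.values
        sigma = est.sigma_hat
        if est.eta_hat.names != h.eta_names:
            raise ValueError(
                f"hypothesis {h.label!r} is defined over {h.eta_names}, "
                f"estimates over {est.eta_hat.names}")
    else:  # (eta_hat, sigma) pair
        eta_hat, sigma = est
        eta_hat = np.asarray(eta_hat, dtype=float)
        sigma = np.asarray(sigma, dtype=float)

    logdet = _logdet_cholesky(sigma)
    k = sigma.shape[0]

    if h.satisfied_by(eta_hat, tol=tol):
        eta_tilde = eta_hat.copy()
        quad = 0.0
    else:
        eta_tilde = solve_restricted(eta_hat, sigma, h.S, h.s, h.R, h.r)
        diff = eta_tilde - eta_hat
        quad = float(diff @ np.linalg.solve(sigma, diff))

    loglik = -0.5 * k * np.log(2 * np.pi) - 0.5 * logdet - 0.5 * quad

    active_eq = list(range(h.n_eq))
    active_ineq = []
    if h.n_ineq:
        resid = h.R @ eta_tilde - h.r
        scale = np.sqrt(np.einsum("ij,jk,ik->i", h.R, sigma, h.R))
        scale = np.where(scale > 0, scale, 1.0)
        active_ineq = list(np.flatnonzero(np.abs(resid) / scale <= tol))
    return RestrictedFit(eta_tilde, float(loglik), quad, active_eq, active_ineq)
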