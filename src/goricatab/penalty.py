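"""Hypothesis complexity: level probabilities and the penalty term.

The penalty of a hypothesis is the expected number of free parameters left
after imposing its restrictions: samples are drawn from the zero-mean normal
null N(0, Sigma_hat), each is projected onto the (relocated, i.e. constants
set to zero) constraint cone, and the *level* of a sample is K minus the
rank of the constraint rows active at its projection.  With level
probabilities LP_l (the fraction of samples at level l),

    PT = sum_l l * LP_l,            0 <= PT <= K.

Because relocated linear constraint sets are closed convex cones, this
penalty does not depend on the scale of the covariance.  Two closed forms
bypass the Monte Carlo: the unconstrained hypothesis has PT = K and an
equality-only hypothesis has PT = K - rank(S).

``penalty_bounded_pi`` implements the alternative construction directly on
the D-1 free cell probabilities with their bound restrictions (each pi >= 0,
sum <= 1) included in the feasible set.  That set is *not* a cone, so the
resulting penalty depends on the null mean mu and on any scale factor c
applied to the covariance — the mode exists to demonstrate exactly this
behaviour, and therefore deliberately does not relocate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from ._qp import ENUM_CAP, activity_levels, project_polyhedron_batch
from .hypotheses import LinearHypothesis, relocate
from .reparam import EtaSpec, eta_matrix

__all__ = [
    "PenaltyResult",
    "BoundedPenaltyConfig",
    "penalty_mc",
    "penalty_closed_form",
    "penalty_bounded_pi",
]


@dataclass
class PenaltyResult:
    """Level probabilities LP_0..LP_K and the penalty PT = sum l * LP_l."""

    level_probs: np.ndarray
    pt: float
    mc_se: float
    T: int
    seed: int | None
    mode: str  # eta | bounded_pi | closed_form

    def __post_init__(self) -> None:
        self.level_probs = np.asarray(self.level_probs, dtype=float)

    @property
    def k(self) -> int:
        return self.level_probs.size - 1

    def to_json(self) -> str:
        return json.dumps({
            "level_probs": self.level_probs.tolist(),
            "pt": self.pt, "mc_se": self.mc_se, "T": self.T,
            "seed": self.seed, "mode": self.mode,
        })


def _result_from_levels(levels: np.ndarray, k: int, seed, mode: str
                        ) -> PenaltyResult:
    T = levels.size
    lp = np.bincount(levels, minlength=k + 1) / T
    pt = float(levels.mean())
    se = float(levels.std(ddof=1) / np.sqrt(T)) if T > 1 else 0.0
    return PenaltyResult(lp, pt, se, T, seed, mode)


def penalty_closed_form(h: LinearHypothesis, k: int | None = None
                        ) -> PenaltyResult | None:
    """Exact penalty where no sampling is needed, else ``None``.

    The unconstrained hypothesis keeps all K parameters free; an
    equality-only hypothesis removes rank(S) of them with certainty.
    """
    k = h.k if k is None else k
    if h.is_unconstrained:
        level = k
    elif h.n_ineq == 0:
        level = k - int(np.linalg.matrix_rank(h.S))
    else:
        return None
    lp = np.zeros(k + 1)
    lp[level] = 1.0
    return PenaltyResult(lp, float(level), 0.0, 0, None, "closed_form")


def penalty_mc(h: LinearHypothesis, sigma: np.ndarray, T: int = 10000,
               seed: int | None = None) -> PenaltyResult:
    """Monte-Carlo penalty under the zero-mean normal null.

    The hypothesis is relocated (constants zeroed) before sampling, so the
    constraint set is a closed convex cone and the result is invariant to
    rescaling ``sigma``.
    """
    sigma = np.asarray(sigma, dtype=float)
    k = sigma.shape[0]
    if h.k != k:
        raise ValueError("covariance size does not match hypothesis parameters")
    if T < 1000:
        warnings.warn(
            f"T = {T} penalty samples gives a large Monte-Carlo error",
            stacklevel=2)
    hr = relocate(h)
    try:
        chol = linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((T, k)) @ chol.T
    X = project_polyhedron_batch(Z, sigma, hr.S, hr.s, hr.R, hr.r)
    levels = activity_levels(X, sigma, hr.S, hr.R, hr.r)
    return _result_from_levels(levels, k, seed, "eta")


# ---------------------------------------------------------------------------
# bounded-pi mode
# ---------------------------------------------------------------------------

@dataclass
class BoundedPenaltyConfig:
    """Settings for the bounded cell-probability penalty.

    ``mu`` is the null mean over all D cells (default: the simplex center
    1/D, i.e. every cell equally probable); ``c`` scales the covariance.
    """

    mu: np.ndarray | None = None
    c: float = 1.0
    T: int = 2000
    tol_active: float = 1e-6
    starts: int = 3
    max_dropped_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.mu is not None:
            self.mu = np.asarray(self.mu, dtype=float)
            if (self.mu <= 0).any() or self.mu.sum() >= 1 + 1e-12:
                raise ValueError("mu must lie strictly inside the simplex")


def penalty_bounded_pi(h: LinearHypothesis | None, spec: EtaSpec,
                       sigma_pi: np.ndarray, cfg: BoundedPenaltyConfig,
                       seed: int | None = None) -> PenaltyResult:
    """Penalty with the bound restrictions on cell probabilities included.

    Works in the D-1 free coordinates (the last cell is one minus the rest).
    Samples are drawn from N(mu, c * Sigma_pi); a sample inside the feasible
    set counts at full level, an infeasible one is projected onto the set by
    constrained minimization of the Mahalanobis distance (multistart), and
    its level is D-1 minus the rank of the active constraints, bound
    restrictions included.  ``h`` states restrictions on ``spec``'s eta
    parameters, evaluated as functions of the cell probabilities; pass
    ``None`` (or an unconstrained hypothesis) for the bounded unconstrained
    hypothesis.
    """
    d = int(np.prod(spec.dims))
    kf = d - 1
    sigma_pi = np.asarray(sigma_pi, dtype=float)
    if sigma_pi.shape != (d, d):
        raise ValueError(f"sigma_pi must be {d}x{d}")
    mu = np.full(d, 1.0 / d) if cfg.mu is None else cfg.mu
    sig_f = cfg.c * sigma_pi[:kf, :kf]
    try:
        chol = linalg.cholesky(sig_f, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "free-coordinate covariance is not positive definite") from exc

    rng = np.random.default_rng(seed)
    Z = mu[:kf] + rng.standard_normal((cfg.T, kf)) @ chol.T

    no_hyp = h is None or h.is_unconstrained
    tol = cfg.tol_active * np.sqrt(max(1.0, cfg.c))

    # feasibility w.r.t. bounds and, when present, the hypothesis inequalities
    full = np.hstack([Z, 1.0 - Z.sum(axis=1, keepdims=True)])
    feasible = (full >= -tol).all(axis=1)
    if not no_hyp:
        if h.n_eq > 0:
            feasible &= False  # equalities are never met by chance
        if h.n_ineq > 0:
            vals, estimable = eta_matrix(spec, np.clip(full, 0.0, None))
            ok = estimable & feasible
            lhs = np.full((cfg.T, h.n_ineq), -np.inf)
            lhs[ok] = vals[ok] @ h.R.T
            feasible &= (lhs - h.r >= -tol).all(axis=1)

    levels = np.empty(cfg.T, dtype=int)
    levels[feasible] = kf
    dropped = 0

    idx_infeasible = np.flatnonzero(~feasible)
    if idx_infeasible.size:
        if no_hyp and d - 1 + 1 <= ENUM_CAP:
            # all constraints linear: exact enumeration projection
            S0 = np.zeros((0, kf))
            Rb = np.vstack([np.eye(kf), -np.ones((1, kf))])
            rb = np.concatenate([np.zeros(kf), [-1.0]])
            X = project_polyhedron_batch(Z[idx_infeasible], sig_f,
                                         S0, np.zeros(0), Rb, rb)
            for j, i in enumerate(idx_infeasible):
                levels[i] = _bounded_level(X[j], spec, h, kf, tol)
        else:
            for i in idx_infeasible:
                x = _project_bounded(Z[i], chol, spec, h, mu, kf, rng, cfg)
                if x is None:
                    dropped += 1
                    levels[i] = -1
                else:
                    levels[i] = _bounded_level(x, spec, h, kf, tol)

    if dropped:
        frac = dropped / cfg.T
        warnings.warn(f"{dropped} of {cfg.T} samples could not be projected",
                      stacklevel=2)
        if frac > cfg.max_dropped_fraction:
            raise RuntimeError(
                f"{frac:.1%} of penalty samples failed to project "
                f"(limit {cfg.max_dropped_fraction:.0%})")
        levels = levels[levels >= 0]
    return _result_from_levels(levels, kf, seed, "bounded_pi")


def _eta_of_free(spec: EtaSpec, x: np.ndarray) -> np.ndarray:
    full = np.append(x, 1.0 - x.sum())
    vals, _ = eta_matrix(spec, full[None, :])
    return vals[0]


def _project_bounded(z, chol, spec, h, mu, kf, rng, cfg):
    """Multistart SLSQP projection onto the bounded feasible set.

    Works in whitened coordinates x = z + L y (Sigma = L L'), where the
    objective is simply ||y||^2 and therefore well scaled.
    """
    def to_x(y):
        return z + chol @ y

    cons = [
        {"type": "ineq", "fun": lambda y: to_x(y),                # pi_i >= 0
         "jac": lambda y: chol},
        {"type": "ineq", "fun": lambda y: 1.0 - to_x(y).sum(),    # last cell
         "jac": lambda y: -chol.sum(axis=0)},
    ]
    if h is not None and h.n_ineq:
        cons.append({"type": "ineq",
                     "fun": lambda y: h.R @ _eta_of_free(spec, to_x(y)) - h.r})
    if h is not None and h.n_eq:
        cons.append({"type": "eq",
                     "fun": lambda y: h.S @ _eta_of_free(spec, to_x(y)) - h.s})

    # start points: the clipped sample, the null mean, random interior points
    starts = [_clip_to_simplex(z), mu[:kf].copy()]
    while len(starts) < max(cfg.starts, 2):
        starts.append(rng.dirichlet(np.ones(kf + 1))[:kf])
    solve = np.linalg.solve

    def violation(x):
        v = max(-x.min(), x.sum() - 1.0, 0.0)
        if h is not None and h.n_ineq:
            eta = h.R @ _eta_of_free(spec, np.clip(x, 1e-12, None)) - h.r
            v = max(v, float(-eta.min()), 0.0)
        if h is not None and h.n_eq:
            eta = h.S @ _eta_of_free(spec, np.clip(x, 1e-12, None)) - h.s
            v = max(v, float(np.abs(eta).max()))
        return v

    best, best_obj = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            lambda y: y @ y,
            x0=solve(chol, x0 - z),
            jac=lambda y: 2 * y,
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 300, "ftol": 1e-10},
        )
        # a solver that stalls near the optimum still yields a usable point
        # as long as the constraints hold
        x = to_x(res.x)
        if res.fun < best_obj and violation(x) <= 1e-6:
            best, best_obj = x, res.fun
    return best


def _clip_to_simplex(z: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    x = np.clip(z, eps, None)
    total = x.sum()
    if total > 1.0 - eps:
        x = x * (1.0 - eps) / total
    return x


def _bounded_level(x: np.ndarray, spec: EtaSpec, h, kf: int,
                   tol: float) -> int:
    """D-1 minus the rank of active constraint gradients at x."""
    grads = []
    for i in range(kf):
        if x[i] <= tol:
            g = np.zeros(kf)
            g[i] = 1.0
            grads.append(g)
    if 1.0 - x.sum() <= tol:
        grads.append(np.ones(kf))
    if h is not None and (h.n_eq or h.n_ineq):
        # evaluate ratio constraints slightly inside the simplex so their
        # gradients stay finite when a denominator column hits zero
        xs = np.clip(x, 1e-9, None)
        eta = _eta_of_free(spec, xs)
        jac = _eta_jacobian(spec, xs, kf)
        for i in range(h.n_eq):
            grads.append(h.S[i] @ jac)
        if h.n_ineq and np.isfinite(eta).all():
            resid = h.R @ eta - h.r
            for i in np.flatnonzero(np.abs(resid) <= tol):
                grads.append(h.R[i] @ jac)
    if not grads:
        return kf
    g = np.vstack(grads)
    g = g[np.isfinite(g).all(axis=1)]
    rank = 0 if g.size == 0 else int(np.linalg.matrix_rank(g, tol=1e-9))
    return kf - rank


def _eta_jacobian(spec: EtaSpec, x: np.ndarray, kf: int,
                  h_step: float = 1e-7) -> np.ndarray:
    """Central-difference Jacobian d eta / d pi_free, shape (K, kf)."""
    jac = np.empty((spec.k, kf))
    for j in range(kf):
        xp, xm = x.copy(), x.copy()
        xp[j] += h_step
        xm[j] -= h_step
        jac[:, j] = (_eta_of_free(spec, xp) - _eta_of_free(spec, xm)) / (2 * h_step)
    return jac
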