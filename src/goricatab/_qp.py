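"""Projection onto polyhedral constraint sets in the Mahalanobis metric.

The restricted estimate solves

    min_x (x - z)' Sigma^{-1} (x - z)   s.t.   S x = s,  R x >= r,

a strictly convex QP whose KKT point is unique.  For the small systems that
arise here (K <= ~15 parameters, a handful of rows) the exact solution is
found by enumerating candidate active sets: for every linearly independent
subset A of inequality rows, the equality-constrained solution

    x = z - Sigma A' (A Sigma A')^{-1} (A z - b)

is a closed form, and exactly one subset satisfies both primal feasibility of
the remaining rows and dual feasibility (non-negative multipliers).  Because
the map z -> x is linear per subset, thousands of Monte-Carlo samples are
projected simultaneously with a few matrix products per subset.  Systems with
more inequality rows than the enumeration cap fall back to SLSQP.

Constraint rows are internally rescaled to unit Sigma-norm so that primal
residuals and dual multipliers are on comparable scales and a single
tolerance applies.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import optimize

__all__ = ["solve_restricted", "project_polyhedron_batch", "activity_levels",
           "InfeasibleError"]

ENUM_CAP = 12  # max inequality rows for exact enumeration (2^12 subsets)


class InfeasibleError(ValueError):
    """The equality system is inconsistent or the feasible set is empty."""


def _normalize(sigma, S, s, R, r):
    """Scale every constraint row to unit Sigma-norm."""
    def norm_rows(M, v):
        if M.shape[0] == 0:
            return M, v
        sc = np.sqrt(np.einsum("ij,jk,ik->i", M, sigma, M))
        sc = np.where(sc > 0, sc, 1.0)
        return M / sc[:, None], v / sc
    S, s = norm_rows(np.asarray(S, float), np.asarray(s, float))
    R, r = norm_rows(np.asarray(R, float), np.asarray(r, float))
    return S, s, R, r


def _subsets(n):
    for size in range(n + 1):
        yield from combinations(range(n), size)


def project_polyhedron_batch(Z, sigma, S, s, R, r, tol: float = 1e-8):
    """Project each row of Z onto {S x = s, R x >= r} in the Sigma metric.

    Returns the array of projections, shape like ``Z``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    T, K = Z.shape
    S, s, R, r = _normalize(sigma, S, s, R, r)
    h_r = R.shape[0]

    if h_r > ENUM_CAP:
        inv = np.linalg.inv(sigma)
        return np.vstack([_slsqp_project(z, inv, S, s, R, r) for z in Z])

    X = np.empty_like(Z)
    unassigned = np.ones(T, dtype=bool)

    for sub in _subsets(h_r):
        if not unassigned.any():
            break
        idx = list(sub)
        A = np.vstack([S, R[idx]]) if (S.shape[0] or idx) else np.zeros((0, K))
        b = np.concatenate([s, r[idx]])
        m = A.shape[0]
        if m == 0:
            # unconstrained-by-equalities candidate: z itself, if feasible
            cand = unassigned.copy()
            if h_r:
                cand &= (Z @ R.T - r >= -tol).all(axis=1)
            X[cand] = Z[cand]
            unassigned &= ~cand
            continue
        G = A @ sigma @ A.T
        # skip linearly dependent active sets; a full-rank subset reproduces
        # the same KKT point with admissible multipliers
        if np.linalg.matrix_rank(G, tol=1e-10 * max(1.0, np.trace(G))) < m:
            continue
        lam = np.linalg.solve(G, A @ Z.T - b[:, None])       # (m, T)
        Xc = Z - (sigma @ A.T @ lam).T
        ok = unassigned.copy()
        n_eq = S.shape[0]
        if m > n_eq:
            # with x = z - Sigma A' lam, a binding >= row has lam <= 0
            ok &= (lam[n_eq:] <= tol).all(axis=0)
        out = [i for i in range(h_r) if i not in sub]
        if out:
            ok &= (Xc @ R[out].T - r[out] >= -tol).all(axis=1)
        X[ok] = Xc[ok]
        unassigned &= ~ok

    if unassigned.any():
        if S.shape[0]:
            # inconsistent equalities leave every subset rejected
            lhs, *_ = np.linalg.lstsq(S, s, rcond=None)
            if np.max(np.abs(S @ lhs - s)) > 1e-8:
                raise InfeasibleError("inconsistent equality constraints")
        inv = np.linalg.inv(sigma)
        for i in np.flatnonzero(unassigned):
            X[i] = _slsqp_project(Z[i], inv, S, s, R, r)
    return X


def solve_restricted(eta_hat, sigma, S, s, R, r, tol: float = 1e-8):
    """Restricted estimate for a single point; see module docstring."""
    x = project_polyhedron_batch(eta_hat[None, :], sigma, S, s, R, r, tol=tol)
    return x[0]


def activity_levels(X, sigma, S, R, r, tol: float = 1e-8):
    """Number of free parameters left at each projected point.

    The level of a point is K minus the rank of the matrix of its active
    constraint rows (all equality rows plus inequality rows with zero
    residual), determined from residuals so the result does not depend on the
    solver's internal active set.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = X.shape[1]
    S, _, R, r = _normalize(sigma, S, np.zeros(S.shape[0]), R, r)
    if R.shape[0]:
        act = np.abs(X @ R.T - r) <= tol
    else:
        act = np.zeros((X.shape[0], 0), dtype=bool)
    levels = np.empty(X.shape[0], dtype=int)
    cache: dict[bytes, int] = {}
    for i, pattern in enumerate(act):
        key = pattern.tobytes()
        if key not in cache:
            A = np.vstack([S, R[pattern]])
            rank = 0 if A.shape[0] == 0 else np.linalg.matrix_rank(A, tol=1e-10)
            cache[key] = K - rank
        levels[i] = cache[key]
    return levels


def _slsqp_project(z, sigma_inv, S, s, R, r):
    cons = []
    if S.shape[0]:
        cons.append({"type": "eq", "fun": lambda x, S=S, s=s: S @ x - s,
                     "jac": lambda x, S=S: S})
    if R.shape[0]:
        cons.append({"type": "ineq", "fun": lambda x, R=R, r=r: R @ x - r,
                     "jac": lambda x, R=R: R})
    res = optimize.minimize(
        lambda x: (x - z) @ sigma_inv @ (x - z),
        x0=z.copy(),
        jac=lambda x: 2 * sigma_inv @ (x - z),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 400, "ftol": 1e-14},
    )
    if not res.success:
        raise RuntimeError(f"QP fallback did not converge: {res.message}")
    return res.x
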