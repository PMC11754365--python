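"""Nonparametric bootstrap of eta and its covariance; sampling-zero repair.

The point estimate eta_hat is always the value computed from the observed
table (not the bootstrap mean); the bootstrap supplies only the covariance.
Each replicate resamples the n observations with replacement, which for a
contingency table is a multinomial(n, pi_hat) draw of cell counts.
Replicates in which any eta component loses its denominator (inestimable)
are discarded and redrawn, and the discard count is reported.

Components that are constant across replicates — sampling zeros, or
conditional proportions stuck at 1 — produce zero rows/columns in the
covariance, which is then not positive definite.  ``adjust_covariance``
repairs the diagonal by substituting a summary (min by default, the smallest
defensible amount of information; mean and max as progressively stronger
fallbacks) of the strictly positive variances, keeping the off-diagonal
entries of the repaired rows at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .reparam import EtaSpec, EtaVector, eta_matrix, eta_value
from .tables import ContingencyTable, mle_probabilities

__all__ = [
    "EstimationResult",
    "bootstrap_estimate",
    "bootstrap_cell_covariance",
    "adjust_covariance",
    "ensure_positive_definite",
]

#: relative eigenvalue tolerance for positive definiteness
PD_TOL = 1e-12


@dataclass
class EstimationResult:
    """Observed-table eta_hat with its bootstrap covariance."""

    eta_hat: EtaVector
    sigma_hat: np.ndarray
    B: int
    discarded: int = 0
    adjustment: str = "none"  # none | min | mean | max
    seed: int | None = None

    def __post_init__(self) -> None:
        self.sigma_hat = np.asarray(self.sigma_hat, dtype=float)
        k = self.eta_hat.values.size
        if self.sigma_hat.shape != (k, k):
            raise ValueError("covariance shape does not match eta")
        if not np.allclose(self.sigma_hat, self.sigma_hat.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")

    @property
    def k(self) -> int:
        return self.eta_hat.values.size

    @property
    def discard_fraction(self) -> float:
        return self.discarded / max(self.discarded + self.B, 1)

    def to_json(self) -> str:
        return json.dumps({
            "eta": self.eta_hat.values.tolist(),
            "flags": list(self.eta_hat.flags),
            "names": list(self.eta_hat.names),
            "sigma": self.sigma_hat.tolist(),
            "B": self.B,
            "discarded": self.discarded,
            "adjustment": self.adjustment,
            "seed": self.seed,
        })

    @classmethod
    def from_json(cls, s: str) -> "EstimationResult":
        d = json.loads(s)
        return cls(
            EtaVector(np.array(d["eta"]), list(d["flags"]), list(d["names"])),
            np.array(d["sigma"]), d["B"], d["discarded"], d["adjustment"],
            d["seed"],
        )


def bootstrap_estimate(table: ContingencyTable, spec: EtaSpec, B: int = 1000,
                       seed: int | None = None,
                       max_discard_fraction: float = 0.5) -> EstimationResult:
    """Bootstrap eta_hat's covariance from ``B`` multinomial replicates."""
    if B < 2:
        raise ValueError("need B >= 2 bootstrap replicates")
    n = table.n
    if n == 0:
        raise ValueError("empty table")
    pi_hat = mle_probabilities(table)
    eta_hat = eta_value(spec, pi_hat)
    if not eta_hat.estimable:
        bad = [nm for nm, f in zip(eta_hat.names, eta_hat.flags)
               if f == "inestimable"]
        raise ValueError(
            f"component(s) {bad} are inestimable from the observed table "
            "(zero denominator); choose a different reparameterization or "
            "pool levels"
        )

    rng = np.random.default_rng(seed)
    p = pi_hat.values
    kept: list[np.ndarray] = []
    n_kept = 0
    discarded = 0
    # cap total draws so a pathological spec terminates with a clear error
    max_total = int(np.ceil(B / (1.0 - max_discard_fraction))) + 8
    while n_kept < B:
        m = min(B - n_kept, max_total - (n_kept + discarded))
        if m <= 0:
            raise ValueError(
                f"bootstrap discard fraction exceeded {max_discard_fraction:.0%} "
                f"({discarded} of {discarded + n_kept} replicates had "
                "inestimable components); choose a different "
                "reparameterization or pool levels"
            )
        counts = rng.multinomial(n, p, size=m)
        values, estimable = eta_matrix(spec, counts / n)
        good = values[estimable]
        discarded += int((~estimable).sum())
        kept.append(good)
        n_kept += good.shape[0]

    reps = np.vstack(kept)[:B]
    sigma = np.atleast_2d(np.cov(reps, rowvar=False, ddof=1))
    sigma = (sigma + sigma.T) / 2
    return EstimationResult(eta_hat, sigma, B, discarded, "none", seed)


def bootstrap_cell_covariance(table: ContingencyTable, B: int = 1000,
                              seed: int | None = None) -> np.ndarray:
    """D x D bootstrap covariance of the raw cell-probability estimates."""
    n = table.n
    p = mle_probabilities(table).values
    rng = np.random.default_rng(seed)
    reps = rng.multinomial(n, p, size=B) / n
    sigma = np.cov(reps, rowvar=False, ddof=1)
    return (sigma + sigma.T) / 2


def _zero_diagonal_mask(sigma: np.ndarray) -> np.ndarray:
    diag = np.diag(sigma)
    top = diag.max(initial=0.0)
    return diag <= PD_TOL * max(top, 1e-300)


def adjust_covariance(sigma: np.ndarray, strategy: str = "min"
                      ) -> tuple[np.ndarray, str]:
    """Replace zero diagonal entries by a summary of the positive ones.

    Returns the (possibly) adjusted matrix and the applied strategy
    (``"none"`` when there was nothing to repair).  Off-diagonal entries of
    repaired rows/columns stay at zero.
    """
    sigma = np.asarray(sigma, dtype=float)
    if not np.allclose(sigma, sigma.T, atol=1e-12):
        raise ValueError("covariance must be symmetric")
    zero = _zero_diagonal_mask(sigma)
    if not zero.any():
        return sigma.copy(), "none"
    pos = np.diag(sigma)[~zero]
    if pos.size == 0:
        raise ValueError("all diagonal entries are zero; nothing to repair from")
    fill = {"min": np.min, "mean": np.mean, "max": np.max}[strategy](pos)
    adj = sigma.copy()
    for i in np.flatnonzero(zero):
        adj[i, :] = 0.0
        adj[:, i] = 0.0
        adj[i, i] = fill
    return adj, strategy


def is_positive_definite(sigma: np.ndarray, tol: float = PD_TOL) -> bool:
    """Smallest eigenvalue exceeds ``tol`` times the largest diagonal entry."""
    w = np.linalg.eigvalsh(sigma)
    return bool(w[0] > tol * max(np.diag(sigma).max(initial=0.0), 1e-300))


def ensure_positive_definite(result: EstimationResult) -> EstimationResult:
    """Repair the covariance with min, then mean, then max substitution.

    Returns the first positive-definite variant with the applied strategy
    recorded; raises if none of the three succeeds (callers such as the
    simulation harness treat that as a skipped iteration).
    """
    if not _zero_diagonal_mask(result.sigma_hat).any():
        if is_positive_definite(result.sigma_hat):
            return result
    for strategy in ("min", "mean", "max"):
        adj, applied = adjust_covariance(result.sigma_hat, strategy)
        if is_positive_definite(adj):
            return replace(result, sigma_hat=adj, adjustment=applied)
    raise np.linalg.LinAlgError(
        "covariance matrix is not positive definite under min/mean/max "
        "diagonal repair"
    )
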