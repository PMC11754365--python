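"""Assembling criterion values, weights, and ranked reports.

For each hypothesis the criterion value is

    GORICA_m = -2 L(eta_tilde_m | eta_hat, Sigma_hat) + 2 PT_m,

smaller is better.  Values are transformed into weights

    w_m = exp(-GORICA_m / 2) / sum_m' exp(-GORICA_m' / 2),

the relative support in the data for each hypothesis within the set (ratios
of weights are evidence ratios).  Penalty weights w_m^P = exp(-PT_m),
normalized, compare hypothesis complexities alone.  With equality-only
hypotheses PT_m = K - rank(S_m), so the ranking reduces to AIC on the same
normal-approximation fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import bootstrap_estimate, ensure_positive_definite
from .hypotheses import HypothesisSet
from .penalty import penalty_closed_form, penalty_mc
from .reparam import EtaSpec
from .restricted import restricted_mle
from .tables import ContingencyTable

__all__ = [
    "EvaluateConfig",
    "GoricaTable",
    "gorica_value",
    "gorica_weights",
    "penalty_weights",
    "evaluate_set",
]


def gorica_value(loglik: float, pt: float) -> float:
    """-2 * fit + 2 * penalty."""
    if not (np.isfinite(loglik) and np.isfinite(pt)):
        raise ValueError("loglik and penalty must be finite")
    return -2.0 * loglik + 2.0 * pt


def gorica_weights(values) -> np.ndarray:
    """exp(-value/2), normalized (shifted by the minimum for stability)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values to compare")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    w = np.exp(-0.5 * (values - values.min()))
    return w / w.sum()


def penalty_weights(pts) -> np.ndarray:
    """exp(-PT_m), normalized over the hypothesis set."""
    pts = np.asarray(pts, dtype=float)
    w = np.exp(-(pts - pts.min()))
    return w / w.sum()


@dataclass
class EvaluateConfig:
    """Sample sizes and seeds for a full evaluation run."""

    B: int = 1000
    T: int = 10000
    seed: int | None = None
    max_discard_fraction: float = 0.5

    def spawn_seeds(self, n: int) -> list[int]:
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


@dataclass
class GoricaTable:
    """Ranked per-hypothesis results with run provenance."""

    labels: list[str]
    logliks: np.ndarray
    penalties: np.ndarray
    values: np.ndarray
    weights: np.ndarray
    penalty_wts: np.ndarray
    config: EvaluateConfig | None = None
    adjustment: str = "none"
    tie_tol: float = 1e-9
    extras: dict = field(default_factory=dict)

    @property
    def best(self) -> list[str]:
        """Label(s) of the smallest criterion value; ties are co-best."""
        v = self.values
        return [self.labels[i] for i in np.flatnonzero(v <= v.min() + self.tie_tol)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "hypothesis": self.labels,
            "loglik": self.logliks,
            "penalty": self.penalties,
            "gorica": self.values,
            "weight": self.weights,
            "penalty_weight": self.penalty_wts,
        })

    def to_json(self) -> str:
        payload = {
            "rows": json.loads(self.to_dataframe().to_json(orient="records")),
            "best": self.best,
            "adjustment": self.adjustment,
        }
        if self.config is not None:
            payload["config"] = {"B": self.config.B, "T": self.config.T,
                                 "seed": self.config.seed}
        return json.dumps(payload, indent=2)

    def to_text(self) -> str:
        df = self.to_dataframe()
        out = df.to_string(
            index=False,
            formatters={
                "loglik": "{:.3f}".format, "penalty": "{:.3f}".format,
                "gorica": "{:.3f}".format, "weight": "{:.3f}".format,
                "penalty_weight": "{:.3f}".format,
            },
        )
        best = self.best
        tag = " (tie)" if len(best) > 1 else ""
        return f"{out}\nbest: {', '.join(best)}{tag}\n"


def evaluate_set(table: ContingencyTable, spec: EtaSpec, hset: HypothesisSet,
                 config: EvaluateConfig | None = None) -> GoricaTable:
    """Full pipeline: bootstrap -> covariance repair -> fit and penalty ->
    ranked table.

    Closed-form penalties are used where exact (unconstrained and
    equality-only hypotheses); otherwise the Monte-Carlo penalty runs on the
    same (possibly adjusted) covariance as the fit.  The unconstrained
    failsafe is appended when the set requests it.
    """
    config = config or EvaluateConfig()
    hset = hset.with_failsafe()
    n_h = len(hset.hypotheses)
    boot_seed, *pen_seeds = config.spawn_seeds(1 + n_h)

    est = bootstrap_estimate(
        table, spec, B=config.B, seed=boot_seed,
        max_discard_fraction=config.max_discard_fraction)
    est = ensure_positive_definite(est)

    logliks, pts = np.empty(n_h), np.empty(n_h)
    extras: dict = {"penalties": {}}
    for i, h in enumerate(hset.hypotheses):
        fit = restricted_mle(est, h)
        logliks[i] = fit.loglik
        pen = penalty_closed_form(h)
        if pen is None:
            pen = penalty_mc(h, est.sigma_hat, T=config.T, seed=pen_seeds[i])
        pts[i] = pen.pt
        extras["penalties"][h.label] = pen

    values = np.array([gorica_value(l, p) for l, p in zip(logliks, pts)])
    weights = (gorica_weights(values) if n_h > 1
               else np.ones(1))
    return GoricaTable(
        labels=hset.labels, logliks=logliks, penalties=pts, values=values,
        weights=weights, penalty_wts=penalty_weights(pts), config=config,
        adjustment=est.adjustment,
        extras={**extras, "estimation": est},
    )
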