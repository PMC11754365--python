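"""Selection-rate simulation for 2 x 4 tables with designed sampling zeros.

Each condition fixes a true data-generating hypothesis (case 1-3: one of the
ordered/equality hypotheses on the male-given-degree conditional
proportions; case 4: a population satisfying none of them), an effect size
(Cramer's V of 0.10 / 0.30 / 0.50) and a sample size.  Per trial a
multinomial table is drawn from the population, the designed cells are set
to zero to mimic sampling zeros, and the full four-hypothesis evaluation
runs; the output is the percentage of trials in which each hypothesis
attains the smallest criterion value.  Trials whose covariance cannot be
repaired to positive definiteness (or that fail at any stage) are skipped
and counted, mirroring how such data sets would be excluded in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixtures import load_fixture
from .hypotheses import HypothesisSet, load_packaged_set
from .reparam import builtin_spec
from .selection import EvaluateConfig, evaluate_set
from .tables import ContingencyTable, ProbabilityVector

__all__ = [
    "SimulationCondition",
    "SimulationResult",
    "generate_table",
    "inject_zeros",
    "run_condition",
    "cramers_v",
]


@dataclass
class SimulationCondition:
    """One cell of the simulation grid."""

    case: int                  # 1..4, the true hypothesis H1/H2/H3/Hu
    phi: float                 # Cramer's V label: 0.10 | 0.30 | 0.50
    N: int                     # per-trial sample size
    trials: int = 250          # successful trials to accumulate
    B: int = 200               # bootstrap replicates per trial
    T: int = 2000              # penalty samples per trial
    seed: int | None = None
    max_skip_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.case not in (1, 2, 3, 4):
            raise ValueError("case must be 1..4")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        key = f"sim_case{self.case}_phi{round(self.phi * 100):02d}"
        if key not in _known_fixture_names():
            raise ValueError(f"no population fixture for case {self.case}, "
                             f"phi {self.phi}")
        self.fixture_name = key

    def population(self) -> ProbabilityVector:
        return load_fixture(self.fixture_name)


def _known_fixture_names():
    from .fixtures import SIM_POPULATIONS
    return SIM_POPULATIONS.keys()


@dataclass
class SimulationResult:
    """Per-hypothesis selection percentages for one condition."""

    condition: SimulationCondition
    pct_selected: dict[str, float]
    attempted: int
    skipped: int
    trials: int = 0

    def to_frame(self) -> pd.DataFrame:
        c = self.condition
        return pd.DataFrame([
            {"case": c.case, "phi": c.phi, "N": c.N, "hypothesis": h,
             "pct_selected": p, "trials": self.trials,
             "skipped": self.skipped}
            for h, p in self.pct_selected.items()
        ])


def generate_table(condition: SimulationCondition,
                   trial_seed: int | None = None) -> ContingencyTable:
    """Draw a 2 x 4 multinomial table of size N from the condition's
    population."""
    pop = condition.population()
    rng = np.random.default_rng(trial_seed)
    counts = rng.multinomial(condition.N, pop.values).reshape(pop.dims)
    return ContingencyTable(counts)


def inject_zeros(table: ContingencyTable, star_cells) -> ContingencyTable:
    """Set the designed cells to an observed count of zero.

    Counts are replaced, not redistributed, so the table total shrinks by
    whatever was drawn in those cells.
    """
    out = table.copy()
    for cell in star_cells:
        out.counts[tuple(cell)] = 0
    return out


def run_condition(condition: SimulationCondition,
                  hset: HypothesisSet | None = None) -> SimulationResult:
    """Accumulate ``trials`` successful evaluations and tally the winners.

    Ties for the smallest criterion value split the selection count
    fractionally, so percentages always sum to 100.
    """
    spec = builtin_spec("conditional_row", (2, 4), level=1)
    if hset is None:
        hset = load_packaged_set("degrees", spec.names)
    labels = hset.with_failsafe().labels
    tally = {lab: 0.0 for lab in labels}
    pop = condition.population()

    master = np.random.SeedSequence(condition.seed)
    successes = attempted = skipped = 0
    while successes < condition.trials:
        attempted += 1
        if skipped > condition.max_skip_fraction * max(attempted, 20):
            raise RuntimeError(
                f"more than {condition.max_skip_fraction:.0%} of iterations "
                "skipped; the condition looks pathological")
        child = master.spawn(1)[0]
        s_table, s_eval = (int(s.generate_state(1)[0] % (2 ** 31))
                           for s in child.spawn(2))
        table = inject_zeros(generate_table(condition, s_table),
                             pop.star_cells)
        try:
            result = evaluate_set(
                table, spec, hset,
                EvaluateConfig(B=condition.B, T=condition.T, seed=s_eval))
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            skipped += 1
            continue
        best = result.best
        for lab in best:
            tally[lab] += 1.0 / len(best)
        successes += 1

    pct = {lab: 100.0 * cnt / successes for lab, cnt in tally.items()}
    return SimulationResult(condition, pct, attempted, skipped,
                            trials=successes)


def cramers_v(pi: ProbabilityVector) -> float:
    """Cramer's V of a two-way probability table.

    sqrt(chi-square functional against the independence product, divided by
    min(I-1, J-1)).
    """
    if len(pi.dims) != 2:
        raise ValueError("Cramer's V is defined here for two-way tables")
    p = pi.values.reshape(pi.dims)
    row = p.sum(axis=1, keepdims=True)
    col = p.sum(axis=0, keepdims=True)
    expected = row @ col
    mask = expected > 0
    chi2 = float(((p - expected)[mask] ** 2 / expected[mask]).sum())
    return float(np.sqrt(chi2 / min(pi.dims[0] - 1, pi.dims[1] - 1)))
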