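# Methods

## Model and criterion

A contingency table of counts over factors with dims (I, J, …) is modelled
as multinomial(n, π) on D = I·J·… cells.  Theory-based hypotheses are
order and equality restrictions on functions of π.  Because restrictions on
conditional probabilities and odds ratios are non-linear in π, each
analysis first chooses a reparameterization η = g(π) under which its
hypotheses are linear:

| kind                  | component                              | table |
|-----------------------|----------------------------------------|-------|
| `cells`               | π<sub>ij</sub>                         | ≥ 2-way |
| `marginal`            | π<sub>i+</sub>, π<sub>+j</sub>, π<sub>ij+</sub>, … | ≥ 2-way |
| `conditional_row/col` | π<sub>ij</sub>/π<sub>+j</sub>, π<sub>ij</sub>/π<sub>i+</sub> | 2-way |
| `local_odds_ratio`    | π<sub>i-1,j-1</sub>π<sub>ij</sub> / (π<sub>i-1,j</sub>π<sub>i,j-1</sub>) | 2-way |
| `marginal_odds_ratio` | the same cross-ratios on two-way margins | ≥ 3-way |
| `conditional_odds_ratio` | cross-ratios in a slice at a fixed level | ≥ 3-way |

Every component is a quotient of products of cell-group sums, so one
evaluation routine covers all kinds, including batched evaluation over
bootstrap replicates.  Cell order is row-major over the factors in declared
order throughout.

Hypotheses are written `S η = s, R η > r` and ranked by

GORICA<sub>m</sub> = −2 L(η̃<sub>m</sub> | η̂, Σ̂) + 2 PT<sub>m</sub>,  with
weights w<sub>m</sub> ∝ exp(−GORICA<sub>m</sub>/2).

The weight transform is fixed here because it exactly reproduces the
published weights of both worked examples from their published criterion
values (a cross-check in the test suite).  With equality-only hypotheses
PT = K − rank(S) and the ranking coincides with AIC on the same
normal-approximation fits.

**Assumptions.** The criterion relies on the large-sample normal
approximation η̂ ~ N(η, Σ̂); with small n or very sparse tables the
approximation degrades and results should be read qualitatively.  Strict
inequalities are represented as closed constraints: the boundary has
probability zero under the sampling distribution of η̂, which is standard
order-restricted-inference practice and what a quadratic-programming
formulation requires.  A consequence worth knowing: an estimate sitting
exactly on the boundary (e.g. two marginals both estimated 0) *satisfies*
the closed constraint, so the restricted fit equals the unconstrained one.

## Estimation

* **η̂** is always the observed-table value (plain ratios of counts), never
  the bootstrap mean.
* **Σ̂** is the sample covariance of η over B nonparametric bootstrap
  replicates; resampling the n observations with replacement is a
  multinomial(n, π̂) draw of cell counts, which is how replicates are
  generated (vectorized).  Default B = 1000.  The examples' published
  covariances are reproduced to within the accuracy their two-significant-
  figure printing permits; B for those published values is not stated
  anywhere we can check, so our default is our own choice.
* **Sampling zeros.**  Components are flagged per replicate: `zero`
  (numerator 0, denominator positive), `one` (conditional proportion with
  empty complement), `inestimable` (denominator 0).  Inestimable components
  in the observed table abort the analysis with advice; inestimable
  replicates are discarded and redrawn (counted; more than a configurable
  50% discarded is an error).  Degenerate-but-estimable components enter
  with their value and produce zero variance, repaired as below.
* **Covariance repair.**  Zero diagonal entries are replaced by the
  minimum of the strictly positive variances (off-diagonals of the repaired
  rows stay 0); if the result is still not positive definite the mean and
  then the maximum are tried; if all fail the caller decides (the
  simulation harness skips the trial).  Min is the default because it adds
  the least unfounded information — small counts have small bootstrap
  variances.  Positive definiteness means smallest eigenvalue
  > 1e-12 × largest diagonal entry.

## Restricted fit and penalty

The restricted estimate minimizes the Mahalanobis distance to η̂ subject to
the constraints — a strictly convex QP.  It is solved *exactly* by
enumerating candidate active sets (for every linearly independent subset of
inequality rows the equality-constrained solution is closed-form; the KKT
point is the unique subset passing primal and dual feasibility).  Because
the per-subset solution map is linear, the Monte-Carlo penalty projects all
T null samples simultaneously with a few matrix products per subset.
Systems with more than 12 inequality rows fall back to SLSQP.  Constraint
rows are rescaled to unit Σ-norm so one tolerance (1e-8) governs primal
residuals and duals; log|Σ̂| is computed via Cholesky; the active set is
reported from constraint residuals, not solver internals; rank (not row
count) of the active rows determines the level, so linearly dependent
active constraints are not double-counted.  The fit and the penalty always
see the same (possibly repaired) covariance.

The penalty relocates the hypothesis (constants to zero) so the constraint
set is a closed convex cone and PT is invariant to rescaling Σ̂ — verified
as a property test at c = 1 vs c = 1e5.  Default T = 10000; the
Monte-Carlo standard error is reported so tolerances can be set rationally.

### Bounded cell-probability mode

`penalty_bounded_pi` exists to demonstrate why the reparameterization is
needed: it computes the penalty directly on the D−1 free cell probabilities
with the bound restrictions (π ≥ 0, Σπ ≤ 1) inside the feasible set, which
is *not* a cone, so the result depends on the null mean μ (default: simplex
center 1/D) and on the covariance scale c.  Samples from N(μ, c·Σ̂_π̂) that
are infeasible are projected by multistart SLSQP in whitened coordinates
(exact enumeration when all constraints are linear); the level is D−1 minus
the rank of the active constraint gradients, bounds included, with
activity tolerance 1e-6·√c.  At c = 1 the mode reproduces the published
demonstration values (7.000 for the bounded unconstrained hypothesis on a
2×4 table with n ≈ 2400; ≈ 6.3 for the conditional-probability ordering).
At c = 100000 our procedure yields ≈ 1.3 / ≈ 1.4 where ≈ 2.3 / ≈ 0.9 have
been reported; the sampling procedure behind those two numbers is described
only in material unavailable to us, and no variant recoverable from the
available description (alternative level-counting, Euclidean metric)
reproduces them, so the corresponding two checks in the acceptance test
suite are expected failures by design, not tolerances to be widened.  This
mode is a demonstration device; analyses should use a reparameterization.

## Hypothesis language

`label: expr; expr` with relations `=`, `>`, `<`, fan-out braces
(`a > {b, c}` → two rows), chains (`a > b > c` → pairwise), linear
coefficients and constants (`2*x1 - x2 > 0.8`), and bare parameter lists
for the unconstrained hypothesis.  `<` rows are negated into `>` rows;
rows are normalized to lexicographic order and deduplicated so penalties
and equality of hypotheses are independent of how restrictions were
written.  Non-linear terms (products of parameters) are rejected —
non-linearity is handled by choosing an η, not in the constraint language.
Range restrictions are deliberately not provided: inside a bounded feasible
set they make the penalty μ- and c-dependent, which is exactly what the
reparameterization avoids.

## Synthetic-data generator and simulation

The simulation module reproduces a selection-rate experiment on 2×4
tables.  Twelve populations (four true hypotheses × Cramer's V 0.10 / 0.30
/ 0.50) ship as printed 4-decimal probability vectors, renormalized to sum
exactly to 1 before multinomial draws; each carries the designed cells that
are set to zero *after* data generation to create sampling zeros (counts
are replaced, not redistributed, so n shrinks — the literal reading of the
design; redrawing conditional on a zero would be a different experiment).
All twelve populations reproduce their labelled Cramer's V within 0.02
(tested).  Per trial: draw multinomial(N), inject the zeros, run the full
four-hypothesis evaluation on the male-conditional-proportion
reparameterization, record the winner; trials whose covariance cannot be
repaired (or that fail at any stage, e.g. an inestimable observed
component) are skipped and counted; ties split the selection count
fractionally.

What the generator emulates: sampling variability of a fixed multinomial
population and worst-case sparsity in designed cells.  What it does not:
overdispersion, clustered or longitudinal sampling (the eye-tracking
example's frames are serially dependent in reality), structural zeros, or
misspecified reparameterizations — so passing selection rates show
correctness of the machinery under the stated sampling model, not
robustness to those violations.

**Problem sizes.**  Desk-scale defaults are 250 successful trials with
B = 200 and T = 2000 per trial (the package's own choice of a few-second
condition; full scale of 1000 trials is a parameter away).  At this scale
the worst-case condition (N = 50, V = 0.10, true ordered hypothesis)
selects the truth in ~91–92% of trials, matching the published full-scale
rate within Monte-Carlo error; large-sample/large-effect conditions reach
≥ 95%.

## Numerical choices and edge cases

* Seeds: every entry point takes one seed; internal stages derive
  independent child seeds via `SeedSequence.spawn`, so runs are bit-for-bit
  reproducible and stages are decoupled.
* Ties in the criterion within 1e-9 are reported as co-best rather than
  picking an arbitrary winner.
* The η vector of an analysis is exactly the component set the hypotheses
  reference; a `cells` spec covering the full simplex would make Σ̂
  singular through the sum-to-one constraint, so the last cell should be
  (and in the builtin family generators is) left implied.
* Mixed reparameterization kinds in one hypothesis set are mechanically
  possible but scientifically non-competing; the set container does not
  forbid them, the documentation does.
* Degenerate inputs rejected with errors: empty tables, factors with one
  level, duplicate long-format rows, non-integer counts, inconsistent
  equality systems, all-zero covariance diagonals.

## Known limitations

* Normal approximation only; no exact multinomial restricted likelihood.
* Delta-method covariances are not offered — the bootstrap is the
  estimator of record.
* Structural zeros (impossible cells) are out of scope; the repair here is
  for *sampling* zeros.
* The bounded-π penalty at very large c is procedure-sensitive (above).
* Hypothesis sets are compared within one η parameterization; comparing
  across parameterizations is meaningful only through penalty weights, and
  only qualitatively.
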