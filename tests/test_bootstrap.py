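import numpy as np
import pytest

import goricatab as gt
from goricatab.bootstrap import (EstimationResult, adjust_covariance,
                                 bootstrap_estimate, ensure_positive_definite,
                                 is_positive_definite)
from goricatab.reparam import builtin_spec
from goricatab.tables import ContingencyTable


class TestBootstrapEstimate:
    def test_point_estimate_is_observed_ratio(self, degrees, degrees_spec):
        est = bootstrap_estimate(degrees, degrees_spec, B=200, seed=0)
        assert np.allclose(np.round(est.eta_hat.values, 3),
                           [0.415, 0.393, 0.463, 0.500])
        assert est.discarded == 0 and est.adjustment == "none"

    def test_variance_matches_binomial_delta_method(self, degrees,
                                                    degrees_spec):
        # each conditional proportion is a binomial fraction of its column
        # total, so Var(eta_j) ~ eta_j (1 - eta_j) / n_col
        est = bootstrap_estimate(degrees, degrees_spec, B=4000, seed=1)
        eta = est.eta_hat.values
        col_totals = degrees.counts.sum(axis=0)
        expected = eta * (1 - eta) / col_totals
        assert np.allclose(np.diag(est.sigma_hat), expected, rtol=0.15)

    def test_reported_variances_recovered(self, degrees, degrees_spec):
        est = bootstrap_estimate(degrees, degrees_spec, B=4000, seed=2)
        assert np.allclose(np.diag(est.sigma_hat),
                           [1.4e-4, 3.7e-4, 2.8e-3, 5.2e-3], rtol=0.15)

    def test_deterministic_under_fixed_seed(self, degrees, degrees_spec):
        a = bootstrap_estimate(degrees, degrees_spec, B=100, seed=9)
        b = bootstrap_estimate(degrees, degrees_spec, B=100, seed=9)
        assert np.array_equal(a.sigma_hat, b.sigma_hat)

    def test_inestimable_observed_component_rejected(self):
        t = ContingencyTable(np.array([[5, 0, 15, 7], [3, 8, 0, 6]]))
        spec = builtin_spec("local_odds_ratio", t.dims)
        with pytest.raises(ValueError, match="inestimable"):
            bootstrap_estimate(t, spec, B=50, seed=0)

    def test_discard_ceiling_enforced(self):
        # a denominator cell that vanishes in ~37% of replicates trips a
        # 20% ceiling
        t = ContingencyTable(np.array([[1, 200], [0, 200]]))
        spec = builtin_spec("conditional_row", t.dims, level=1)
        with pytest.raises(ValueError, match="discard fraction"):
            bootstrap_estimate(t, spec, B=400, seed=3,
                               max_discard_fraction=0.2)

    def test_consistency_with_growing_sample(self):
        # estimates converge to the population values and n * Sigma settles
        pop = gt.load_fixture("sim_case1_phi30")
        spec = builtin_spec("conditional_row", (2, 4), level=1)
        truth = gt.eta_value(spec, pop).values
        errs, scaled = [], []
        for n in (200, 2000, 20000):
            rng = np.random.default_rng(n)
            counts = rng.multinomial(n, pop.values).reshape(2, 4)
            est = bootstrap_estimate(ContingencyTable(counts), spec,
                                     B=600, seed=5)
            errs.append(np.linalg.norm(est.eta_hat.values - truth))
            scaled.append(n * np.diag(est.sigma_hat))
        assert errs[2] < errs[0]
        assert np.allclose(scaled[1], scaled[2], rtol=0.5)

    def test_json_round_trip(self, degrees, degrees_spec):
        est = bootstrap_estimate(degrees, degrees_spec, B=50, seed=4)
        back = EstimationResult.from_json(est.to_json())
        assert np.allclose(back.sigma_hat, est.sigma_hat)
        assert back.eta_hat.flags == est.eta_hat.flags


class TestCovarianceAdjustment:
    def test_zero_diagonal_replaced_by_min(self):
        sig = np.array([[4.0, 0.0, 1.0], [0.0, 0.0, 0.0], [1.0, 0.0, 2.0]])
        adj, applied = adjust_covariance(sig, "min")
        assert applied == "min"
        assert adj[1, 1] == 2.0
        assert adj[1, 0] == adj[0, 1] == adj[1, 2] == 0.0
        assert adj[0, 2] == 1.0

    @pytest.mark.parametrize("strategy,value", [("min", 2.0), ("mean", 3.0),
                                                ("max", 4.0)])
    def test_strategies(self, strategy, value):
        sig = np.diag([4.0, 0.0, 2.0])
        adj, _ = adjust_covariance(sig, strategy)
        assert adj[1, 1] == value

    def test_no_zero_diagonal_is_identity(self):
        sig = np.eye(3)
        adj, applied = adjust_covariance(sig, "min")
        assert applied == "none" and np.array_equal(adj, sig)

    def test_idempotent(self):
        sig = np.diag([4.0, 0.0, 2.0])
        once, _ = adjust_covariance(sig, "min")
        twice, applied = adjust_covariance(once, "min")
        assert applied == "none" and np.array_equal(once, twice)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all diagonal"):
            adjust_covariance(np.zeros((2, 2)))

    def test_eyetracking_zero_rows_filled_with_smallest_variance(
            self, eye_reported):
        # reconstruct the raw (unadjusted) matrix and repair it
        _, adjusted = eye_reported
        raw = adjusted.copy()
        raw[2, 2] = raw[3, 3] = 0.0
        repaired, applied = adjust_covariance(raw, "min")
        assert applied == "min"
        assert repaired[2, 2] == repaired[3, 3] == pytest.approx(3.2e-7)
        assert np.allclose(repaired, adjusted)


class TestEnsurePositiveDefinite:
    def _result(self, sigma):
        k = sigma.shape[0]
        ev = gt.EtaVector(np.zeros(k), ["ok"] * k,
                          [f"eta{i+1}" for i in range(k)])
        return EstimationResult(ev, sigma, B=10)

    def test_min_strategy_suffices_for_gaze_matrix(self, eye_reported):
        _, adjusted = eye_reported
        raw = adjusted.copy()
        raw[2, 2] = raw[3, 3] = 0.0
        out = ensure_positive_definite(self._result(raw))
        assert out.adjustment == "min"
        assert is_positive_definite(out.sigma_hat)

    def test_identity_untouched(self):
        out = ensure_positive_definite(self._result(np.eye(3)))
        assert out.adjustment == "none"

    def test_duplicated_rows_fail_after_max(self):
        sig = np.ones((3, 3))  # rank one, no zero diagonal to repair
        with pytest.raises(np.linalg.LinAlgError):
            ensure_positive_definite(self._result(sig))

    def test_simulation_style_zero_variance_component(self):
        # an injected-zero table gives a constant eta component whose zero
        # variance must be repaired for the pipeline to proceed
        pop = gt.load_fixture("sim_case1_phi10")
        rng = np.random.default_rng(123)
        counts = rng.multinomial(50, pop.values).reshape(2, 4)
        counts[1, 2] = 0
        spec = builtin_spec("conditional_row", (2, 4), level=1)
        est = bootstrap_estimate(ContingencyTable(counts), spec, B=200,
                                 seed=7)
        assert est.sigma_hat[2, 2] == 0.0
        out = ensure_positive_definite(est)
        assert out.adjustment in ("min", "mean", "max")
        assert is_positive_definite(out.sigma_hat)
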