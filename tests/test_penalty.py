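import numpy as np
import pytest

import goricatab as gt
from goricatab.hypotheses import parse, unconstrained
from goricatab.penalty import (BoundedPenaltyConfig, penalty_bounded_pi,
                               penalty_closed_form, penalty_mc)

N2, N4 = ["x1", "x2"], ["x1", "x2", "x3", "x4"]


class TestClosedForm:
    def test_unconstrained_keeps_all_parameters(self):
        pen = penalty_closed_form(unconstrained(N4))
        assert pen.pt == 4.0 and pen.level_probs[4] == 1.0

    def test_equality_chain_removes_rank(self):
        pen = penalty_closed_form(parse("x1 = x2 = x3 = x4", N4))
        assert pen.pt == 1.0

    def test_twelve_marginals_four_equalities(self, eye_hset):
        pen = penalty_closed_form(eye_hset.hypotheses[2])
        assert pen.pt == 8.0

    def test_redundant_equalities_counted_by_rank(self):
        pen = penalty_closed_form(parse("x1 = x2; 2*x1 - 2*x2 = 0", N2))
        assert pen.pt == 1.0

    def test_inequalities_defer_to_monte_carlo(self):
        assert penalty_closed_form(parse("x1 > x2", N2)) is None


class TestMonteCarlo:
    def test_two_orthant_constraints_identity(self):
        pen = penalty_mc(parse("x1 > 0; x2 > 0", N2), np.eye(2), T=40000,
                         seed=1)
        assert pen.pt == pytest.approx(1.0, abs=3 * pen.mc_se + 0.01)
        assert pen.level_probs[1] == pytest.approx(0.50, abs=0.02)
        assert pen.level_probs[2] == pytest.approx(0.25, abs=0.02)

    def test_single_difference_constraint(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((2, 4))
        sigma = a @ a.T / 4 + 0.2 * np.eye(2)
        sigma[0, 0] = sigma[1, 1] = 1.0  # equal variances
        pen = penalty_mc(parse("x1 > x2", N2), sigma, T=40000, seed=2)
        assert pen.pt == pytest.approx(1.5, abs=3 * pen.mc_se + 0.01)

    def test_correlated_orthant_probability_oracle(self):
        # P(both > 0) for an equicorrelated pair has the closed form
        # 1/4 + asin(rho) / (2 pi)
        rho = 0.6
        sigma = np.array([[1.0, rho], [rho, 1.0]])
        pen = penalty_mc(parse("x1 > 0; x2 > 0", N2), sigma, T=60000, seed=3)
        lp2 = 0.25 + np.arcsin(rho) / (2 * np.pi)
        se = np.sqrt(lp2 * (1 - lp2) / 60000)
        assert pen.level_probs[2] == pytest.approx(lp2, abs=3 * se + 0.003)

    def test_equality_only_hits_single_level_exactly(self):
        pen = penalty_mc(parse("x1 = x2", N2), np.eye(2), T=2000, seed=4)
        assert pen.pt == 1.0 and pen.mc_se == 0.0
        assert pen.level_probs[1] == 1.0

    def test_degrees_fan_out_penalty(self, degrees_reported):
        _, sig = degrees_reported
        pen = penalty_mc(parse("x1 > {x2, x3, x4}", N4), sig, T=40000, seed=5)
        assert pen.pt == pytest.approx(2.547, abs=0.04)

    def test_relocation_makes_constants_irrelevant(self):
        sigma = np.array([[1.0, 0.3], [0.3, 1.0]])
        a = penalty_mc(parse("x1 - x2 > 0.8", N2), sigma, T=20000, seed=6)
        b = penalty_mc(parse("x1 - x2 > 0", N2), sigma, T=20000, seed=6)
        assert a.pt == b.pt

    def test_scale_invariance_of_relocated_cones(self, degrees_reported):
        # multiplying the covariance by c leaves the penalty unchanged up
        # to Monte-Carlo error
        _, sig = degrees_reported
        for text in ["x1 > {x2, x3, x4}", "x1 = x2, x3 > x4",
                     "x1 > x2 > x3 > x4"]:
            h = parse(text, N4)
            a = penalty_mc(h, sig, T=20000, seed=7)
            b = penalty_mc(h, 1e5 * sig, T=20000, seed=8)
            tol = 3 * np.hypot(a.mc_se, b.mc_se)
            assert abs(a.pt - b.pt) <= tol + 1e-9, text

    @pytest.mark.parametrize("text,k,h_r", [
        ("x1 > x2", 2, 1),
        ("x1 > 0; x2 > 0", 2, 2),
        ("x1 > x2 > x3 > x4", 4, 3),
    ])
    def test_sandwich_bounds(self, text, k, h_r):
        names = N4[:k]
        pen = penalty_mc(parse(text, names), np.eye(k), T=5000, seed=9)
        assert k - h_r - 1e-9 <= pen.pt <= k + 1e-9
        assert pen.level_probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_small_T_warns(self):
        with pytest.warns(UserWarning, match="Monte-Carlo"):
            penalty_mc(parse("x1 > x2", N2), np.eye(2), T=500, seed=10)

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            penalty_mc(parse("x1 > x2", N2),
                       np.array([[1.0, 2.0], [2.0, 1.0]]), T=2000)


class TestBoundedPi:
    @pytest.fixture(scope="class")
    def sigma_pi(self, degrees):
        return gt.bootstrap_cell_covariance(degrees, B=2000, seed=3)

    def test_unconstrained_inside_simplex_keeps_all_free(self, degrees_spec,
                                                         sigma_pi):
        # at c = 1 the null mass sits deep inside the simplex, so every
        # sample keeps the D - 1 free cell probabilities
        pen = penalty_bounded_pi(None, degrees_spec, sigma_pi,
                                 BoundedPenaltyConfig(c=1.0, T=2000), seed=5)
        assert pen.pt == pytest.approx(7.0, abs=0.05)

    def test_penalty_depends_on_scale(self, degrees_spec, sigma_pi):
        # unlike the relocated-cone penalty, the bounded one shrinks once
        # the inspected space outgrows the simplex
        pen = penalty_bounded_pi(None, degrees_spec, sigma_pi,
                                 BoundedPenaltyConfig(c=1e5, T=1000), seed=5)
        assert pen.pt < 6.0

    def test_ratio_constraints_at_unit_scale(self, degrees_spec, sigma_pi):
        h1 = parse("eta1 > {eta2, eta3, eta4}", degrees_spec.names)
        pen = penalty_bounded_pi(h1, degrees_spec, sigma_pi,
                                 BoundedPenaltyConfig(c=1.0, T=400), seed=5)
        assert pen.pt == pytest.approx(6.322, abs=0.2)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BoundedPenaltyConfig(c=-1.0)
        with pytest.raises(ValueError):
            BoundedPenaltyConfig(mu=np.array([0.5, 0.7]))


class TestSerialization:
    def test_penalty_result_json(self):
        pen = penalty_mc(parse("x1 > x2", N2), np.eye(2), T=2000, seed=11)
        import json
        d = json.loads(pen.to_json())
        assert d["T"] == 2000 and len(d["level_probs"]) == 3
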