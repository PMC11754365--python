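import numpy as np
import pytest

import goricatab as gt
from goricatab.hypotheses import parse_set
from goricatab.selection import (EvaluateConfig, evaluate_set, gorica_value,
                                 gorica_weights, penalty_weights)

# reported (loglik, penalty, criterion, weight) rows for the two examples
DEGREES_ROWS = [
    ("H1", 9.214, 2.584, -13.261, 0.238),
    ("H2", 9.694, 2.505, -14.377, 0.415),
    ("H3", 8.544, 2.182, -12.724, 0.182),
    ("Hu", 10.267, 4.000, -12.535, 0.165),
]
# the H4 criterion value is published truncated to two decimals (-106.96)
EYE_ROWS = [
    ("H1", 67.228, 9.983, -114.490, 0.182),
    ("H2", 68.654, 10.044, -117.220, 0.712),
    ("H3", 59.779, 8.000, -103.559, 0.001),
    ("H4", 61.481, 8.000, -106.96, 0.004),
    ("Hu", 68.654, 12.000, -113.308, 0.101),
]


def printed_tol(value: float) -> float:
    """Half a unit in the last printed decimal place, plus rounding slack."""
    decimals = len(str(value).rsplit(".", 1)[1])
    return 0.002 + 0.5 * 10 ** -decimals if decimals < 3 else 0.002


class TestArithmetic:
    @pytest.mark.parametrize("loglik,pt,value", [
        (9.214, 2.584, -13.260),
        (0.0, 0.0, 0.0),
        (68.654, 10.044, -117.220),
    ])
    def test_gorica_value(self, loglik, pt, value):
        assert gorica_value(loglik, pt) == pytest.approx(value, abs=1e-9)

    @pytest.mark.parametrize("rows", [DEGREES_ROWS, EYE_ROWS])
    def test_printed_rows_reproduce(self, rows):
        # each printed criterion value follows from its printed (fit, penalty)
        for _, loglik, pt, value, _ in rows:
            assert gorica_value(loglik, pt) == pytest.approx(
                value, abs=printed_tol(value))

    @pytest.mark.parametrize("rows", [DEGREES_ROWS, EYE_ROWS])
    def test_printed_weights_reproduce(self, rows):
        values = [r[3] for r in rows]
        expected = [r[4] for r in rows]
        assert np.allclose(gorica_weights(values), expected, atol=0.002)

    def test_equal_values_split_evenly(self):
        assert np.allclose(gorica_weights([3.0, 3.0]), [0.5, 0.5])

    def test_evidence_ratio_closed_form(self):
        w = gorica_weights([0.0, 2 * np.log(9)])
        assert w[0] / w[1] == pytest.approx(9.0)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = gorica_weights(rng.normal(size=5) * 40)
            assert w.sum() == pytest.approx(1.0, abs=1e-10)
            assert (w >= 0).all()

    @pytest.mark.parametrize("pts,expected", [
        ((6.322, 7.000), (0.663, 0.337)),
        ((2.547, 4.000), (0.810, 0.190)),
        ((1.000, 4.000), (0.953, 0.047)),
    ])
    def test_penalty_weights(self, pts, expected):
        assert np.allclose(np.round(penalty_weights(pts), 3), expected)


class TestEvaluateSet:
    @pytest.fixture(scope="class")
    def degrees_result(self, degrees, degrees_spec, degrees_hset):
        return evaluate_set(degrees, degrees_spec, degrees_hset,
                            EvaluateConfig(B=600, T=6000, seed=11))

    def test_h2_selected_for_degrees(self, degrees_result):
        assert degrees_result.best == ["H2"]
        w = dict(zip(degrees_result.labels, degrees_result.weights))
        assert w["H2"] == pytest.approx(0.415, abs=0.05)

    def test_table_invariants(self, degrees_result):
        r = degrees_result
        assert r.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert r.penalty_wts.sum() == pytest.approx(1.0, abs=1e-10)
        assert r.labels[int(np.argmax(r.weights))] in r.best
        assert np.allclose(r.values, -2 * r.logliks + 2 * r.penalties)

    def test_support_ratios_are_weight_ratios(self, degrees_result):
        w = dict(zip(degrees_result.labels, degrees_result.weights))
        assert w["H2"] / w["H1"] == pytest.approx(0.415 / 0.238, rel=0.25)

    def test_failsafe_preserves_relative_weights(self, degrees, degrees_spec,
                                                 degrees_hset):
        cfg = EvaluateConfig(B=400, T=4000, seed=21)
        with_u = evaluate_set(degrees, degrees_spec, degrees_hset, cfg)
        bare = gt.HypothesisSet(degrees_hset.hypotheses[:3],
                                include_unconstrained=False)
        without_u = evaluate_set(degrees, degrees_spec, bare, cfg)
        ratios_with = with_u.weights[:3] / with_u.weights[:3].sum()
        assert np.allclose(ratios_with, without_u.weights, atol=1e-9)

    def test_equality_only_set_reduces_to_aic(self, degrees, degrees_spec):
        # with equality-only hypotheses PT = K - rank(S), so the ranking is
        # the AIC ranking of the same normal-approximation fits
        hset = parse_set(
            "Ha: eta1 = eta2\nHb: eta1 = eta2 = eta3 = eta4",
            degrees_spec.names)
        res = evaluate_set(degrees, degrees_spec, hset,
                           EvaluateConfig(B=400, T=1000, seed=31))
        k = 4
        ranks = {"Ha": 3, "Hb": 1, "Hu": 4}
        aic = [-2 * l + 2 * ranks[lab]
               for lab, l in zip(res.labels, res.logliks)]
        assert np.allclose(res.values, aic)
        assert np.argsort(res.values).tolist() == np.argsort(aic).tolist()
        assert res.penalties.tolist() == [3.0, 1.0, float(k)]

    def test_single_unconstrained_hypothesis(self, degrees, degrees_spec):
        hset = parse_set("Hu: eta1, eta2, eta3, eta4", degrees_spec.names,
                         include_unconstrained=False)
        res = evaluate_set(degrees, degrees_spec, hset,
                           EvaluateConfig(B=200, T=1000, seed=41))
        assert res.weights.tolist() == [1.0]

    def test_ties_reported_as_co_best(self, degrees, degrees_spec):
        hset = parse_set("Ha: eta1 = eta2\nHb: eta1 = eta2",
                         degrees_spec.names, include_unconstrained=False)
        # same constraints -> identical fits and penalties -> exact tie
        hset.hypotheses[1].label = "Hb"
        res = evaluate_set(degrees, degrees_spec, hset,
                           EvaluateConfig(B=300, T=1000, seed=51))
        assert res.best == ["Ha", "Hb"]

    def test_report_writers(self, degrees_result, tmp_path):
        txt = degrees_result.to_text()
        assert "H2" in txt and "best" in txt
        import json
        d = json.loads(degrees_result.to_json())
        assert {r["hypothesis"] for r in d["rows"]} == {"H1", "H2", "H3", "Hu"}
        df = degrees_result.to_dataframe()
        assert list(df.columns) == ["hypothesis", "loglik", "penalty",
                                    "gorica", "weight", "penalty_weight"]
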