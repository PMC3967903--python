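"""Model set, AICc arithmetic, averaging, and BLUP-derived defense."""

import numpy as np
import pandas as pd
import pytest

from feederdef import inference
from feederdef.inference import (ModelSpec, aicc, akaike_weights,
                                 blup_slopes, build_model_set,
                                 model_average)
from feederdef.lmm import LMMResult


class TestModelSet:
    def test_ten_models_with_shared_controls(self):
        specs = build_model_set()
        assert [s.model_id for s in specs] == list(range(1, 11))
        for s in specs:
            for t in inference.CONTROL_TERMS:
                assert t in s

    def test_baseline_models_lack_concentration(self):
        specs = build_model_set()
        for s in specs[:2]:
            assert "spatial_concentration" not in s
            assert not any("spatial_concentration" in t
                           for t in s.fixed_terms)
        for s in specs[2:]:
            assert "spatial_concentration" in s

    def test_full_model_has_all_fifteen_terms(self):
        full = build_model_set()[-1]
        assert len(full.fixed_terms) == 15
        assert set(full.fixed_terms) == set(inference.FULL_TERMS)

    def test_three_way_membership(self):
        term = "spatial_concentration:openness:lateral_visibility"
        has = [s.model_id for s in build_model_set() if term in s]
        assert has == [4, 5, 6, 9, 10]

    def test_sucrose_interaction_only_in_full_model(self):
        term = "spatial_concentration:sucrose"
        has = [s.model_id for s in build_model_set() if term in s]
        assert has == [10]

    def test_single_term_omissions(self):
        by_id = {s.model_id: set(s.fixed_terms) for s in build_model_set()}
        assert "daily_visits" not in by_id[4]
        assert "spatial_stability" not in by_id[5]
        assert "spatial_concentration:n_competitors" not in by_id[6]
        assert "openness" not in by_id[7]
        assert "openness" in by_id[8]


def _mock_fit(coefs, ses, method="REML", n=100, loglik=-50.0,
              n_vparams=4):
    names = list(coefs)
    return LMMResult(method=method,
                     coefficients=pd.Series(coefs),
                     se=pd.Series(ses),
                     cov_fixed=pd.DataFrame(np.diag([s ** 2 for s in
                                                     ses.values()]),
                                            index=names, columns=names),
                     loglik=loglik, n=n, n_fixed=len(coefs),
                     n_vparams=n_vparams, vparams={},
                     blups=pd.DataFrame({"tag_id": [], "intercept": [],
                                         "slope": []}),
                     converged=True, singular=False, random_slope=True)


class TestAicc:
    def test_hand_arithmetic(self):
        fit = _mock_fit({"Intercept": 0.0}, {"Intercept": 1.0},
                        method="ML", n=50, loglik=-50.0, n_vparams=3)
        # K = 1 fixed + 3 + 1 residual = 5; 100 + 10 + 60/44
        assert aicc(fit) == pytest.approx(100 + 10 + 60 / 44)

    def test_large_n_limit(self):
        fit = _mock_fit({"Intercept": 0.0}, {"Intercept": 1.0},
                        method="ML", n=10 ** 9, loglik=-50.0)
        assert aicc(fit) == pytest.approx(100 + 2 * 6, abs=1e-5)

    def test_extra_parameter_increases_penalty(self):
        f1 = _mock_fit({"a": 0.0}, {"a": 1.0}, method="ML", n=60)
        f2 = _mock_fit({"a": 0.0, "b": 0.0}, {"a": 1.0, "b": 1.0},
                       method="ML", n=60)
        assert aicc(f2) > aicc(f1)

    def test_requires_ml_and_enough_data(self):
        with pytest.raises(ValueError):
            aicc(_mock_fit({"a": 0.0}, {"a": 1.0}, method="REML"))
        with pytest.raises(ValueError):
            aicc(_mock_fit({"a": 0.0}, {"a": 1.0}, method="ML", n=6))


class TestAkaikeWeights:
    def test_symmetric_pair(self):
        assert np.allclose(akaike_weights([0.0, 0.0]), [0.5, 0.5])

    def test_closed_form_delta_two(self):
        w = akaike_weights([0.0, 2.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def test_sum_to_one_and_best_model_heaviest(self):
        w = akaike_weights([3.2, 0.0, 11.0, 1.4])
        assert w.sum() == pytest.approx(1.0)
        assert np.argmax(w) == 1


class TestModelAverage:
    def test_hand_example_zero_substitution(self):
        f1 = _mock_fit({"Intercept": 0.0, "x": 1.0},
                       {"Intercept": 0.0, "x": 0.0})
        f2 = _mock_fit({"Intercept": 0.0}, {"Intercept": 0.0})
        out = model_average([f1, f2], [0.5, 0.5])
        assert out.loc["x", "coef"] == pytest.approx(0.5)
        assert out.loc["x", "unconditional_se"] == pytest.approx(0.5)

    def test_agreeing_models_pass_through(self):
        f1 = _mock_fit({"x": 0.7}, {"x": 0.1})
        f2 = _mock_fit({"x": 0.7}, {"x": 0.1})
        out = model_average([f1, f2], [0.3, 0.7])
        assert out.loc["x", "coef"] == pytest.approx(0.7)
        assert out.loc["x", "unconditional_se"] == pytest.approx(0.1)

    def test_ci_is_coef_pm_196_se(self):
        f1 = _mock_fit({"x": -0.09017}, {"x": 0.03778})
        out = model_average([f1], [1.0])
        assert out.loc["x", "ci_lower"] == pytest.approx(
            -0.09017 - 1.96 * 0.03778)
        assert out.loc["x", "ci_upper"] == pytest.approx(
            -0.09017 + 1.96 * 0.03778)

    def test_shrinkage_and_variance_inflation_bounds(self):
        f1 = _mock_fit({"x": 1.2}, {"x": 0.2})
        f2 = _mock_fit({"x": -0.4, "z": 1.0}, {"x": 0.3, "z": 0.1})
        w = [0.6, 0.4]
        out = model_average([f1, f2], w)
        assert abs(out.loc["x", "coef"]) <= 1.2
        weighted_se = 0.6 * 0.2 + 0.4 * 0.3
        assert out.loc["x", "unconditional_se"] >= weighted_se

    def test_natural_averaging_renormalizes(self):
        f1 = _mock_fit({"x": 1.0}, {"x": 0.0})
        f2 = _mock_fit({"y": 2.0}, {"y": 0.0})
        out = model_average([f1, f2], [0.5, 0.5], method="natural")
        assert out.loc["x", "coef"] == pytest.approx(1.0)
        assert out.loc["y", "coef"] == pytest.approx(2.0)


class TestBlupSlopes:
    def _fit_with_blups(self, fixed_slope, blup_by_tag):
        f = _mock_fit({"spatial_concentration": fixed_slope},
                      {"spatial_concentration": 0.1})
        f.blups = pd.DataFrame({
            "tag_id": list(blup_by_tag),
            "intercept": 0.0,
            "slope": list(blup_by_tag.values())})
        return f

    def test_zero_blup_gives_population_value(self):
        table = pd.DataFrame({"daily_visits": [10.0],
                              "n_competitors": [2.0],
                              "spatial_stability": [0.5],
                              "lateral_visibility_m": [5.0]})
        f = self._fit_with_blups(-1.0, {"a": 0.0, "b": -0.5})
        out = blup_slopes([f], [1.0], table).set_index("tag_id")
        assert out.loc["a", "total_slope"] == pytest.approx(-1.0)
        assert out.loc["a", "nvc_reduction_pct"] == pytest.approx(
            100 * (1 - np.exp(-1)), abs=1e-6)
        assert out.loc["b", "total_slope"] == pytest.approx(-1.5)

    def test_zero_total_slope_means_no_reduction(self):
        table = pd.DataFrame({"daily_visits": [0.0], "n_competitors": [0.0],
                              "spatial_stability": [0.0],
                              "lateral_visibility_m": [0.0]})
        f = self._fit_with_blups(0.0, {"a": 0.0})
        out = blup_slopes([f], [1.0], table)
        assert out["nvc_reduction_pct"].iloc[0] == pytest.approx(0.0)

    def test_interactions_evaluated_at_covariate_means(self):
        table = pd.DataFrame({"daily_visits": [10.0, 30.0],
                              "n_competitors": [2.0, 4.0],
                              "spatial_stability": [0.0, 1.0],
                              "lateral_visibility_m": [0.0, 0.0]})
        f = self._fit_with_blups(-0.2, {"a": 0.0})
        f.coefficients["spatial_concentration:spatial_stability"] = -0.8
        f.se["spatial_concentration:spatial_stability"] = 0.1
        out = blup_slopes([f], [1.0], table)
        assert out["total_slope"].iloc[0] == pytest.approx(
            -0.2 + (-0.8) * 0.5)


def test_fit_model_set_order_and_convergence(small_analysis_table):
    ml, reml = inference.fit_model_set(small_analysis_table)
    assert len(ml) == len(reml) == 10
    assert all(f.method == "ML" for f in ml)
    assert all(f.method == "REML" for f in reml)
    sel = inference.selection_table(ml)
    assert sel["weight"].sum() == pytest.approx(1.0)
    assert sel.loc[sel["aicc"].idxmin(), "weight"] == sel["weight"].max()


def test_random_slope_support_is_deterministic(small_analysis_table):
    a = inference.random_slope_support(small_analysis_table)
    b = inference.random_slope_support(small_analysis_table)
    assert a == b
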