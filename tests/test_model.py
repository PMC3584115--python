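"""Diagnostic model: scoring, ML fitting, stepwise selection, LOESS cutoff."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from gate50 import (
    ModelCoefficients,
    Term,
    estimate_cutoff,
    fit_logistic,
    odds_ratios,
    score_probability,
    score_table,
    simulate_model_cohort,
    stepwise_select,
)
from gate50.errors import (
    ConfigurationError,
    NoCutoffError,
    ScoringError,
    SeparationError,
    SingularDesignError,
)


class TestScoring:
    def test_all_zero_covariates_give_intercept_probability(self, published):
        rec = dict.fromkeys(
            ["gating", "cpt_d", "arithmetic", "block_design", "piq", "smoker"], 0
        )
        p = score_probability(rec, published)
        assert p == pytest.approx(special.expit(10.20), abs=1e-6)

    def test_patient_mean_covariates(self, published):
        rec = {"gating": 1, "cpt_d": -0.71, "arithmetic": 8.38,
               "block_design": 9.93, "piq": 90.58, "smoker": 0}
        p = score_probability(rec, published)
        eta = (10.20 + 1.00 - 0.37 * (-0.71) - 0.32 * 8.38
               + 0.28 * 9.93 - 0.19 * 90.58)
        assert p == pytest.approx(special.expit(eta), abs=1e-9)
        assert p == pytest.approx(0.0035, abs=0.0005)

    def test_arithmetic_unit_change_multiplies_odds(self, published):
        base = {"gating": 0, "cpt_d": 0, "arithmetic": 10, "block_design": 0,
                "piq": 100, "smoker": 0}
        p0 = score_probability(base, published)
        p1 = score_probability({**base, "arithmetic": 11}, published)
        odds_ratio = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert odds_ratio == pytest.approx(np.exp(-0.32), rel=1e-9)
        assert round(odds_ratio, 2) == 0.73

    def test_missing_covariate_named_in_error(self, published):
        with pytest.raises(ScoringError, match="piq"):
            score_probability({"gating": 0, "cpt_d": 0, "arithmetic": 0,
                               "block_design": 0, "smoker": 0}, published)

    def test_monotone_in_each_covariate(self, published):
        base = {"gating": 0, "cpt_d": 0, "arithmetic": 10, "block_design": 10,
                "piq": 95, "smoker": 0}
        p0 = score_probability(base, published)
        for name in ("cpt_d", "arithmetic", "piq", "block_design", "smoker",
                     "gating"):
            sign = np.sign(published.get(name).coef)
            p1 = score_probability({**base, name: base[name] + 1}, published)
            assert np.sign(p1 - p0) == sign

    def test_score_table_derives_gating_from_ratio(self, published):
        table = pd.DataFrame({
            "ratio": [0.3, 0.5], "cpt_d": [0, 0], "arithmetic": [10, 10],
            "block_design": [10, 10], "piq": [95, 95], "smoker": [0, 0],
        })
        probs = score_table(table, published)
        # the only difference is gating 0 vs 1: odds ratio e^1.0
        or_ = (probs[1] / (1 - probs[1])) / (probs[0] / (1 - probs[0]))
        assert or_ == pytest.approx(np.e, rel=1e-9)


class TestOddsRatios:
    def test_published_table_reconstruction(self, published):
        table = odds_ratios(published).round(2)
        assert table.loc["gating", "odds_ratio"] == 2.72
        assert table.loc["cpt_d", "odds_ratio"] == 0.69
        assert table.loc["arithmetic", "odds_ratio"] == 0.73
        assert table.loc["block_design", "odds_ratio"] == 1.32

    def test_null_coefficient_symmetric_ci(self):
        coefs = ModelCoefficients([Term("Intercept", 0.0, 1.0),
                                   Term("x", 0.0, 0.5)])
        row = odds_ratios(coefs).loc["x"]
        assert row["odds_ratio"] == 1.0
        assert row["ci_low"] * row["ci_high"] == pytest.approx(1.0)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        df = pd.DataFrame({"group": [1] * 30 + [0] * 70})
        fit = fit_logistic(df, [])
        assert fit.coefficients.get("Intercept").coef == \
            pytest.approx(np.log(30 / 70), abs=1e-6)

    def test_two_by_two_closed_form(self):
        a, b, c, d = 20, 30, 10, 40  # exposed-case, unexposed-case, ...
        rows = ([{"group": 1, "x": 1}] * a + [{"group": 1, "x": 0}] * b
                + [{"group": 0, "x": 1}] * c + [{"group": 0, "x": 0}] * d)
        fit = fit_logistic(pd.DataFrame(rows), ["x"])
        assert fit.coefficients.get("x").coef == \
            pytest.approx(np.log(a * d / (b * c)), abs=1e-6)
        or_hat = odds_ratios(fit).loc["x", "odds_ratio"]
        assert or_hat == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_parameter_recovery_from_published_model(self, published):
        sim = simulate_model_cohort(published, 10_000, seed=11)
        fit = fit_logistic(sim, published.covariate_names())
        for term in fit.coefficients.terms:
            truth = published.get(term.name).coef
            assert abs(term.coef - truth) <= 3 * term.se
            if abs(truth) >= 0.1:
                assert abs(term.coef - truth) <= 0.05 * abs(truth) + 2 * term.se

    def test_separation_detected(self):
        df = pd.DataFrame({"group": [0] * 20 + [1] * 20,
                           "x": list(range(20)) + list(range(30, 50))})
        with pytest.raises(SeparationError):
            fit_logistic(df, ["x"])

    def test_singular_design_names_terms(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        df = pd.DataFrame({"group": (rng.random(100) < 0.5).astype(int),
                           "x": x, "y": 2 * x})
        with pytest.raises(SingularDesignError):
            fit_logistic(df, ["x", "y"])

    def test_single_class_rejected(self):
        df = pd.DataFrame({"group": [1] * 10, "x": range(10)})
        with pytest.raises(ConfigurationError):
            fit_logistic(df, ["x"])


class TestStepwise:
    @staticmethod
    def _sim(seed, n=1000):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = (rng.random(n) < special.expit(2 * x)).astype(int)
        return pd.DataFrame({"group": y, "x": x, "z": z})

    def test_strong_predictor_selected_noise_rarely(self):
        n_noise = 0
        for rep in range(40):
            fit = stepwise_select(self._sim(3000 + rep), ["x", "z"])
            names = fit.coefficients.names
            assert "x" in names
            n_noise += "z" in names
        assert n_noise <= 12  # ~nominal 15% entry rate, small-sample slack

    def test_boundary_sle_zero_gives_intercept_only(self):
        fit = stepwise_select(self._sim(1), ["x", "z"], sle=0.0, sls=0.0)
        assert fit.coefficients.names == ["Intercept"]

    def test_boundary_sle_one_gives_full_model(self):
        fit = stepwise_select(self._sim(2), ["x", "z"], sle=1.0, sls=1.0)
        assert set(fit.coefficients.names) == {"Intercept", "x", "z"}

    def test_audit_trail_records_entries(self):
        fit = stepwise_select(self._sim(5), ["x", "z"])
        assert any(s["action"] == "enter" and s["term"] == "x"
                   for s in fit.audit_trail)
        for step in fit.audit_trail:
            assert 0.0 <= step["p"] <= 1.0

    def test_published_terms_reselected_on_simulated_data(self, published):
        """On data generated from the published model, stepwise selection
        recovers the published covariate set in the majority of replicates."""
        hits = 0
        for rep in range(11):
            sim = simulate_model_cohort(published, 2000, seed=900 + rep)
            fit = stepwise_select(sim, published.covariate_names())
            hits += set(fit.coefficients.names) == \
                set(published.names)
        assert hits > 5


class TestCutoff:
    def test_known_step_recovered(self):
        rng = np.random.default_rng(2)
        ratio = rng.uniform(0, 0.8, 2000)
        eta = special.logit(0.35) + 1.0 * (ratio > 0.4)
        y = (rng.random(2000) < special.expit(eta)).astype(int)
        cut, curve = estimate_cutoff(pd.DataFrame({"ratio": ratio, "group": y}))
        assert cut == pytest.approx(0.4, abs=0.05)
        assert {"ratio", "risk", "log_odds"} <= set(curve.columns)

    def test_flat_curve_raises_with_curve_attached(self):
        tbl = pd.DataFrame({"ratio": np.linspace(0, 1, 120), "group": 0.4})
        with pytest.raises(NoCutoffError) as err:
            estimate_cutoff(tbl)
        assert len(err.value.curve) > 0

    def test_monotone_logit_crossing_matches_closed_form(self):
        rng = np.random.default_rng(9)
        a_, b_ = -2.0, 4.0
        x = rng.uniform(0, 1, 4000)
        y = (rng.random(4000) < special.expit(a_ + b_ * x)).astype(int)
        cut, _ = estimate_cutoff(pd.DataFrame({"ratio": x, "group": y}),
                                 span=0.4)
        expected = (special.logit(y.mean()) - a_) / b_
        assert cut == pytest.approx(expected, abs=0.05)

    def test_too_few_observations(self):
        tbl = pd.DataFrame({"ratio": np.linspace(0, 1, 30),
                            "group": [0, 1] * 15})
        with pytest.raises(ConfigurationError):
            estimate_cutoff(tbl)
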