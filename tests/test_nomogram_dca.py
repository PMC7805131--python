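"""Nomogram survival prediction and decision-curve analysis."""

import numpy as np
import pandas as pd
import pytest

from ctibm.nomogram_dca import (
    build_nomogram,
    compare_strategies,
    decision_curve,
    predict_survival,
)
from ctibm.synthetic import SurvivalTruth, generate_survival


def _cohort(lp, seed=0, **truth_kwargs):
    truth = SurvivalTruth(**truth_kwargs)
    surv = generate_survival(lp, truth, seed=seed)
    return surv


class TestNomogram:
    def test_null_score_predictions_match_marginal_km(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal(400)
        surv = _cohort(np.zeros(400), seed=1)
        model = build_nomogram(scores, surv)
        from ctibm.evaluation import km_estimate

        km = km_estimate(surv)
        for t in (12.0, 36.0, 60.0):
            probs, _ = predict_survival(model, 0.0, (t,))
            assert probs[t] == pytest.approx(
                float(km.survival_function_at_times(t).iloc[0]), abs=0.05
            )

    def test_recovers_exponential_truth(self):
        # two groups with known rates: S(t|x) should track exp(-rate t)
        x = np.concatenate([np.zeros(500), np.ones(500)])
        lp = np.log(3.0) * x
        surv = _cohort(lp, seed=2, baseline_rate=0.03,
                       censor_horizon=1e9, uniform_censor_max=1e9)
        model = build_nomogram(x.astype(float), surv)
        for score, rate in ((0.0, 0.03), (1.0, 0.09)):
            probs, _ = predict_survival(model, score, (24.0,))
            assert probs[24.0] == pytest.approx(np.exp(-rate * 24.0), abs=0.05)

    def test_points_scale_is_affine_over_training_range(self):
        scores = np.linspace(-2, 3, 50)
        surv = _cohort(scores, seed=3)
        model = build_nomogram(scores, surv)
        assert model.points(-2.0) == pytest.approx(0.0)
        assert model.points(3.0) == pytest.approx(100.0)
        assert model.points(0.5) == pytest.approx(50.0)

    def test_predictions_monotone_in_score_and_time(self):
        rng = np.random.default_rng(4)
        scores = rng.standard_normal(300)
        surv = _cohort(0.8 * scores, seed=5)
        model = build_nomogram(scores, surv)
        assert model.beta > 0
        s_at = [predict_survival(model, s, (60.0,))[0][60.0] for s in (-1.0, 0.0, 1.0)]
        assert s_at[0] > s_at[1] > s_at[2]  # higher score, lower survival
        probs, _ = predict_survival(model, 0.0, (12.0, 36.0, 60.0))
        vals = [probs[t] for t in (12.0, 36.0, 60.0)]
        assert vals[0] >= vals[1] >= vals[2]

    def test_median_not_reached_when_curve_stays_high(self):
        surv = _cohort(np.zeros(400), seed=6, baseline_rate=0.004, censor_horizon=24.0)
        scores = np.random.default_rng(7).standard_normal(400)
        model = build_nomogram(scores, surv)
        _, median = predict_survival(model, 0.0)
        assert median is None

    def test_extrapolation_warns(self):
        rng = np.random.default_rng(8)
        scores = rng.standard_normal(200)
        surv = _cohort(scores, seed=9)
        model = build_nomogram(scores, surv)
        with pytest.warns(UserWarning, match="outside the training range"):
            predict_survival(model, scores.max() + 5.0)

    def test_too_few_events_rejected(self):
        surv = pd.DataFrame({"time_months": np.arange(1.0, 9.0),
                             "event": [1, 0, 0, 0, 0, 0, 0, 0]})
        with pytest.raises(ValueError, match="10 events"):
            build_nomogram(np.arange(8.0), surv)


class TestDecisionCurve:
    def test_treat_all_closed_form_without_censoring(self):
        # uncensored: prevalence rho at tau; NB_all = rho - (1-rho) pt/(1-pt)
        times = np.concatenate([np.full(30, 10.0), np.full(70, 100.0)])
        surv = pd.DataFrame({"time_months": times, "event": np.ones(100, int)})
        risks = np.linspace(0.01, 0.99, 100)
        curve = decision_curve(risks, surv, tau=50.0)
        rho = 0.3
        expected = rho - (1 - rho) * curve.thresholds / (1 - curve.thresholds)
        np.testing.assert_allclose(curve.nb_all, expected, atol=1e-12)

    def test_treat_all_limit_is_prevalence(self):
        times = np.concatenate([np.full(40, 10.0), np.full(60, 100.0)])
        surv = pd.DataFrame({"time_months": times, "event": np.ones(100, int)})
        curve = decision_curve(np.linspace(0, 1, 100), surv, tau=50.0,
                               thresholds=np.array([1e-6]))
        assert curve.nb_all[0] == pytest.approx(0.4, abs=1e-4)

    def test_treat_none_identically_zero(self):
        surv = pd.DataFrame({"time_months": np.arange(1.0, 41.0),
                             "event": np.ones(40, int)})
        curve = decision_curve(np.linspace(0, 1, 40), surv, tau=20.0)
        assert np.all(curve.nb_none == 0.0)

    def test_calibrated_risks_dominate_treat_all_mid_range(self):
        # uncensored two-group world with exactly known risks
        rng = np.random.default_rng(10)
        n = 2000
        risk = np.where(rng.random(n) < 0.5, 0.2, 0.8)
        event_by_tau = rng.random(n) < risk
        times = np.where(event_by_tau, 10.0, 100.0)
        surv = pd.DataFrame({"time_months": times, "event": np.ones(n, int)})
        grid = np.arange(0.25, 0.76, 0.05)
        curve = decision_curve(risk, surv, tau=50.0, thresholds=grid)
        assert np.all(curve.nb_model >= curve.nb_all - 1e-9)
        assert np.all(curve.nb_model >= -1e-9)

    def test_thresholds_outside_unit_interval_rejected(self):
        surv = pd.DataFrame({"time_months": [1.0, 2.0], "event": [1, 1]})
        with pytest.raises(ValueError, match="inside"):
            decision_curve(np.array([0.5, 0.5]), surv, tau=1.5,
                           thresholds=np.array([0.0, 0.5]))


class TestCompareStrategies:
    @staticmethod
    def _toy_curves(grid_a, grid_b, tau_b=50.0):
        surv = pd.DataFrame({"time_months": np.linspace(1, 100, 50),
                             "event": np.ones(50, int)})
        risks = np.linspace(0.05, 0.95, 50)
        a = decision_curve(risks, surv, tau=50.0, thresholds=grid_a)
        b = decision_curve(risks, surv, tau=tau_b, thresholds=grid_b)
        return a, b

    def test_identical_inputs_zero_difference(self):
        grid = np.arange(0.1, 0.91, 0.1)
        a, b = self._toy_curves(grid, grid)
        table = compare_strategies(a, b)
        np.testing.assert_allclose(table["difference"], 0.0, atol=1e-15)

    def test_mismatched_grids_rejected(self):
        a, b = self._toy_curves(np.arange(0.1, 0.91, 0.1), np.arange(0.2, 0.81, 0.1))
        with pytest.raises(ValueError, match="grids"):
            compare_strategies(a, b)

    def test_score_beats_its_own_coarsening(self):
        # "clinical stage" as a 3-level coarsening of the risk score loses
        # net benefit over a mid-range band
        rng = np.random.default_rng(11)
        n = 3000
        risk = rng.uniform(0.05, 0.95, n)
        event_by_tau = rng.random(n) < risk
        times = np.where(event_by_tau, 10.0, 100.0)
        surv = pd.DataFrame({"time_months": times, "event": np.ones(n, int)})
        stage = np.digitize(risk, [0.33, 0.66])
        stage_risk = np.array([risk[stage == k].mean() for k in range(3)])[stage]
        grid = np.arange(0.2, 0.81, 0.05)
        fine = decision_curve(risk, surv, tau=50.0, thresholds=grid)
        coarse = decision_curve(stage_risk, surv, tau=50.0, thresholds=grid)
        table = compare_strategies(fine, coarse)
        mid = (table["threshold"] > 0.3) & (table["threshold"] < 0.7)
        # the finer score dominates its coarsening over the mid-range band
        assert table.loc[mid, "difference"].mean() > 0
        assert (table.loc[mid, "difference"] > 1e-4).sum() >= mid.sum() // 2
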