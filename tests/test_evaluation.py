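"""Concordance, time-dependent ROC, KM, log-rank, Cox tables, balance tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ctibm.evaluation import (
    cohort_balance,
    concordance_index,
    cox_multivariable,
    km_estimate,
    log_rank,
    stratify,
    time_dependent_roc,
    youden_cutoff,
)
from ctibm.synthetic import SurvivalTruth, generate_feature_cohort, generate_survival


def _surv(times, events):
    return pd.DataFrame({"time_months": times, "event": events})


class TestConcordance:
    def test_perfect_anti_ordering_gives_one(self):
        # higher score = higher risk = earlier death
        surv = _surv([1, 2, 3, 4], [1, 1, 1, 1])
        c, _ = concordance_index(np.array([4.0, 3.0, 2.0, 1.0]), surv)
        assert c == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        surv = generate_survival(np.zeros(500), SurvivalTruth(), seed=1)
        c, _ = concordance_index(rng.standard_normal(500), surv)
        assert 0.45 <= c <= 0.55

    def test_matches_exhaustive_pair_enumeration_with_censoring(self):
        times = np.array([5.0, 3.0, 9.0, 3.0, 7.0])
        events = np.array([1, 1, 0, 0, 1])
        scores = np.array([0.1, 0.9, 0.2, 0.4, 0.4])
        surv = _surv(times, events)
        num = den = 0.0
        for i, j in itertools.permutations(range(5), 2):
            if events[i] != 1:
                continue
            if times[j] > times[i] or (times[j] == times[i] and events[j] == 0):
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
        c, _ = concordance_index(scores, surv)
        assert c == pytest.approx(num / den)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal(80)
        surv = generate_survival(scores, SurvivalTruth(), seed=4)
        c1, _ = concordance_index(scores, surv)
        c2, _ = concordance_index(np.exp(3 * scores), surv)
        assert c1 == pytest.approx(c2)

    def test_no_comparable_pair_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index(np.array([1.0, 2.0]), _surv([5, 5], [0, 0]))


class TestTimeDependentRoc:
    def test_uncensored_auc_equals_mann_whitney(self):
        scores = np.array([0.1, 0.5, 0.3, 0.9, 0.7, 0.2, 0.8, 0.4])
        times = np.array([10, 2, 8, 1, 3, 12, 2, 9], dtype=float)
        events = np.ones(8, dtype=int)
        tau = 5.0
        cases = times <= tau
        pairs = [(i, j) for i in np.flatnonzero(cases) for j in np.flatnonzero(~cases)]
        mw = np.mean([
            1.0 if scores[i] > scores[j] else 0.5 if scores[i] == scores[j] else 0.0
            for i, j in pairs
        ])
        roc = time_dependent_roc(scores, _surv(times, events), tau)
        assert roc.auc == pytest.approx(mw)

    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        times = np.array([50, 60, 70, 1, 2, 3], dtype=float)
        roc = time_dependent_roc(scores, _surv(times, np.ones(6, int)), tau=10.0)
        assert roc.auc == pytest.approx(1.0)
        assert roc.youden.max() == pytest.approx(1.0)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.standard_normal(100)
        surv = generate_survival(scores, SurvivalTruth(), seed=6)
        r1 = time_dependent_roc(scores, surv, 36.0)
        r2 = time_dependent_roc(np.tanh(scores) * 7, surv, 36.0)
        assert r1.auc == pytest.approx(r2.auc)

    def test_no_event_by_horizon_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            time_dependent_roc(np.array([1.0, 2.0]), _surv([50, 60], [1, 1]), tau=5.0)


class TestYouden:
    def test_midpoint_cutoff_on_separable_toy(self):
        # scores {1,2,3,4}, cases are 3 and 4 -> cutoff 2.5 with J = 1
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        times = np.array([50.0, 60.0, 2.0, 3.0])
        roc = time_dependent_roc(scores, _surv(times, np.ones(4, int)), tau=10.0)
        assert youden_cutoff(roc) == pytest.approx(2.5)
        assert roc.youden.max() == pytest.approx(1.0)

    def test_tie_resolves_to_higher_specificity(self):
        # two thresholds reach the same J; pick the one sparing more controls
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        times = np.array([50.0, 3.0, 60.0, 2.0])
        roc = time_dependent_roc(scores, _surv(times, np.ones(4, int)), tau=10.0)
        j = roc.youden
        best = j.max()
        ties = roc.thresholds[j == best]
        assert youden_cutoff(roc) == max(ties)

    def test_reversed_labels_warn(self):
        scores = np.array([4.0, 3.0, 2.0, 1.0])
        times = np.array([50.0, 60.0, 2.0, 3.0])
        roc = time_dependent_roc(scores, _surv(times, np.ones(4, int)), tau=10.0)
        with pytest.warns(UserWarning, match="J <= 0"):
            youden_cutoff(roc)

    def test_constant_scores_rejected(self):
        scores = np.ones(4)
        times = np.array([50.0, 60.0, 2.0, 3.0])
        roc = time_dependent_roc(scores, _surv(times, np.ones(4, int)), tau=10.0)
        with pytest.raises(ValueError, match="equal"):
            youden_cutoff(roc)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate(_surv([1, 2, 3, 4], [1, 1, 1, 1]))
        assert km.survival_function_at_times(2.0).iloc[0] == pytest.approx(0.5)

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate(_surv([1, 2, 3], [0, 0, 0]))
        assert km.survival_function_at_times(3.0).iloc[0] == 1.0

    def test_mixed_table_matches_hand_product_limit(self):
        # times 1,2,2,3,4,5 events 1,0,1,1,0,1; at each event time the
        # at-risk set includes records censored at that same time:
        # S = (5/6) at 1, x(4/5) at 2, x(2/3) at 3, x(0/1) at 5
        km = km_estimate(_surv([1, 2, 2, 3, 4, 5], [1, 0, 1, 1, 0, 1]))
        s = km.survival_function_at_times([1.0, 2.0, 3.0, 4.5, 5.0]).to_numpy()
        expect = [5 / 6, 5 / 6 * 4 / 5, 5 / 6 * 4 / 5 * 2 / 3,
                  5 / 6 * 4 / 5 * 2 / 3, 0.0]
        np.testing.assert_allclose(s, expect)


class TestLogRank:
    def test_identical_groups_give_zero(self):
        g = _surv([1, 2, 3, 4], [1, 1, 0, 1])
        chi2, p = log_rank(g, g.copy())
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_small_table_matches_observed_minus_expected_formula(self):
        a = _surv([1.0, 3.0, 5.0], [1, 1, 0])
        b = _surv([2.0, 4.0, 6.0], [1, 0, 1])
        # hand computation over the pooled event times
        times = np.concatenate([a["time_months"], b["time_months"]])
        events = np.concatenate([a["event"], b["event"]])
        group = np.array([0, 0, 0, 1, 1, 1])
        o_minus_e = 0.0
        var = 0.0
        for t in sorted(times[events == 1]):
            at_risk = times >= t
            d = ((times == t) & (events == 1)).sum()
            n = at_risk.sum()
            n1 = (at_risk & (group == 0)).sum()
            d1 = ((times == t) & (events == 1) & (group == 0)).sum()
            e1 = d * n1 / n
            o_minus_e += d1 - e1
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / var
        chi2, _ = log_rank(a, b)
        assert chi2 == pytest.approx(expected_chi2, rel=1e-9)

    def test_power_against_threefold_hazard_ratio(self):
        hits = 0
        for seed in range(20):
            sa = generate_survival(np.zeros(200), SurvivalTruth(baseline_rate=0.02), seed=seed)
            sb = generate_survival(np.zeros(200), SurvivalTruth(baseline_rate=0.06), seed=500 + seed)
            _, p = log_rank(sa, sb)
            hits += int(p < 0.001)
        assert hits >= 19


class TestStratify:
    def test_planted_effect_detected_across_seeds(self):
        for seed in range(5):
            tab, _ = generate_feature_cohort(200, n_features=3, beta=0.8, seed=seed)
            scores = tab[["F000", "F001", "F002"]].sum(axis=1).to_numpy()
            roc = time_dependent_roc(scores, tab, tau=60.0)
            cutoff = youden_cutoff(roc)
            strat = stratify(scores, tab, cutoff)
            assert strat.hazard_ratio > 1.0
            assert strat.logrank_p < 0.05


class TestCoxMultivariable:
    def test_recovers_planted_binary_hazard_ratio(self):
        rng = np.random.default_rng(10)
        x = rng.integers(0, 2, size=1000)
        surv = generate_survival(np.log(2.0) * x, SurvivalTruth(censor_horizon=200.0), seed=11)
        cohort = pd.DataFrame({"time_months": surv["time_months"],
                               "event": surv["event"], "x": x})
        table = cox_multivariable(cohort, ["x"])["final"]
        assert 1.7 <= table.loc["x", "HR"] <= 2.3

    def test_duplicated_covariate_flagged(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(100)
        surv = generate_survival(x, SurvivalTruth(), seed=13)
        cohort = pd.DataFrame({"time_months": surv["time_months"],
                               "event": surv["event"], "x": x, "x2": x})
        with pytest.raises(ValueError, match="Cox fit failed"):
            cox_multivariable(cohort, ["x", "x2"])

    def test_backward_elimination_clears_null_covariates(self):
        empties = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            surv = generate_survival(np.zeros(150), SurvivalTruth(), seed=seed)
            cohort = pd.DataFrame({
                "time_months": surv["time_months"], "event": surv["event"],
                "a": rng.standard_normal(150), "b": rng.standard_normal(150),
            })
            out = cox_multivariable(cohort, ["a", "b"], mode="backward_LR")
            empties += int(len(out["final"]) == 0)
        assert empties >= 12  # null covariates usually leave an empty model

    def test_informative_covariate_survives_backward(self):
        tab, _ = generate_feature_cohort(300, n_features=2, n_informative=1,
                                         beta=0.8, rho=0.0, seed=14)
        out = cox_multivariable(tab, ["F000", "F001"], mode="backward_LR")
        assert "F000" in out["final"].index


class TestCohortBalance:
    def test_identical_categorical_proportions(self):
        a = pd.DataFrame({"sex": ["m"] * 30 + ["f"] * 10})
        b = pd.DataFrame({"sex": ["m"] * 60 + ["f"] * 20})
        p = cohort_balance(a, b, {"sex": "categorical"})
        assert p["sex"] == pytest.approx(1.0)

    def test_identical_continuous_samples(self):
        a = pd.DataFrame({"age": np.arange(20.0, 40.0)})
        p = cohort_balance(a, a.copy(), {"age": "continuous"})
        assert p["age"] == pytest.approx(1.0)

    def test_published_sex_split_p_value(self):
        # 77/22 male/female vs 42/13: chi-squared without continuity correction
        a = pd.DataFrame({"sex": ["m"] * 77 + ["f"] * 22})
        b = pd.DataFrame({"sex": ["m"] * 42 + ["f"] * 13})
        p = cohort_balance(a, b, {"sex": "categorical"})
        assert p["sex"] == pytest.approx(0.841, abs=5e-4)
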