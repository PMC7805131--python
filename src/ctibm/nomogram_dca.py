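"""Individual survival prediction and decision-curve analysis.

The nomogram is a univariable Cox model on the score with a Breslow
baseline cumulative hazard: ``S(t | x) = exp(-H0(t) * exp(beta * x))``.
A points scale rescales the observed score range linearly to 0-100 for
presentation.

Decision curves quantify the clinical utility of acting on a predicted
event risk at horizon tau: at threshold probability p_t, net benefit =
(n+/n) * [risk+ - (1 - risk+) * p_t / (1 - p_t)], where "+" is the
group whose predicted risk reaches p_t and risk+ is that group's
Kaplan-Meier event probability by tau (so censoring is handled).  The
comparators are treat-all (everybody "+") and treat-none (net benefit
identically zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

__all__ = [
    "NomogramModel",
    "build_nomogram",
    "predict_survival",
    "DecisionCurve",
    "decision_curve",
    "compare_strategies",
]


@dataclass
class NomogramModel:
    """Univariable Cox model on the score with a Breslow baseline."""

    beta: float
    score_mean: float  # lifelines centres covariates; needed to reconstruct H0
    baseline_times: np.ndarray  # event times (ascending)
    baseline_cumhaz: np.ndarray  # H0 at those times, for the centred covariate
    score_range: tuple[float, float]  # observed training range, for the points scale
    prediction_times: tuple[float, ...] = (12.0, 36.0, 60.0)

    def points(self, score: float | np.ndarray) -> np.ndarray:
        """Linear 0-100 points scale over the observed training range."""
        lo, hi = self.score_range
        return 100.0 * (np.asarray(score, dtype=float) - lo) / (hi - lo)

    def cumhaz_at(self, t: float | np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        h = np.where(idx >= 0, self.baseline_cumhaz[np.clip(idx, 0, None)], 0.0)
        return h


def build_nomogram(
    scores: np.ndarray,
    survival: pd.DataFrame,
    prediction_times: tuple[float, ...] = (12.0, 36.0, 60.0),
) -> NomogramModel:
    """Fit the score-only Cox model and its Breslow baseline."""
    scores = np.asarray(scores, dtype=np.float64)
    if int(survival["event"].sum()) < 10:
        raise ValueError("nomogram needs at least 10 events")
    if scores.max() == scores.min():
        raise ValueError("constant scores cannot support a nomogram")
    df = pd.DataFrame({
        "time_months": survival["time_months"].to_numpy(),
        "event": survival["event"].to_numpy(),
        "score": scores,
    })
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time_months", event_col="event")
    beta = float(cph.params_["score"])
    base = cph.baseline_cumulative_hazard_  # Breslow, at the centred covariate
    times = base.index.to_numpy(dtype=float)
    h0 = base.iloc[:, 0].to_numpy(dtype=float)
    return NomogramModel(
        beta=beta,
        score_mean=float(scores.mean()),
        baseline_times=times,
        baseline_cumhaz=h0,
        score_range=(float(scores.min()), float(scores.max())),
        prediction_times=tuple(prediction_times),
    )


def predict_survival(
    model: NomogramModel,
    score: float,
    times: tuple[float, ...] | None = None,
) -> tuple[dict[float, float], float | None]:
    """S(t | score) at the requested times plus the median survival time.

    The median is the smallest observed event time with S <= 0.5, or
    ``None`` ("not reached") if the curve never crosses 0.5 within
    follow-up.  Scores outside the training range are allowed but
    flagged with a warning.
    """
    times = times if times is not None else model.prediction_times
    lo, hi = model.score_range
    span = hi - lo
    if score < lo - 0.1 * span or score > hi + 0.1 * span:
        warnings.warn(
            f"score {score:.3g} lies outside the training range [{lo:.3g}, {hi:.3g}]; "
            "prediction is an extrapolation"
        )
    rel = np.exp(model.beta * (score - model.score_mean))
    probs = {float(t): float(np.exp(-model.cumhaz_at(t)[0] * rel)) for t in times}
    s_curve = np.exp(-model.baseline_cumhaz * rel)
    below = np.flatnonzero(s_curve <= 0.5)
    median = float(model.baseline_times[below[0]]) if below.size else None
    return probs, median


@dataclass
class DecisionCurve:
    """Net benefit of acting on predicted risk, per threshold probability."""

    tau: float
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray  # identically zero, kept for tabulation

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "nb_model": self.nb_model,
            "nb_all": self.nb_all,
            "nb_none": self.nb_none,
        })


def _km_event_prob(survival: pd.DataFrame, tau: float) -> float:
    """KM estimate of P(event by tau) within a (sub)cohort."""
    km = KaplanMeierFitter()
    km.fit(survival["time_months"].to_numpy(), survival["event"].to_numpy())
    return 1.0 - float(km.survival_function_at_times(tau).iloc[0])


def decision_curve(
    risks: np.ndarray,
    survival: pd.DataFrame,
    tau: float,
    thresholds: np.ndarray | None = None,
) -> DecisionCurve:
    """Survival-weighted decision curve for predicted risks at horizon tau."""
    risks = np.asarray(risks, dtype=np.float64)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")

    n = len(risks)
    rho_all = _km_event_prob(survival, tau)
    odds = thresholds / (1.0 - thresholds)
    nb_all = rho_all - (1.0 - rho_all) * odds

    nb_model = np.zeros_like(thresholds)
    for k, pt in enumerate(thresholds):
        pos = risks >= pt
        npos = int(pos.sum())
        if npos == 0:
            nb_model[k] = 0.0  # nobody treated at this threshold
            continue
        rho_pos = _km_event_prob(survival[pos], tau)
        nb_model[k] = (npos / n) * (rho_pos - (1.0 - rho_pos) * odds[k])
    return DecisionCurve(
        tau=float(tau), thresholds=thresholds, nb_model=nb_model,
        nb_all=nb_all, nb_none=np.zeros_like(thresholds),
    )


def compare_strategies(
    curve_a: DecisionCurve, curve_b: DecisionCurve
) -> pd.DataFrame:
    """Per-threshold net-benefit difference (A - B) and who dominates where.

    Both curves must share the horizon and the threshold grid.
    """
    if curve_a.tau != curve_b.tau:
        raise ValueError(f"horizons differ: {curve_a.tau} vs {curve_b.tau}")
    if len(curve_a.thresholds) != len(curve_b.thresholds) or not np.allclose(
        curve_a.thresholds, curve_b.thresholds
    ):
        raise ValueError("threshold grids differ; curves are not comparable")
    diff = curve_a.nb_model - curve_b.nb_model
    return pd.DataFrame({
        "threshold": curve_a.thresholds,
        "nb_a": curve_a.nb_model,
        "nb_b": curve_b.nb_model,
        "difference": diff,
        "a_dominates": diff > 0,
    })
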