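"""Score-performance machinery for censored survival data.

Implements Harrell's concordance, time-dependent ROC analysis with the
cumulative-case / dynamic-control estimator under Kaplan-Meier
inverse-censoring weights, Youden-index cutoff selection, Kaplan-Meier /
log-rank risk stratification, multivariable Cox modelling with optional
backward likelihood-ratio elimination, and cohort balance testing.

Convention throughout: a *higher* score means *higher* risk (shorter
survival).  Confidence intervals, where reported, are seeded percentile
bootstrap intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "concordance_index",
    "RocCurve",
    "time_dependent_roc",
    "youden_cutoff",
    "km_estimate",
    "log_rank",
    "stratify",
    "StratificationResult",
    "cox_multivariable",
    "cohort_balance",
]


# ------------------------------------------------------------ concordance

def _harrell_c(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    n = len(scores)
    num = 0.0
    den = 0.0
    for i in range(n):
        if event[i] != 1:
            continue
        # patient i fails at time[i]; comparable with everyone surviving past it
        later = (time > time[i]) | ((time == time[i]) & (event == 0))
        den += later.sum()
        num += (scores[i] > scores[later]).sum() + 0.5 * (scores[i] == scores[later]).sum()
    if den == 0:
        raise ValueError("no comparable pair: concordance undefined")
    return num / den


def concordance_index(
    scores: np.ndarray,
    survival: pd.DataFrame,
    ci: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float] | None]:
    """Harrell's C over usable pairs (score ties count 1/2).

    Returns ``(C, (lo, hi))``; the percentile-bootstrap 95% interval is
    computed only when ``ci=True``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    time = survival["time_months"].to_numpy(dtype=np.float64)
    event = survival["event"].to_numpy(dtype=int)
    c = _harrell_c(scores, time, event)
    if not ci:
        return c, None
    rng = np.random.default_rng(seed)
    n = len(scores)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            reps.append(_harrell_c(scores[idx], time[idx], event[idx]))
        except ValueError:
            continue
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return c, (float(lo), float(hi))


# ------------------------------------------------------ time-dependent ROC

@dataclass
class RocCurve:
    """Time-dependent ROC at horizon tau (cumulative cases, dynamic controls)."""

    tau: float
    thresholds: np.ndarray  # candidate cutoffs (midpoints between observed scores)
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float] | None = None

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def _censoring_km(time: np.ndarray, event: np.ndarray):
    """KM estimate of the censoring distribution G(t) = P(censoring > t)."""
    km = KaplanMeierFitter()
    km.fit(time, event_observed=1 - event)
    return km


def _roc_at_tau(
    scores: np.ndarray, time: np.ndarray, event: np.ndarray, tau: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    cases = (time <= tau) & (event == 1)
    controls = time > tau
    if cases.sum() == 0:
        raise ValueError(f"no events by horizon {tau}: ROC undefined")
    if controls.sum() == 0:
        raise ValueError(f"no patient at risk beyond horizon {tau}: ROC undefined")

    gkm = _censoring_km(time, event)
    # weight each case by 1/G(T_i-), each control by 1/G(tau); the control
    # weight is shared so it cancels within the control group
    g_case = gkm.survival_function_at_times(np.maximum(time[cases] - 1e-9, 0.0)).to_numpy()
    g_case = np.clip(g_case, 1e-12, None)
    w_case = 1.0 / g_case
    s_case = scores[cases]
    s_ctrl = scores[controls]

    order = np.sort(np.unique(scores))
    mids = (order[:-1] + order[1:]) / 2.0
    thresholds = np.concatenate(([order[0] - 1.0], mids, [order[-1] + 1.0]))
    sens = np.array([w_case[s_case > c].sum() / w_case.sum() for c in thresholds])
    spec = np.array([(s_ctrl <= c).sum() / len(s_ctrl) for c in thresholds])

    # trapezoidal AUC over the weighted ROC polyline; with descending
    # threshold both fpr and sens increase monotonically, so reversing the
    # ascending-threshold arrays walks the curve left to right
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    return thresholds, sens, spec, auc


def time_dependent_roc(
    scores: np.ndarray,
    survival: pd.DataFrame,
    tau: float,
    ci: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> RocCurve:
    """Cumulative-case / dynamic-control ROC with KM censoring weights.

    Cases are patients with an observed event by ``tau``; controls are
    patients still event-free beyond ``tau``.  With no censoring before
    ``tau`` the weights collapse and the curve equals the plain empirical
    ROC of event-by-tau labels.
    """
    scores = np.asarray(scores, dtype=np.float64)
    time = survival["time_months"].to_numpy(dtype=np.float64)
    event = survival["event"].to_numpy(dtype=int)
    thresholds, sens, spec, auc = _roc_at_tau(scores, time, event, tau)
    auc_ci = None
    if ci:
        rng = np.random.default_rng(seed)
        n = len(scores)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                reps.append(_roc_at_tau(scores[idx], time[idx], event[idx], tau)[3])
            except ValueError:
                continue
        lo, hi = np.percentile(reps, [2.5, 97.5])
        auc_ci = (float(lo), float(hi))
    return RocCurve(tau=tau, thresholds=thresholds, sensitivity=sens,
                    specificity=spec, auc=auc, auc_ci=auc_ci)


def youden_cutoff(roc: RocCurve) -> float:
    """Threshold maximising J = sensitivity + specificity - 1.

    Ties resolve toward higher specificity (the larger threshold under
    the higher-score-higher-risk convention).  The returned cutoff is the
    midpoint between adjacent observed scores (already how the curve's
    thresholds are laid out).
    """
    if len(roc.thresholds) < 3:
        raise ValueError("all scores are equal: no cutoff can stratify")
    j = roc.youden
    if np.all(j <= 0):
        warnings.warn("no threshold separates cases from controls (J <= 0 everywhere)")
    best_j = j.max()
    candidates = np.flatnonzero(j == best_j)
    specs = roc.specificity[candidates]
    best = candidates[np.argmax(specs)]
    cutoff = float(roc.thresholds[best])
    if not np.isfinite(cutoff):
        raise ValueError("degenerate ROC curve: no usable cutoff")
    return cutoff


# ------------------------------------------------------------ KM / log-rank

def km_estimate(survival: pd.DataFrame) -> KaplanMeierFitter:
    """Product-limit estimator with Greenwood variance (lifelines fitter).

    Survival probabilities at arbitrary times are right-continuous step
    lookups via ``.survival_function_at_times``.
    """
    km = KaplanMeierFitter()
    km.fit(
        survival["time_months"].to_numpy(),
        event_observed=survival["event"].to_numpy(),
    )
    return km


def log_rank(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test (1 df); returns (chi-square, p)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    res = logrank_test(
        group_a["time_months"], group_b["time_months"],
        event_observed_A=group_a["event"], event_observed_B=group_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class StratificationResult:
    """High/low risk groups at a score cutoff with their survival contrast."""

    cutoff: float
    high: np.ndarray  # boolean per patient
    hazard_ratio: float
    hr_ci: tuple[float, float]
    logrank_chi2: float
    logrank_p: float
    km_at_times: dict[str, dict[float, float]] = field(default_factory=dict)


def stratify(
    scores: np.ndarray,
    survival: pd.DataFrame,
    cutoff: float,
    km_times: tuple[float, ...] = (12.0, 36.0, 60.0),
) -> StratificationResult:
    """Split at the cutoff (high = score > cutoff) and contrast the groups."""
    scores = np.asarray(scores, dtype=np.float64)
    high = scores > cutoff
    if high.all() or (~high).all():
        raise ValueError(f"cutoff {cutoff} does not split the cohort")
    df = pd.DataFrame({
        "time_months": survival["time_months"].to_numpy(),
        "event": survival["event"].to_numpy(),
        "high": high.astype(int),
    })
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time_months", event_col="event")
    hr = float(np.exp(cph.params_["high"]))
    lo, hi = np.exp(cph.confidence_intervals_.loc["high"]).to_numpy()
    chi2, p = log_rank(df[df["high"] == 1], df[df["high"] == 0])
    km_at = {}
    for label, sel in (("high", high), ("low", ~high)):
        km = km_estimate(df[sel])
        km_at[label] = {
            float(t): float(km.survival_function_at_times(t).iloc[0]) for t in km_times
        }
    return StratificationResult(
        cutoff=float(cutoff), high=high, hazard_ratio=hr, hr_ci=(float(lo), float(hi)),
        logrank_chi2=chi2, logrank_p=p, km_at_times=km_at,
    )


# ------------------------------------------------------- multivariable Cox

def cox_multivariable(
    cohort: pd.DataFrame,
    covariates: list[str],
    mode: str = "full",
    removal_p: float = 0.10,
) -> dict[str, pd.DataFrame]:
    """Proportional-hazards fit over several covariates.

    ``mode="full"`` fits all covariates.  ``mode="backward_LR"``
    additionally removes, one at a time, the covariate whose removal has
    the largest likelihood-ratio p above ``removal_p``, until none
    qualifies.  Returns ``{"full": table, "final": table}`` with columns
    HR, ci_lower, ci_upper, p per covariate.
    """
    if mode not in ("full", "backward_LR"):
        raise ValueError(f"unknown mode {mode!r}")
    if int(cohort["event"].sum()) <= len(covariates):
        raise ValueError("need more events than covariates")

    def _fit(cols: list[str]) -> CoxPHFitter:
        df = cohort[["time_months", "event", *cols]]
        cph = CoxPHFitter(penalizer=0.0)
        try:
            cph.fit(df, duration_col="time_months", event_col="event")
        except Exception as exc:  # separation / collinearity / non-convergence
            raise ValueError(
                f"Cox fit failed for covariates {cols}: {exc}"
            ) from exc
        return cph

    def _table(cph: CoxPHFitter) -> pd.DataFrame:
        s = cph.summary
        return pd.DataFrame({
            "HR": np.exp(s["coef"]),
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        })

    full_fit = _fit(covariates)
    out = {"full": _table(full_fit)}

    if mode == "full":
        out["final"] = out["full"]
        return out

    current = list(covariates)
    cur_fit = full_fit
    while current:
        ll_cur = cur_fit.log_likelihood_
        worst_p, worst_cov, worst_fit = -1.0, None, None
        for cov in current:
            reduced_cols = [c for c in current if c != cov]
            if reduced_cols:
                red_fit = _fit(reduced_cols)
                ll_red = red_fit.log_likelihood_
            else:
                red_fit = None
                # null model partial log-likelihood: no covariates
                ll_red = _null_partial_loglik(cohort)
            lr = 2.0 * (ll_cur - ll_red)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            if p > worst_p:
                worst_p, worst_cov, worst_fit = p, cov, red_fit
        if worst_p <= removal_p:
            break
        current.remove(worst_cov)
        cur_fit = worst_fit
        if cur_fit is None:
            break
    out["final"] = _table(cur_fit) if current else pd.DataFrame(
        columns=["HR", "ci_lower", "ci_upper", "p"]
    )
    return out


def _null_partial_loglik(cohort: pd.DataFrame) -> float:
    from .signature import cox_partial_loglik

    time = cohort["time_months"].to_numpy(dtype=np.float64)
    event = cohort["event"].to_numpy(dtype=int)
    return cox_partial_loglik(np.zeros(len(cohort)), time, event)


# ----------------------------------------------------------- balance tests

def cohort_balance(
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    variables: dict[str, str],
) -> pd.Series:
    """Per-variable p comparing two cohorts.

    ``variables`` maps column name to type: ``"continuous"`` (two-sided
    pooled-variance t-test) or ``"categorical"`` (Pearson chi-squared, no
    continuity correction).  Categories absent from both cohorts drop out
    of the contingency table.
    """
    out = {}
    for name, kind in variables.items():
        if kind == "continuous":
            t, p = stats.ttest_ind(cohort_a[name], cohort_b[name], equal_var=True)
            out[name] = float(p)
        elif kind == "categorical":
            levels = sorted(set(cohort_a[name]) | set(cohort_b[name]))
            table = np.array([
                [(cohort_a[name] == lv).sum() for lv in levels],
                [(cohort_b[name] == lv).sum() for lv in levels],
            ])
            table = table[:, table.sum(axis=0) > 0]
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            out[name] = float(p)
        else:
            raise ValueError(f"unknown variable type {kind!r} for {name!r}")
    return pd.Series(out, name="p")
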