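"""LASSO-Cox imaging-biomarker scores.

The score of a patient is the log-partial hazard of an L1-penalised Cox
model over pre-selected features, plus an additive constant chosen so
that all training scores are positive.  The penalty weight is chosen by
10-fold cross-validated partial-likelihood deviance at its minimum.

Two published formulas (one for overall survival with 11 terms and
constant +2.5, one for progression-free survival with 8 terms and
constant -1.4) are exposed verbatim as frozen scorers.  Their
coefficients are interpreted as acting on *standardised* feature values:
applied to raw CT-scale inputs (e.g. an intensity percentile of several
hundred HU against a coefficient of -3.231) the printed constants could
not yield positive scores, so a raw-scale application is possible but
must be requested explicitly by building a formula with no scaling spec.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "LassoFit",
    "ScoreFormula",
    "fit_lasso_cox",
    "build_score",
    "published_formula",
    "ibm_score",
    "score_cohort",
    "cox_partial_loglik",
]


def cox_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox partial log-likelihood of linear predictors (Breslow ties)."""
    order = np.argsort(time, kind="stable")
    lp, time, event = lp[order], time[order], event[order]
    # log of the risk-set sum for each position: sum over j with time_j >= t
    rev = np.logaddexp.accumulate(lp[::-1])[::-1]
    first = np.searchsorted(time, time, side="left")
    return float(np.sum(lp[event == 1] - rev[first][event == 1]))


@dataclass
class LassoFit:
    """A cross-validated LASSO-Cox path and its selected model."""

    alphas: np.ndarray  # descending penalty grid
    cv_deviance: np.ndarray  # mean held-out deviance per alpha
    coef_path: np.ndarray  # (n_features, n_alphas) on the full training data
    feature_names: list[str]
    chosen_alpha: float
    coefficients: dict[str, float]  # nonzero at chosen alpha
    scaling: dict[str, tuple[float, float]]  # feature -> (mean, sd) from training
    seed: int
    fold_assignment: np.ndarray | None = None

    @property
    def all_zero(self) -> bool:
        return len(self.coefficients) == 0


def _stratified_folds(event: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels with events and censored records dealt out separately."""
    assignment = np.empty(len(event), dtype=int)
    for flag in (0, 1):
        idx = np.flatnonzero(event == flag)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % n_folds
    return assignment


def fit_lasso_cox(
    cohort: pd.DataFrame,
    features: list[str],
    folds: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-4,
) -> LassoFit:
    """Fit the L1 Cox path and choose the penalty by cross-validation.

    Features are standardised with the cohort's own mean/SD (recorded on
    the fit so downstream scoring is self-contained).  Folds are
    stratified by event status; if a fold's training portion still ends
    up without events, the folds are re-dealt with a bumped seed.
    """
    n_events = int(cohort["event"].sum())
    if n_events < folds:
        raise ValueError(f"need at least {folds} events for {folds}-fold CV, have {n_events}")

    x_raw = cohort[features].to_numpy(dtype=np.float64)
    means = x_raw.mean(axis=0)
    sds = x_raw.std(axis=0, ddof=0)
    if np.any(sds == 0):
        bad = [f for f, s in zip(features, sds) if s == 0]
        raise ValueError(f"constant feature(s) cannot enter the penalised fit: {bad}")
    x = (x_raw - means) / sds
    time = cohort["time_months"].to_numpy(dtype=np.float64)
    event = cohort["event"].to_numpy(dtype=int)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio, max_iter=100_000
    )
    model.fit(x, y)
    alphas = np.asarray(model.alphas_)
    coef_path = np.asarray(model.coef_)

    rng = np.random.default_rng(seed)
    attempt = 0
    while True:
        folds_of = _stratified_folds(event, folds, rng)
        if all(event[folds_of != k].sum() > 0 for k in range(folds)):
            break
        attempt += 1
        warnings.warn("a CV fold left no events in training; re-dealing folds")
        rng = np.random.default_rng(seed + attempt)

    deviance = np.zeros((folds, len(alphas)))
    for k in range(folds):
        tr = folds_of != k
        te = ~tr
        cv_model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, max_iter=100_000)
        cv_model.fit(x[tr], Surv.from_arrays(event=event[tr].astype(bool), time=time[tr]))
        fitted_alphas = np.asarray(cv_model.alphas_)
        cv_coefs = np.asarray(cv_model.coef_)
        for a_idx, alpha in enumerate(alphas):
            j = int(np.argmin(np.abs(fitted_alphas - alpha)))
            lp_te = x[te] @ cv_coefs[:, j]
            deviance[k, a_idx] = -2.0 * cox_partial_loglik(lp_te, time[te], event[te])

    mean_dev = deviance.mean(axis=0)
    best = int(np.argmin(mean_dev))
    chosen = float(alphas[best])
    coefs = {
        f: float(c) for f, c in zip(features, coef_path[:, best]) if c != 0.0
    }
    if not coefs:
        warnings.warn("all coefficients are zero at the selected penalty")
    return LassoFit(
        alphas=alphas,
        cv_deviance=mean_dev,
        coef_path=coef_path,
        feature_names=list(features),
        chosen_alpha=chosen,
        coefficients=coefs,
        scaling={f: (float(m), float(s)) for f, m, s in zip(features, means, sds)},
        seed=seed,
        fold_assignment=folds_of,
    )


def relax_to_nonzero(fit: LassoFit) -> LassoFit:
    """Fall back to the best-deviance penalty with a nonzero active set.

    When cross-validation prefers the fully shrunk (empty) model — the
    expected outcome when no feature carries signal — a score cannot be
    built at the selected penalty.  This helper re-selects the penalty
    with minimal CV deviance among those whose active set is nonempty,
    so a pipeline can still emit a (prognostically useless) score; the
    relaxation is flagged with a warning.
    """
    if not fit.all_zero:
        return fit
    nonzero = np.flatnonzero((fit.coef_path != 0).any(axis=0))
    if nonzero.size == 0:
        raise ValueError("the whole path is zero: no feature ever enters the model")
    best = nonzero[np.argmin(fit.cv_deviance[nonzero])]
    warnings.warn(
        "CV selected the empty model; relaxing to the best penalty with a "
        "nonzero active set"
    )
    import dataclasses

    return dataclasses.replace(
        fit,
        chosen_alpha=float(fit.alphas[best]),
        coefficients={
            f: float(c)
            for f, c in zip(fit.feature_names, fit.coef_path[:, best])
            if c != 0.0
        },
    )


@dataclass(frozen=True)
class ScoreFormula:
    """A named linear scoring rule: sum of coefficient × (scaled) feature + constant.

    ``scaling`` maps each feature to the (mean, sd) used to standardise it
    before the linear combination; an empty dict means values are used as
    given (the convention for the published formulas, whose inputs are
    expected to be standardised already).
    """

    endpoint: str  # "OS" or "PFS"
    terms: tuple[tuple[str, float], ...]
    constant: float
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return [f for f, _ in self.terms]

    def to_json(self) -> str:
        return json.dumps(
            {
                "endpoint": self.endpoint,
                "terms": [{"feature": f, "coefficient": c} for f, c in self.terms],
                "constant": self.constant,
                "scaling": {f: {"mean": m, "sd": s} for f, (m, s) in self.scaling.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoreFormula":
        obj = json.loads(text)
        return cls(
            endpoint=obj["endpoint"],
            terms=tuple((t["feature"], t["coefficient"]) for t in obj["terms"]),
            constant=obj["constant"],
            scaling={f: (v["mean"], v["sd"]) for f, v in obj.get("scaling", {}).items()},
        )


#: published overall-survival scoring formula (11 terms, constant +2.5)
_OS_TERMS = (
    ("Range", 0.019),
    ("Q975", -3.231),
    ("Sphericity", -0.260),
    ("Major_axis_length", 0.093),
    ("Maximum_Probability_GLCM", 0.035),
    ("Sum_of_Square_Variance_GLCM", -0.304),
    ("Coarseness_NGTDM", -0.014),
    ("Contrast_NGTDM", -0.020),
    ("Busyness_NGTDM", 0.020),
    ("Small_Zone_Emphasis_GLSZM", 0.670),
    ("Zone_percentage_GLSZM", -0.064),
)

#: published progression-free-survival scoring formula (8 terms, constant -1.4)
_PFS_TERMS = (
    ("Q75", -0.663),
    ("Q975", -0.234),
    ("Volume_Density", -0.246),
    ("Sphericity", -0.010),
    ("Major_axis_length", 0.122),
    ("Contrast_NGTDM", -0.021),
    ("Small_Zone_Emphasis_GLSZM", 0.468),
    ("Zone_percentage_GLSZM", -0.069),
)


def published_formula(endpoint: str) -> ScoreFormula:
    """The frozen published scoring formula for "OS" or "PFS"."""
    key = endpoint.upper()
    if key == "OS":
        return ScoreFormula(endpoint="OS", terms=_OS_TERMS, constant=2.5)
    if key == "PFS":
        return ScoreFormula(endpoint="PFS", terms=_PFS_TERMS, constant=-1.4)
    raise ValueError(f"unknown endpoint {endpoint!r}: expected 'OS' or 'PFS'")


def build_score(fit: LassoFit, training: pd.DataFrame, endpoint: str = "OS") -> ScoreFormula:
    """Turn a LASSO fit into a self-contained scoring formula.

    The score is the model's log-partial hazard plus a constant: the
    smallest multiple of 0.1 for which every training score is strictly
    positive (a training minimum linear predictor of -2.43 gives +2.5).
    Scaling statistics are embedded so the formula applies to raw
    feature values anywhere.
    """
    if fit.all_zero:
        raise ValueError("cannot build a score from an all-zero fit")
    terms = tuple(fit.coefficients.items())
    scaling = {f: fit.scaling[f] for f, _ in terms}
    base = ScoreFormula(endpoint=endpoint, terms=terms, constant=0.0, scaling=scaling)
    min_lp = float(np.min(score_cohort(training, base)))
    k = int(np.floor(round(-min_lp / 0.1, 9))) + 1
    c = max(k, 0) * 0.1
    return ScoreFormula(endpoint, terms, float(round(c, 10)), scaling)


def ibm_score(feature_vector: dict[str, float] | pd.Series, formula: ScoreFormula) -> float:
    """Apply a scoring formula to one patient's feature vector."""
    total = formula.constant
    for name, coef in formula.terms:
        if name not in feature_vector:
            raise KeyError(f"feature vector is missing {name!r} required by the formula")
        v = float(feature_vector[name])
        if name in formula.scaling:
            mean, sd = formula.scaling[name]
            v = (v - mean) / sd
        total += coef * v
    return float(total)


def score_cohort(features: pd.DataFrame, formula: ScoreFormula) -> np.ndarray:
    """Vectorised scoring of a cohort table (one row per patient)."""
    missing = [f for f in formula.features if f not in features.columns]
    if missing:
        raise KeyError(f"cohort table is missing feature(s) {missing}")
    total = np.full(len(features), formula.constant, dtype=np.float64)
    for name, coef in formula.terms:
        v = features[name].to_numpy(dtype=np.float64)
        if name in formula.scaling:
            mean, sd = formula.scaling[name]
            v = (v - mean) / sd
        total += coef * v
    return total
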