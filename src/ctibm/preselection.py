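"""Three-rule feature pre-selection before the penalised fit.

Rule 1 — univariable Cox screen: keep features whose Wald p-value is
below 0.25.  Rule 2 — correlation pruning: among kept features, while
any pair has |Pearson r| at or above 0.8, drop the feature with the
larger univariable p.  Rule 3 (diagnostic) — variance inflation factors
of the retained set.

Features are standardised (zero mean, unit variance, using the cohort
passed in) before every model fit so that coefficients and penalties are
comparable across features on very different native scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

__all__ = ["ScreenResult", "univariable_cox_screen", "correlation_prune", "vif"]

SURVIVAL_COLUMNS = ("time_months", "event")


@dataclass
class ScreenResult:
    """Univariable screening output plus collinearity diagnostics."""

    table: pd.DataFrame  # index: feature; columns: coef, hr, p, kept, constant
    p_threshold: float
    retained: list[str] = field(default_factory=list)  # after correlation pruning
    correlation: pd.DataFrame | None = None
    vif: pd.Series | None = None
    pruning_log: list[str] = field(default_factory=list)

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def _standardise(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=0)
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def univariable_cox_screen(
    cohort: pd.DataFrame,
    features: list[str] | None = None,
    p_threshold: float = 0.25,
) -> ScreenResult:
    """One single-covariate Cox fit per standardised feature.

    A feature is kept iff its Wald p is strictly below ``p_threshold``.
    Constant features cannot be fit; they are dropped with p set to 1 and
    flagged in the ``constant`` column.
    """
    if cohort["event"].sum() < 2:
        raise ValueError("univariable screen needs at least 2 events")
    if features is None:
        features = [c for c in cohort.columns if c not in SURVIVAL_COLUMNS
                    and c != "patient_id" and not c.startswith("truth_")]
    rows = []
    for name in features:
        x = cohort[name]
        if x.std(ddof=0) == 0:
            rows.append({"feature": name, "coef": 0.0, "hr": 1.0, "p": 1.0,
                         "kept": False, "constant": True})
            continue
        df = pd.DataFrame({
            "time_months": cohort["time_months"].to_numpy(),
            "event": cohort["event"].to_numpy(),
            "x": _standardise(x).to_numpy(),
        })
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time_months", event_col="event")
        coef = float(cph.params_["x"])
        p = float(cph.summary.loc["x", "p"])  # Wald test
        rows.append({"feature": name, "coef": coef, "hr": float(np.exp(coef)),
                     "p": p, "kept": p < p_threshold, "constant": False})
    table = pd.DataFrame(rows).set_index("feature")
    return ScreenResult(table=table, p_threshold=p_threshold)


def correlation_prune(
    features: pd.DataFrame,
    screen: ScreenResult,
    r_threshold: float = 0.8,
) -> list[str]:
    """Eliminate highly correlated features, worst univariable p first.

    Builds the graph of feature pairs with |Pearson r| >= threshold among
    the screen's kept features, then repeatedly deletes the feature with
    the largest univariable p among those touching any remaining edge.
    Ties in p break by column order.  The deletion order is logged on the
    screen result, and the surviving set is stored as ``screen.retained``.
    """
    kept = [f for f in features.columns if f in screen.kept]
    corr = features[kept].corr()
    screen.correlation = corr
    alive = list(kept)
    log: list[str] = []
    while True:
        sub = corr.loc[alive, alive].abs()
        np.fill_diagonal(sub.values, 0.0)
        if not (sub.values >= r_threshold).any():
            break
        incident = list(sub.index[(sub.values >= r_threshold).any(axis=1)])
        # highest univariable p goes first; ties break by column order
        max_p = max(screen.table.loc[f, "p"] for f in incident)
        worst = next(f for f in incident if screen.table.loc[f, "p"] == max_p)
        alive.remove(worst)
        log.append(worst)
    screen.retained = alive
    screen.pruning_log = log
    return alive


def vif(features: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R²) from OLS on the rest.

    Perfectly collinear columns report ``inf``.
    """
    cols = list(features.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 features")
    n = len(features)
    if n <= len(cols) + 1:
        raise ValueError(f"VIF needs n > #features + 1 (n={n}, features={len(cols)})")
    x = features.to_numpy(dtype=np.float64)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    out = {}
    for k, name in enumerate(cols):
        others = np.delete(x, k, axis=1)
        y = x[:, k]
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(y @ y)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
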