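"""End-to-end study replica on synthetic cohorts.

simulate -> extract -> split -> pre-select -> LASSO-Cox fit -> score ->
evaluate -> nomogram / decision curves.  All fitting, scaling, penalty
selection and cutoff choice use the training cohort only; the validation
cohort is scored and thresholded with frozen training artefacts.  The
run is fully determined by the seeds in the config, and the emitted JSON
report records them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (
    concordance_index,
    stratify,
    time_dependent_roc,
    youden_cutoff,
)
from .features import DiscretisationScheme, extract_all
from .nomogram_dca import build_nomogram, decision_curve, predict_survival
from .preselection import correlation_prune, univariable_cox_screen, vif
from .signature import build_score, fit_lasso_cox, relax_to_nonzero, score_cohort
from .synthetic import CohortConfig, SurvivalTruth, generate_cohort

__all__ = ["PipelineConfig", "random_split", "extract_features_table", "run_pipeline"]

logger = logging.getLogger("ctibm")


@dataclass
class PipelineConfig:
    """Everything a full run depends on, seeds included."""

    n_patients: int = 154
    split_ratio: float = 99 / 154  # training fraction
    seed_simulation: int = 1
    seed_folds: int = 2
    seed_bootstrap: int = 3
    endpoint: str = "OS"
    bin_number: int = 32
    p_threshold: float = 0.25
    r_threshold: float = 0.8
    folds: int = 10
    horizons: tuple[float, ...] = (12.0, 36.0, 60.0)
    planted_betas: dict[str, float] = field(
        default_factory=lambda: {"log_major_axis": 0.9, "smoothing_sigma": 0.6}
    )
    bootstrap_reps: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")


def random_split(
    cohort: pd.DataFrame, ratio: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simple random partition of patients into training/validation."""
    n = len(cohort)
    if n < 4:
        raise ValueError("need at least 4 patients to split")
    n_train = int(round(n * ratio))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    val_idx = np.sort(perm[n_train:])
    return cohort.iloc[train_idx].reset_index(drop=True), cohort.iloc[val_idx].reset_index(drop=True)


def extract_features_table(
    pairs, table: pd.DataFrame, scheme: DiscretisationScheme | None = None
) -> pd.DataFrame:
    """Run feature extraction for every patient and join with survival."""
    rows = []
    for (vol, roi), pid in zip(pairs, table["patient_id"]):
        feats = extract_all(vol, roi, scheme)
        feats["patient_id"] = pid
        rows.append(feats)
    features = pd.DataFrame(rows)
    return features.merge(table, on="patient_id")


def _evaluate_cohort(
    scores: np.ndarray,
    survival: pd.DataFrame,
    horizons: tuple[float, ...],
    cutoff: float,
    seed: int,
    bootstrap_reps: int,
) -> dict:
    c, c_ci = concordance_index(scores, survival, ci=True, n_boot=bootstrap_reps, seed=seed)
    aucs = {}
    for tau in horizons:
        try:
            roc = time_dependent_roc(scores, survival, tau)
            aucs[str(tau)] = roc.auc
        except ValueError as exc:
            aucs[str(tau)] = None
            logger.warning("ROC at %s months unavailable: %s", tau, exc)
    strat = stratify(scores, survival, cutoff, km_times=horizons)
    return {
        "c_index": c,
        "c_index_ci": list(c_ci),
        "auc_by_horizon": aucs,
        "cutoff": cutoff,
        "hazard_ratio": strat.hazard_ratio,
        "hazard_ratio_ci": list(strat.hr_ci),
        "logrank_p": strat.logrank_p,
        "km_at_times": strat.km_at_times,
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the whole study replica; returns (and optionally writes) the report."""
    logger.info("simulating cohort of %d patients", config.n_patients)
    cohort_cfg = CohortConfig(survival=SurvivalTruth(true_betas=dict(config.planted_betas)))
    pairs, table = generate_cohort(config.n_patients, cohort_cfg, seed=config.seed_simulation)

    scheme = DiscretisationScheme("fixed_bin_number", config.bin_number)
    logger.info("extracting 96 features per patient")
    full = extract_features_table(pairs, table, scheme)

    train, val = random_split(full, config.split_ratio, seed=config.seed_simulation)

    logger.info("pre-selection on training cohort (n=%d)", len(train))
    screen = univariable_cox_screen(train, p_threshold=config.p_threshold)
    feature_cols = list(screen.table.index)
    retained = correlation_prune(train[feature_cols], screen, r_threshold=config.r_threshold)
    if len(retained) >= 2 and len(train) > len(retained) + 1:
        screen.vif = vif(train[retained])

    logger.info("LASSO-Cox over %d retained features", len(retained))
    fit = fit_lasso_cox(train, retained, folds=config.folds, seed=config.seed_folds)
    if fit.all_zero:
        logger.warning("empty model at the CV-selected penalty; relaxing")
        fit = relax_to_nonzero(fit)
    formula = build_score(fit, train, endpoint=config.endpoint)

    train_scores = score_cohort(train, formula)
    val_scores = score_cohort(val, formula)

    # cutoff learned on training only, applied unchanged to validation
    roc_train = time_dependent_roc(train_scores, train, tau=max(config.horizons))
    cutoff = youden_cutoff(roc_train)

    evaluation = {
        "training": _evaluate_cohort(
            train_scores, train, config.horizons, cutoff,
            config.seed_bootstrap, config.bootstrap_reps,
        ),
        "validation": _evaluate_cohort(
            val_scores, val, config.horizons, cutoff,
            config.seed_bootstrap, config.bootstrap_reps,
        ),
    }

    nomogram = build_nomogram(train_scores, train, prediction_times=config.horizons)
    tau = max(config.horizons)
    risks_val = np.array(
        [1.0 - predict_survival(nomogram, s, (tau,))[0][tau] for s in val_scores]
    )
    dca = decision_curve(risks_val, val, tau)

    report = {
        "schema_version": 1,
        "package_version": __version__,
        "config": {**asdict(config), "horizons": list(config.horizons)},
        "cohort_sizes": {"training": len(train), "validation": len(val)},
        "preselection": {
            "kept_after_screen": screen.kept,
            "retained_after_pruning": retained,
            "pruning_order": screen.pruning_log,
            "vif": screen.vif.to_dict() if screen.vif is not None else None,
        },
        "signature": {
            "chosen_lambda": fit.chosen_alpha,
            "n_nonzero": len(fit.coefficients),
            "formula": json.loads(formula.to_json()),
        },
        "evaluation": evaluation,
        "decision_curve": dca.as_frame().to_dict(orient="list"),
        "lineage": {
            "fitting_cohort": "training",
            "validation_used_for": ["scoring", "evaluation", "decision_curve"],
            "seeds": {
                "simulation": config.seed_simulation,
                "folds": config.seed_folds,
                "bootstrap": config.seed_bootstrap,
            },
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        full.to_csv(out / "features.csv", index=False)
        (out / "formula.json").write_text(formula.to_json())
        pd.DataFrame({
            "patient_id": pd.concat([train["patient_id"], val["patient_id"]]),
            "cohort": ["training"] * len(train) + ["validation"] * len(val),
            "score": np.concatenate([train_scores, val_scores]),
        }).to_csv(out / "scores.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        logger.info("report written to %s", out / "report.json")
    return report
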