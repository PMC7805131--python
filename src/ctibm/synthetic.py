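"""Synthetic CT-like tumour cohorts with linked survival outcomes.

The generator emulates the essentials of a planning-CT radiomics study:
ellipsoidal tumour masks on an anisotropic voxel grid (1×1×3 or 1×1×5 mm
slices), a stationary correlated intensity texture inside the tumour
(smoothed Gaussian noise whose correlation length is the tunable
``smoothing_sigma_mm``), and exponential survival times whose hazard is a
configured linear combination of the generative tumour parameters, with
administrative plus uniform random censoring.  Because the hazard is
tied to parameters that specific features measure (tumour size via the
major semi-axis, texture coarseness via the smoothing width), selected
features are informative *by construction* and recovery can be tested.

A purely tabular generator (:func:`generate_feature_cohort`) produces
feature matrices with a small planted set of prognostic columns among
correlated noise, for exercising the model stack without images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import ImageVolume, ROIMask

__all__ = [
    "TumourParams",
    "SurvivalTruth",
    "CohortConfig",
    "generate_tumour",
    "generate_survival",
    "generate_cohort",
    "generate_feature_cohort",
]

#: intensity (HU-like) assigned to every voxel outside the tumour mask
BACKGROUND_VALUE = -100.0


@dataclass(frozen=True)
class TumourParams:
    """Generative parameters of one synthetic tumour."""

    semi_axes_mm: tuple[float, float, float] = (15.0, 12.0, 10.0)
    mean_intensity: float = 60.0
    noise_sd: float = 12.0
    smoothing_sigma_mm: float = 1.5
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes_mm}")
        if min(self.semi_axes_mm) < 2 * max(self.spacing_mm):
            raise ValueError(
                f"semi-axes {self.semi_axes_mm} too small for spacing {self.spacing_mm}: "
                "each must be at least twice the largest voxel dimension so the "
                "discretised mask is non-degenerate"
            )
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError(f"noise_sd must be finite and >= 0, got {self.noise_sd}")
        if self.smoothing_sigma_mm < 0:
            raise ValueError("smoothing_sigma_mm must be >= 0")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")


@dataclass(frozen=True)
class SurvivalTruth:
    """Parameters of the generating proportional-hazards model.

    Event times are exponential with rate ``baseline_rate * exp(lp)``
    (events per month).  Censoring is the minimum of the administrative
    ``censor_horizon`` and a uniform draw on (0, ``uniform_censor_max``];
    shrinking ``uniform_censor_max`` raises the censoring rate.
    """

    baseline_rate: float = 0.02
    censor_horizon: float = 84.0
    uniform_censor_max: float = 250.0
    true_betas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be > 0")
        if self.uniform_censor_max <= 0:
            raise ValueError("uniform_censor_max must be > 0")


def generate_tumour(
    params: TumourParams, seed: int
) -> tuple[ImageVolume, ROIMask, TumourParams]:
    """Generate one tumour volume and its ROI mask.

    The mask is the ellipsoid discretised at voxel centres in physical
    coordinates.  In-mask intensity is ``mean_intensity`` plus a smoothed
    white-noise field rescaled to standard deviation ``noise_sd`` (so the
    marginal noise level is comparable across smoothing widths while the
    spatial correlation length tracks ``smoothing_sigma_mm``).  Outside
    the mask every voxel equals :data:`BACKGROUND_VALUE`.  Identical
    seeds give bit-identical output.
    """
    a = np.asarray(params.semi_axes_mm, dtype=np.float64)
    spacing = np.asarray(params.spacing_mm, dtype=np.float64)
    margin = 2  # voxels of background padding around the ellipsoid
    half = np.ceil(a / spacing).astype(int) + margin
    shape = tuple(2 * half + 1)
    centre = half * spacing
    grids = np.meshgrid(*[np.arange(s) * sp for s, sp in zip(shape, spacing)], indexing="ij")
    r2 = sum(((g - c) / ax) ** 2 for g, c, ax in zip(grids, centre, a))
    indicator = r2 <= 1.0
    if not indicator.any():
        raise ValueError(
            f"degenerate tumour: semi-axes {params.semi_axes_mm} produce an empty mask "
            f"at spacing {params.spacing_mm}"
        )

    values = np.full(shape, BACKGROUND_VALUE, dtype=np.float64)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(shape)
        if params.smoothing_sigma_mm > 0:
            sigma_vox = params.smoothing_sigma_mm / spacing
            noise = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        sd = noise.std()
        if sd > 0:
            noise = noise * (params.noise_sd / sd)
        values[indicator] = params.mean_intensity + noise[indicator]
    else:
        values[indicator] = params.mean_intensity

    vol = ImageVolume(values=values, spacing_mm=tuple(spacing), origin_mm=(0.0, 0.0, 0.0))
    roi = ROIMask(indicator=indicator, spacing_mm=tuple(spacing), origin_mm=(0.0, 0.0, 0.0))
    return vol, roi, params


def generate_survival(
    linear_predictors: np.ndarray, truth: SurvivalTruth, seed: int
) -> pd.DataFrame:
    """Draw (time, event) pairs from the generating hazard model.

    Event time ~ Exponential(rate = baseline_rate * exp(lp)); censoring
    time = min(censor_horizon, U(0, uniform_censor_max]); event = 1 iff
    the event precedes censoring.  Times are strictly positive.
    """
    lp = np.asarray(linear_predictors, dtype=np.float64)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictors must be finite")
    rng = np.random.default_rng(seed)
    rates = truth.baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rates)
    u = rng.uniform(0.0, truth.uniform_censor_max, size=lp.shape)
    t_cens = np.minimum(truth.censor_horizon, np.maximum(u, np.finfo(float).tiny))
    event = (t_event <= t_cens).astype(int)
    time = np.where(event == 1, t_event, t_cens)
    return pd.DataFrame({"time_months": time, "event": event})


@dataclass(frozen=True)
class CohortConfig:
    """Distributions of per-patient tumour parameters and the planted effect.

    ``true_betas`` maps generative parameter names to hazard coefficients.
    Supported names: ``log_major_axis`` (log of the largest semi-axis, mm)
    and ``smoothing_sigma`` (texture correlation length, mm); each is
    standardised over its sampling distribution before entering the
    linear predictor, so a coefficient of log(2) means one SD of the
    parameter doubles the hazard.
    """

    major_axis_range_mm: tuple[float, float] = (10.0, 22.0)
    axis_ratio_range: tuple[float, float] = (0.6, 1.0)
    mean_intensity_sd: float = 8.0
    mean_intensity: float = 60.0
    noise_sd: float = 12.0
    smoothing_sigma_range_mm: tuple[float, float] = (0.5, 3.0)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    survival: SurvivalTruth = field(default_factory=SurvivalTruth)


def _standardise_uniform(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Centre/scale a U(lo, hi) draw by its population mean and SD."""
    mean = (lo + hi) / 2.0
    sd = (hi - lo) / np.sqrt(12.0)
    return (x - mean) / sd


def generate_cohort(
    n: int, config: CohortConfig | None = None, seed: int = 0
) -> tuple[list[tuple[ImageVolume, ROIMask]], pd.DataFrame]:
    """Generate ``n`` patients: images, masks and a survival table.

    The linear predictor of the hazard is the configured combination of
    standardised generative parameters, recorded per patient in
    ``truth_``-prefixed columns of the returned table.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2 patients")
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)

    major = rng.uniform(*config.major_axis_range_mm, size=n)
    ratio_b = rng.uniform(*config.axis_ratio_range, size=n)
    ratio_c = rng.uniform(*config.axis_ratio_range, size=n)
    sigma = rng.uniform(*config.smoothing_sigma_range_mm, size=n)
    intensity = config.mean_intensity + config.mean_intensity_sd * rng.standard_normal(n)

    betas = config.survival.true_betas
    lp = np.zeros(n)
    log_major = np.log(major)
    lo, hi = config.major_axis_range_mm
    if "log_major_axis" in betas:
        # standardise against the population of the uniform sampling range
        lg = np.log(np.linspace(lo, hi, 100_001))
        z = (log_major - lg.mean()) / lg.std()
        lp = lp + betas["log_major_axis"] * z
    if "smoothing_sigma" in betas:
        lp = lp + betas["smoothing_sigma"] * _standardise_uniform(
            sigma, *config.smoothing_sigma_range_mm
        )

    pairs: list[tuple[ImageVolume, ROIMask]] = []
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    for k in range(n):
        params = TumourParams(
            semi_axes_mm=(major[k], major[k] * ratio_b[k], major[k] * ratio_c[k]),
            mean_intensity=float(intensity[k]),
            noise_sd=config.noise_sd,
            smoothing_sigma_mm=float(sigma[k]),
            spacing_mm=config.spacing_mm,
        )
        vol, roi, _ = generate_tumour(params, seed=int(child_seeds[k]))
        pairs.append((vol, roi))

    surv = generate_survival(lp, config.survival, seed=int(rng.integers(0, 2**31 - 1)))
    table = pd.DataFrame(
        {
            "patient_id": [f"P{k:04d}" for k in range(n)],
            "time_months": surv["time_months"].to_numpy(),
            "event": surv["event"].to_numpy(),
            "truth_linear_predictor": lp,
            "truth_major_axis_mm": major,
            "truth_smoothing_sigma_mm": sigma,
        }
    )
    return pairs, table


def generate_feature_cohort(
    n: int,
    n_features: int = 30,
    n_informative: int = 3,
    beta: float = 0.7,
    rho: float = 0.2,
    truth: SurvivalTruth | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Tabular cohort: equicorrelated Gaussian features, planted Cox effect.

    The first ``n_informative`` columns carry coefficient ``beta`` each in
    the hazard's linear predictor; the remainder are prognostically null.
    Features share a pairwise correlation ``rho``.  Returns the cohort
    table (features + time/event) and the informative column names.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    truth = truth or SurvivalTruth()
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal((n, 1))
    x = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((n, n_features))
    names = [f"F{j:03d}" for j in range(n_features)]
    informative = names[:n_informative]
    lp = x[:, :n_informative].sum(axis=1) * beta
    surv = generate_survival(lp, truth, seed=int(rng.integers(0, 2**31 - 1)))
    table = pd.DataFrame(x, columns=names)
    table.insert(0, "patient_id", [f"P{k:04d}" for k in range(n)])
    table["time_months"] = surv["time_months"].to_numpy()
    table["event"] = surv["event"].to_numpy()
    return table, informative
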