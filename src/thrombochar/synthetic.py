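"""Synthetic phantoms and cohorts with known ground truth.

Two generators make the whole pipeline testable without any patient data:

``simulate_thrombus_pair``
    An ellipsoidal thrombus phantom on a regular voxel grid.  NCCT thrombus
    voxels are Normal(mean, SD); the CTA counterpart adds a contrast uplift
    delta (plus noise) to a random *fraction p* of thrombus voxels.  The
    mixture mimics partial contrast penetration of a pervious clot — the
    behaviour the quartile TAI metrics are designed to resolve — with the
    rigid shift as the degenerate p = 1 case.  Ground-truth characteristics
    are computed from the generated voxel values by definition.

``simulate_cohort``
    Patient cohorts whose 90-day mRS follows a proportional-odds
    (cumulative-logit) model and whose first-pass success and final
    reperfusion follow binary logistic models, all on the per-unit-scaled
    characteristics with configurable odds ratios.  Marginal distributions
    of the characteristics and covariates default to values typical of
    Dutch EVT registry/trial populations.  ``inject_missingness`` then
    removes outcome cells completely at random (MCAR) or dependent on an
    observed informer (MAR).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .characteristics import (
    ThrombusCharacteristics,
    build_histograms,
)
from .cohort import (
    CHARACTERISTIC_COLUMNS,
    Cohort,
    SCALINGS,
)
from .errors import ValidationError
from .imaging_io import VoxelVolumePair

# ---------------------------------------------------------------------------
# imaging phantom


@dataclass
class ImagingSimConfig:
    """Configuration of one ellipsoidal thrombus phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    semi_axes_mm: tuple[float, float, float] = (6.0, 4.0, 4.0)
    center_mm: tuple[float, float, float] | None = None  # default: grid centre
    background_hu: float = 35.0
    background_noise_sd: float = 2.0
    thrombus_mean_hu: float = 50.0
    thrombus_sd_hu: float = 9.0
    pervious_fraction: float = 0.3
    uplift_hu: float = 25.0
    uplift_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pervious_fraction <= 1.0:
            raise ValidationError("pervious_fraction must lie in [0, 1]")
        for name in ("thrombus_sd_hu", "uplift_noise_sd", "background_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValidationError("semi-axes must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")


def _population_sd(x: np.ndarray) -> float:
    return float(np.std(x))


def _brute_force_mcc(ncct_vals, cta_vals, bin_width=1.0, max_lag_bins=100) -> float:
    """Ground-truth MCC lag via numpy full cross-correlation (independent route)."""
    hist_n, hist_c = build_histograms(ncct_vals, cta_vals, bin_width)
    a = hist_n.counts
    b = hist_c.counts
    n = len(a)
    # np.correlate(b, a, 'full')[k] = sum_j a[j] * b[j + (k - (n-1))]
    full = np.correlate(b, a, mode="full")
    lags = np.arange(-(n - 1), n)
    keep = np.abs(lags) <= max_lag_bins
    lags, full = lags[keep], full[keep]
    best = full.max()
    candidates = lags[full == best]
    lag = min(candidates, key=lambda l: (abs(l), -np.sign(l)))
    return float(lag * bin_width)


def simulate_thrombus_pair(
    cfg: ImagingSimConfig,
) -> tuple[VoxelVolumePair, ThrombusCharacteristics]:
    """Generate an NCCT/CTA phantom pair and its ground-truth characteristics.

    The mask is the voxelized ellipsoid (voxel centres inside the surface).
    Ground truth is computed directly from the generated voxel values:
    volume as count x voxel volume, quartile TAIs and medians/SDs by their
    definitions, and TAI_MCC by an exhaustive histogram-lag scan.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(int(s) for s in cfg.shape)
    dx, dy, dz = cfg.spacing
    extent = (shape[0] * dx, shape[1] * dy, shape[2] * dz)
    center = cfg.center_mm if cfg.center_mm is not None else tuple(e / 2 for e in extent)
    for c, a, e in zip(center, cfg.semi_axes_mm, extent):
        if c - a < 0 or c + a > e:
            raise ValidationError(
                f"ellipsoid (centre {center}, semi-axes {cfg.semi_axes_mm} mm) "
                f"not contained in grid of extent {extent} mm"
            )
    # voxel-centre coordinates in mm
    xs = (np.arange(shape[0]) + 0.5) * dx
    ys = (np.arange(shape[1]) + 0.5) * dy
    zs = (np.arange(shape[2]) + 0.5) * dz
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    ax, ay, az = cfg.semi_axes_mm
    mask = (
        ((gx - center[0]) / ax) ** 2
        + ((gy - center[1]) / ay) ** 2
        + ((gz - center[2]) / az) ** 2
    ) <= 1.0
    n_fg = int(mask.sum())
    if n_fg == 0:
        raise ValidationError("ellipsoid contains no voxel centres")

    ncct = cfg.background_hu + rng.normal(0.0, cfg.background_noise_sd, size=shape)
    thrombus_vals = rng.normal(cfg.thrombus_mean_hu, cfg.thrombus_sd_hu, size=n_fg)
    ncct[mask] = thrombus_vals

    cta = ncct.copy()
    pervious = rng.random(n_fg) < cfg.pervious_fraction
    uplift = cfg.uplift_hu + rng.normal(0.0, cfg.uplift_noise_sd, size=int(pervious.sum()))
    cta_thrombus = thrombus_vals.copy()
    cta_thrombus[pervious] += uplift
    cta[mask] = cta_thrombus

    pair = VoxelVolumePair(ncct=ncct, cta=cta, mask=mask, spacing=cfg.spacing)
    gt = ThrombusCharacteristics(
        volume_mm3=float(n_fg * dx * dy * dz),
        ncct_median_hu=float(np.median(thrombus_vals)),
        tai_q1_hu=float(np.quantile(cta_thrombus, 0.25) - np.quantile(thrombus_vals, 0.25)),
        tai_q2_hu=float(np.quantile(cta_thrombus, 0.50) - np.quantile(thrombus_vals, 0.50)),
        tai_q3_hu=float(np.quantile(cta_thrombus, 0.75) - np.quantile(thrombus_vals, 0.75)),
        tai_mcc_hu=_brute_force_mcc(thrombus_vals, cta_thrombus),
        cta_median_hu=float(np.median(cta_thrombus)),
        cta_sd_hu=_population_sd(cta_thrombus),
        ncct_sd_hu=_population_sd(thrombus_vals),
    )
    return pair, gt


# ---------------------------------------------------------------------------
# cohort simulation

# Marginal parameters of the nine characteristics, registry-flavoured.
# Volume is lognormal (median, log-SD); all other characteristics Normal
# (mean, SD), with SDs back-solved from interquartile ranges (IQR/1.349).
REGISTRY_CHAR_MEANS = {
    "volume_mm3": 128.0,
    "ncct_median_hu": 47.6,
    "tai_q1_hu": 0.51,
    "tai_q2_hu": 5.8,
    "tai_q3_hu": 11.9,
    "tai_mcc_hu": 4.3,
    "cta_median_hu": 54.0,
    "cta_sd_hu": 21.2,
    "ncct_sd_hu": 8.6,
}
REGISTRY_CHAR_SDS = {
    "volume_mm3": 1.24,  # log-scale SD
    "ncct_median_hu": 4.45,
    "tai_q1_hu": 8.5,
    "tai_q2_hu": 9.9,
    "tai_q3_hu": 13.4,
    "tai_mcc_hu": 9.3,
    "cta_median_hu": 10.9,
    "cta_sd_hu": 8.0,
    "ncct_sd_hu": 2.9,
}
NOIV_CHAR_MEANS = {
    "volume_mm3": 132.0,
    "ncct_median_hu": 49.2,
    "tai_q1_hu": 3.5,
    "tai_q2_hu": 9.6,
    "tai_q3_hu": 15.7,
    "tai_mcc_hu": 7.3,
    "cta_median_hu": 58.0,
    "cta_sd_hu": 24.0,
    "ncct_sd_hu": 9.1,
}
NOIV_CHAR_SDS = {
    "volume_mm3": 1.21,
    "ncct_median_hu": 5.4,
    "tai_q1_hu": 8.1,
    "tai_q2_hu": 9.7,
    "tai_q3_hu": 12.2,
    "tai_mcc_hu": 9.4,
    "cta_median_hu": 9.4,
    "cta_sd_hu": 9.6,
    "ncct_sd_hu": 3.0,
}

REGISTRY_COVARIATES = {
    "age_mean": 72.0, "age_sd": 13.3,
    "male": 0.548,
    "nihss_mean": 16.0, "nihss_sd": 6.7,
    "otp_median": 190.0, "otp_sdlog": 0.50,
    "atherosclerosis": 0.117, "diabetes": 0.157, "hypertension": 0.506,
    "antiplatelet": 0.302, "ivt": 0.684, "atrial_fibrillation": 0.25,
    "prestroke_mrs": (0.653, 0.146, 0.201),
    "aspects_bins": (0.043, 0.197, 0.760),
    "collateral": (0.053, 0.395, 0.389, 0.163),
    "location": (0.039, 0.208, 0.611, 0.142),  # ICA, ICA-t, M1, M2
}
NOIV_COVARIATES = {
    "age_mean": 70.0, "age_sd": 11.1,
    "male": 0.608,
    "nihss_mean": 17.0, "nihss_sd": 6.7,
    "otp_median": 92.0, "otp_sdlog": 0.54,
    "atherosclerosis": 0.162, "diabetes": 0.146, "hypertension": 0.486,
    "antiplatelet": 0.331, "ivt": 0.529, "atrial_fibrillation": 0.25,
    "prestroke_mrs": (0.687, 0.188, 0.125),
    "aspects_bins": (0.035, 0.159, 0.806),
    "collateral": (0.068, 0.288, 0.441, 0.203),
    "location": (0.030, 0.248, 0.637, 0.085),
}

# Marginal probabilities of the INVERTED mRS (0 = dead ... 6 = symptom-free)
# at the mean of the linear predictor.
REGISTRY_MRS_PROBS = (0.273, 0.054, 0.112, 0.131, 0.177, 0.176, 0.077)
NOIV_MRS_PROBS = (0.197, 0.099, 0.092, 0.111, 0.350, 0.115, 0.035)

OUTCOMES = ("mrs", "fps", "etici")

# conditional grade distributions used to expand a binary reperfusion
# success into a full eTICI grade
_ETICI_SUCCESS_GRADES = (("2b", 0.40), ("2c", 0.20), ("3", 0.40))
_ETICI_FAILURE_GRADES = (("0", 0.45), ("1", 0.20), ("2a", 0.35))


@dataclass
class CohortSimConfig:
    """Generating model of one synthetic cohort.

    ``odds_ratios`` maps each outcome ("mrs", "fps", "etici") to a dict of
    per-scaled-unit odds ratios by characteristic name (per 0.1 mL for
    volume, per 10 HU otherwise); unlisted characteristics have OR 1.
    ``mrs_probs`` are the marginal inverted-mRS level probabilities at the
    mean linear predictor, from which the proportional-odds cutpoints are
    derived; ``mrs_cutpoints`` overrides them directly when given.
    ``covariate_outcome_logor`` and ``covariate_char_slopes`` inject
    confounding: centred per-unit log-OR contributions of a covariate on an
    outcome, and linear effects of a covariate on a characteristic's mean.
    """

    n: int = 1000
    seed: int = 0
    population: str = "registry-sim"
    char_means: dict = field(default_factory=lambda: dict(REGISTRY_CHAR_MEANS))
    char_sds: dict = field(default_factory=lambda: dict(REGISTRY_CHAR_SDS))
    char_corr: np.ndarray | None = None
    lognormal_chars: tuple = ("volume_mm3",)
    odds_ratios: dict = field(default_factory=lambda: {o: {} for o in OUTCOMES})
    mrs_probs: tuple = REGISTRY_MRS_PROBS
    mrs_cutpoints: tuple | None = None
    fps_rate: float = 0.34
    etici_success_rate: float = 0.658
    covariates: dict = field(default_factory=lambda: dict(REGISTRY_COVARIATES))
    covariate_outcome_logor: dict = field(default_factory=dict)
    covariate_char_slopes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        for o, ors in self.odds_ratios.items():
            if o not in OUTCOMES:
                raise ValidationError(f"unknown outcome {o!r}")
            for c, v in ors.items():
                if c not in CHARACTERISTIC_COLUMNS:
                    raise ValidationError(f"unknown characteristic {c!r}")
                if v <= 0:
                    raise ValidationError("odds ratios must be > 0")
        if self.mrs_cutpoints is not None:
            cp = np.asarray(self.mrs_cutpoints, dtype=float)
            if len(cp) != 6:
                raise ValidationError("need 6 cutpoints for 7 mRS levels")
            if np.any(np.diff(cp) < 0):
                raise ValidationError("mRS cutpoints must be non-decreasing")
        else:
            probs = np.asarray(self.mrs_probs, dtype=float)
            # small deviations from 1 (rounded percentages) are renormalized
            if len(probs) != 7 or np.any(probs < 0) or abs(probs.sum() - 1) > 5e-3:
                raise ValidationError("mrs_probs must be 7 non-negative values summing to 1")
        if not 0 < self.fps_rate < 1 or not 0 < self.etici_success_rate < 1:
            raise ValidationError("outcome rates must lie in (0, 1)")


def registry_like_config(n: int = 1839, seed: int = 0, **overrides) -> CohortSimConfig:
    """A cohort config mirroring a nationwide EVT registry population."""
    return CohortSimConfig(n=n, seed=seed, population="registry-sim", **overrides)


def no_iv_like_config(n: int = 314, seed: int = 0, **overrides) -> CohortSimConfig:
    """A cohort config mirroring a randomized direct-to-EVT trial population."""
    defaults = dict(
        population="no-iv-sim",
        char_means=dict(NOIV_CHAR_MEANS),
        char_sds=dict(NOIV_CHAR_SDS),
        mrs_probs=NOIV_MRS_PROBS,
        fps_rate=0.518,
        etici_success_rate=0.791,
        covariates=dict(NOIV_COVARIATES),
    )
    defaults.update(overrides)
    return CohortSimConfig(n=n, seed=seed, **defaults)


# Default injected effects for end-to-end demonstrations: the statistically
# significant univariable cells of the study populations these configs emulate.
REGISTRY_TRUE_ORS = {
    "mrs": {
        "volume_mm3": 0.91,
        "tai_q1_hu": 1.14,
        "tai_q2_hu": 1.10,
        "tai_q3_hu": 1.05,
        "tai_mcc_hu": 1.11,
        "cta_median_hu": 1.09,
        "cta_sd_hu": 0.93,
        "ncct_sd_hu": 0.87,
    },
    "fps": {},
    "etici": {"ncct_sd_hu": 0.88},
}
NOIV_TRUE_ORS = {
    "mrs": {
        "tai_q1_hu": 1.20,
        "tai_q2_hu": 1.22,
        "tai_q3_hu": 1.16,
        "tai_mcc_hu": 1.17,
        "cta_median_hu": 1.23,
    },
    "fps": {"ncct_sd_hu": 0.55},
    "etici": {},
}

# Outcome-wise missingness rates of the two emulated populations.
REGISTRY_MISSING_RATES = {"mrs_90d": 0.09, "fps": 0.25, "etici": 0.04}
NOIV_MISSING_RATES = {"mrs_90d": 0.0, "fps": 0.12, "etici": 0.09}


def _scaled(name: str, values: np.ndarray) -> np.ndarray:
    return np.asarray(values, dtype=float) / SCALINGS[name][0]


def _char_mean(cfg: CohortSimConfig, name: str) -> float:
    """Expected raw value of a characteristic under the config's marginal."""
    if name in cfg.lognormal_chars:
        return cfg.char_means[name] * float(np.exp(cfg.char_sds[name] ** 2 / 2))
    return cfg.char_means[name]


def _linear_predictors(cfg: CohortSimConfig, chars: pd.DataFrame, cov: pd.DataFrame):
    """Per-patient eta and its population mean eta-bar for each outcome."""
    etas, eta_bars = {}, {}
    for outcome in OUTCOMES:
        eta = np.zeros(len(chars))
        eta_bar = 0.0
        for name, or_ in cfg.odds_ratios.get(outcome, {}).items():
            beta = float(np.log(or_))
            eta += beta * _scaled(name, chars[name].to_numpy())
            eta_bar += beta * _char_mean(cfg, name) / SCALINGS[name][0]
        for cov_name, beta in cfg.covariate_outcome_logor.get(outcome, {}).items():
            x = cov[cov_name].to_numpy(dtype=float)
            eta += beta * (x - x.mean())  # centred: rates stay anchored
        etas[outcome], eta_bars[outcome] = eta, eta_bar
    return etas, eta_bars


def _simulate_covariates(cfg: CohortSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    p = cfg.covariates
    n = cfg.n
    from .cohort import OCCLUSION_LOCATIONS

    aspects_bin = rng.choice(3, size=n, p=np.asarray(p["aspects_bins"]) / sum(p["aspects_bins"]))
    aspects = np.empty(n, dtype=int)
    for b, (lo, hi) in enumerate(((0, 4), (5, 7), (8, 10))):
        idx = aspects_bin == b
        aspects[idx] = rng.integers(lo, hi + 1, size=int(idx.sum()))
    cov = pd.DataFrame(
        {
            "age": rng.normal(p["age_mean"], p["age_sd"], n).round(1),
            "sex": rng.random(n) < p["male"],
            "nihss_baseline": np.clip(
                np.round(rng.normal(p["nihss_mean"], p["nihss_sd"], n)), 0, 42
            ).astype(int),
            "onset_to_puncture_min": np.round(
                p["otp_median"] * np.exp(rng.normal(0, p["otp_sdlog"], n)), 1
            ),
            "ivt": rng.random(n) < p["ivt"],
            "antiplatelet": rng.random(n) < p["antiplatelet"],
            "diabetes": rng.random(n) < p["diabetes"],
            "atrial_fibrillation": rng.random(n) < p["atrial_fibrillation"],
            "atherosclerosis": rng.random(n) < p["atherosclerosis"],
            "hypertension": rng.random(n) < p["hypertension"],
            "prestroke_mrs": rng.choice(
                3, size=n, p=np.asarray(p["prestroke_mrs"]) / sum(p["prestroke_mrs"])
            ),
            "aspects": aspects,
            "collateral_score": rng.choice(
                4, size=n, p=np.asarray(p["collateral"]) / sum(p["collateral"])
            ),
            "occlusion_location": rng.choice(
                OCCLUSION_LOCATIONS, size=n, p=np.asarray(p["location"]) / sum(p["location"])
            ),
        }
    )
    for c in ("sex", "ivt", "antiplatelet", "diabetes", "atrial_fibrillation",
              "atherosclerosis", "hypertension"):
        cov[c] = cov[c].astype(int)
    return cov


def simulate_cohort(cfg: CohortSimConfig) -> Cohort:
    """Draw a cohort from the configured generating model.

    Characteristics come from a (possibly correlated) Gaussian copula with
    the configured marginals; the inverted mRS is sampled from a
    proportional-odds model, FPS and eTICI >= 2b from logistic models, each
    anchored so that the marginal outcome distribution at the mean linear
    predictor matches the configured rates.  The binary reperfusion success
    is expanded into a full eTICI grade.  The generating parameters are
    stored in ``Cohort.ground_truth``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    names = CHARACTERISTIC_COLUMNS
    k = len(names)
    corr = np.eye(k) if cfg.char_corr is None else np.asarray(cfg.char_corr, dtype=float)
    if corr.shape != (k, k):
        raise ValidationError(f"char_corr must be {k}x{k}")
    z = rng.multivariate_normal(np.zeros(k), corr, size=n, method="cholesky")
    chars = pd.DataFrame(index=range(n))
    for j, name in enumerate(names):
        if name in cfg.lognormal_chars:
            chars[name] = cfg.char_means[name] * np.exp(cfg.char_sds[name] * z[:, j])
        else:
            chars[name] = cfg.char_means[name] + cfg.char_sds[name] * z[:, j]

    cov = _simulate_covariates(cfg, rng)
    for char_name, slopes in cfg.covariate_char_slopes.items():
        for cov_name, slope in slopes.items():
            x = cov[cov_name].to_numpy(dtype=float)
            chars[char_name] = chars[char_name] + slope * (x - x.mean())

    etas, eta_bars = _linear_predictors(cfg, chars, cov)

    # ordinal mRS via cumulative logits: P(Y_inv <= k) = expit(c_k - eta)
    if cfg.mrs_cutpoints is not None:
        cutpoints = np.asarray(cfg.mrs_cutpoints, dtype=float)
    else:
        cum = (np.cumsum(cfg.mrs_probs) / np.sum(cfg.mrs_probs))[:6]
        cutpoints = logit(np.clip(cum, 1e-12, 1 - 1e-12)) + eta_bars["mrs"]
    u = rng.random(n)
    cum_probs = expit(cutpoints[None, :] - etas["mrs"][:, None])  # n x 6
    inv_mrs = (u[:, None] > cum_probs).sum(axis=1)  # 0..6
    mrs = 6 - inv_mrs

    p_fps = expit(logit(cfg.fps_rate) - eta_bars["fps"] + etas["fps"])
    fps = (rng.random(n) < p_fps).astype(int)

    p_rep = expit(logit(cfg.etici_success_rate) - eta_bars["etici"] + etas["etici"])
    success = rng.random(n) < p_rep
    grades_s, probs_s = zip(*_ETICI_SUCCESS_GRADES)
    grades_f, probs_f = zip(*_ETICI_FAILURE_GRADES)
    etici = np.where(
        success,
        rng.choice(grades_s, size=n, p=probs_s),
        rng.choice(grades_f, size=n, p=probs_f),
    )

    df = pd.DataFrame({"id": [f"P{i + 1:05d}" for i in range(n)], "population": cfg.population})
    for name in names:
        df[name] = chars[name].astype(float)
    for c in cov.columns:
        df[c] = cov[c]
    df["mrs_90d"] = mrs
    df["fps"] = fps
    df["etici"] = etici
    for c in ("sex", "nihss_baseline", "ivt", "antiplatelet", "diabetes",
              "atrial_fibrillation", "atherosclerosis", "hypertension",
              "prestroke_mrs", "aspects", "collateral_score", "mrs_90d", "fps"):
        df[c] = df[c].astype("Int64")
    df["age"] = df["age"].astype(float)
    df["onset_to_puncture_min"] = df["onset_to_puncture_min"].astype(float)

    gt = {
        "odds_ratios": {o: dict(v) for o, v in cfg.odds_ratios.items()},
        "config": {
            key: val
            for key, val in asdict(cfg).items()
            if key not in ("char_corr",)
        },
    }
    return Cohort(df, provenance="simulated", ground_truth=gt)


def _mar_probs(rate: float, odds_ratio: float) -> tuple[float, float]:
    """Group-wise missingness probabilities (below/above the informer median)
    with the given missingness odds ratio and overall expected rate."""
    if rate == 0:
        return 0.0, 0.0

    def f(p_low):
        odds_high = odds_ratio * p_low / (1 - p_low)
        p_high = odds_high / (1 + odds_high)
        return 0.5 * (p_low + p_high) - rate

    p_low = brentq(f, 1e-12, min(1 - 1e-12, 2 * rate))
    odds_high = odds_ratio * p_low / (1 - p_low)
    return p_low, odds_high / (1 + odds_high)


def inject_missingness(
    cohort: Cohort,
    rates: dict[str, float],
    mechanism: str = "MCAR",
    seed: int = 0,
    mar_informer: str = "age",
    mar_odds_ratio: float = 2.0,
) -> Cohort:
    """Blank cells of the given columns at the given expected rates.

    MCAR blanks each cell independently with its rate.  MAR conditions the
    missingness on an observed informer: rows above the informer's median
    have ``mar_odds_ratio`` times the missingness odds of rows below, with
    the overall expected rate preserved.
    """
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValidationError(f"rate for {col!r} outside [0, 1]")
        if col not in cohort.df.columns:
            raise ValidationError(f"column {col!r} not in cohort")
    if mechanism not in ("MCAR", "MAR"):
        raise ValidationError(f"unknown mechanism {mechanism!r}")
    rng = np.random.default_rng(seed)
    df = cohort.df.copy()
    for col, rate in rates.items():
        if rate == 0:
            continue
        if mechanism == "MCAR":
            miss = rng.random(len(df)) < rate
        else:
            informer = df[mar_informer].to_numpy(dtype=float)
            high = informer > np.median(informer)
            p_low, p_high = _mar_probs(rate, mar_odds_ratio)
            miss = rng.random(len(df)) < np.where(high, p_high, p_low)
        df.loc[miss, col] = pd.NA if df[col].dtype != float else np.nan
    return Cohort(df, provenance=cohort.provenance, ground_truth=dict(cohort.ground_truth))
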