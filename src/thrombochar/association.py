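"""Associations between thrombus characteristics and treatment outcomes.

Three outcomes are analysed: the 90-day modified Rankin Scale (mRS, inverted
so that higher = better and odds ratios below one indicate a worse
functional outcome), first-pass success (FPS), and final successful
reperfusion (eTICI >= 2b).  The inverted mRS is modelled with a
proportional-odds cumulative-logit regression; the two technical success
measures with binary logistic regression.  Predictors enter the models
scaled to their reporting unit — per 0.1 mL for volume, per 10 HU for every
HU-valued characteristic — so exp(coefficient) is directly the reported OR.

Inference is Wald throughout (point estimate, 95% CI, p-value), which keeps
pooled inference under Rubin's rules tractable.  Missing data are handled by
chained-equation multiple imputation with bootstrap-refitted additive
regressions and predictive mean matching (PMM), pooled with Rubin's rules on
the log-OR scale using Barnard-Rubin degrees of freedom, with a complete-case
path as a sensitivity analysis.  Population comparisons use Mann-Whitney U
tests for numerical variables and chi-square tests for categorical ones; no
multiple-testing correction is applied, and significance is flagged at the
nominal p < 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .cohort import (
    CHARACTERISTIC_COLUMNS,
    Cohort,
    ETICI_GRADES,
    ETICI_SUCCESS,
    SCALINGS,
)
from .errors import FittingError, ValidationError

logger = logging.getLogger(__name__)

Z975 = float(stats.norm.ppf(0.975))

#: default adjustment set = the imputation informers
DEFAULT_CONFOUNDERS = [
    "age",
    "occlusion_location",
    "nihss_baseline",
    "ivt",
    "diabetes",
    "onset_to_puncture_min",
    "antiplatelet",
    "atrial_fibrillation",
    "atherosclerosis",
    "collateral_score",
]

OUTCOME_COLUMNS = {"mrs": "mrs_90d", "fps": "fps", "etici": "etici"}


# ---------------------------------------------------------------------------
# codings


def invert_mrs(mrs):
    """Invert the mRS (6 - mrs) so that higher values mean a better outcome."""
    arr = np.asarray(mrs)
    if np.any((arr < 0) | (arr > 6)) or not np.allclose(arr, np.round(arr)):
        raise ValidationError(f"mRS values must be integers in 0..6")
    inv = 6 - arr
    return int(inv) if np.isscalar(mrs) else inv


def binarize_reperfusion(etici):
    """1 iff the eTICI grade is 2b, 2c or 3 (more than 50% reperfusion)."""
    if isinstance(etici, str):
        if etici not in ETICI_GRADES:
            raise ValidationError(f"unknown eTICI grade {etici!r}")
        return int(etici in ETICI_SUCCESS)
    out = []
    for g in etici:
        if g not in ETICI_GRADES:
            raise ValidationError(f"unknown eTICI grade {g!r}")
        out.append(int(g in ETICI_SUCCESS))
    return np.asarray(out)


def scale_predictor(name: str, raw_value):
    """Scale a raw characteristic to its model unit (per 0.1 mL / per 10 HU)."""
    if name not in SCALINGS:
        raise ValidationError(f"unknown characteristic {name!r}")
    divisor, _ = SCALINGS[name]
    arr = np.asarray(raw_value, dtype=float) / divisor
    return float(arr) if np.isscalar(raw_value) else arr


# ---------------------------------------------------------------------------
# results


@dataclass
class AssociationResult:
    """One cell of the OR grid: a fitted (predictor, outcome) association."""

    predictor: str
    scaling: str
    outcome: str
    model: str  # "ordinal" | "binary"
    adjusted: bool
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    pooled: bool = False
    log_or: float = float("nan")
    se: float = float("nan")
    df_resid: float = float("inf")

    def __post_init__(self) -> None:
        if not self.or_ > 0:
            raise ValidationError("OR must be > 0")
        if not (self.ci_low <= self.or_ <= self.ci_high):
            raise ValidationError("CI must bracket the OR")
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p-value outside [0, 1]")


def _wald_result(
    beta: float, se: float, n: int, df_resid: float, *, predictor, outcome,
    model, adjusted, pooled=False,
) -> AssociationResult:
    return AssociationResult(
        predictor=predictor,
        scaling=SCALINGS[predictor][1],
        outcome=outcome,
        model=model,
        adjusted=adjusted,
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        p_value=float(2 * stats.norm.sf(abs(beta) / se)),
        n_used=n,
        pooled=pooled,
        log_or=float(beta),
        se=float(se),
        df_resid=df_resid,
    )


# ---------------------------------------------------------------------------
# design-matrix helpers


def _outcome_vector(df: pd.DataFrame, outcome: str) -> pd.Series:
    col = OUTCOME_COLUMNS[outcome]
    if outcome == "mrs":
        return pd.Series(invert_mrs(df[col].astype(int).to_numpy()), index=df.index)
    if outcome == "fps":
        return df[col].astype(int)
    return pd.Series(binarize_reperfusion(list(df[col])), index=df.index)


def _confounder_matrix(df: pd.DataFrame, confounders) -> pd.DataFrame:
    cols = {}
    for c in confounders:
        if c == "occlusion_location":
            dummies = pd.get_dummies(df[c], prefix="loc", dtype=float)
            # drop the first present level as reference
            for d in dummies.columns[1:]:
                cols[d] = dummies[d]
        else:
            cols[c] = df[c].astype(float)
    return pd.DataFrame(cols, index=df.index)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[0] <= X.shape[1]:
        raise FittingError("more design columns than observations")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns via pivoted QR on the centred design
        _, r, piv = linalg.qr(X, pivoting=True, mode="economic")
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise FittingError(f"collinear design; aliased columns: {aliased}")


def _prepare(cohort: Cohort, predictor: str, outcome: str, confounders):
    """Drop rows with missing analysis variables; return (y, X, names, n)."""
    if predictor not in CHARACTERISTIC_COLUMNS:
        raise ValidationError(f"unknown characteristic {predictor!r}")
    if outcome not in OUTCOME_COLUMNS:
        raise ValidationError(f"unknown outcome {outcome!r}")
    needed = [predictor, OUTCOME_COLUMNS[outcome]] + [c for c in confounders]
    df = cohort.df.dropna(subset=[c for c in needed if c in cohort.df.columns])
    missing_cols = [c for c in needed if c not in cohort.df.columns]
    if missing_cols:
        raise ValidationError(f"cohort lacks columns {missing_cols}")
    if len(df) == 0:
        raise ValidationError("no complete rows for this model")
    y = _outcome_vector(df, outcome)
    x = scale_predictor(predictor, df[predictor].to_numpy(dtype=float))
    if np.ptp(x) == 0:
        raise ValidationError(f"predictor {predictor!r} is constant")
    X = pd.DataFrame({predictor: x}, index=df.index)
    if confounders:
        X = pd.concat([X, _confounder_matrix(df, confounders)], axis=1)
    names = list(X.columns)
    _check_full_rank(X.to_numpy(dtype=float), names)
    return y, X, names, len(df)


# ---------------------------------------------------------------------------
# model fits


def _fit_ordinal_core(y: pd.Series, X: pd.DataFrame):
    levels = np.sort(y.unique())
    if len(levels) < 2:
        raise ValidationError("outcome has fewer than 2 distinct levels")
    endog = pd.Series(pd.Categorical(y, categories=levels, ordered=True), index=y.index)
    model = OrderedModel(endog, X.astype(float), distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="bfgs", maxiter=500, disp=False, gtol=1e-8)
        except Exception as exc:
            raise FittingError(f"ordinal fit failed: {exc}") from exc
    # BFGS can report precision loss when already at the optimum; accept any
    # solution whose score is numerically zero, reject drifting (separated) fits
    gnorm = float(np.max(np.abs(model.score(np.asarray(res.params)))))
    if np.max(np.abs(np.asarray(res.params))) > 30:
        raise FittingError("ordinal fit diverged; check for separation")
    if not res.mle_retvals.get("converged", False) and gnorm > 1e-3:
        raise FittingError(
            f"ordinal fit did not converge (gradient norm {gnorm:.3g}); "
            "check for separation or sparse outcome levels"
        )
    return res


def _fit_binary_core(y: pd.Series, X: pd.DataFrame):
    Xc = sm.add_constant(X.to_numpy(dtype=float), prepend=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y.to_numpy(dtype=float), Xc).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise FittingError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FittingError("logistic fit did not converge; check for separation")
    return res


def fit_univariable_ordinal(cohort: Cohort, predictor: str) -> AssociationResult:
    """Proportional-odds fit of the inverted mRS on one scaled characteristic."""
    y, X, _, n = _prepare(cohort, predictor, "mrs", [])
    res = _fit_ordinal_core(y, X)
    beta, se = float(np.asarray(res.params)[0]), float(np.asarray(res.bse)[0])
    return _wald_result(
        beta, se, n, n - len(res.params),
        predictor=predictor, outcome="mrs", model="ordinal", adjusted=False,
    )


def fit_univariable_binary(cohort: Cohort, predictor: str, outcome: str) -> AssociationResult:
    """Logistic fit of FPS or eTICI >= 2b on one scaled characteristic."""
    if outcome not in ("fps", "etici"):
        raise ValidationError("binary outcome must be 'fps' or 'etici'")
    y, X, _, n = _prepare(cohort, predictor, outcome, [])
    if y.nunique() < 2:
        raise ValidationError("outcome has fewer than 2 distinct levels")
    res = _fit_binary_core(y, X)
    beta, se = float(np.asarray(res.params)[1]), float(np.asarray(res.bse)[1])
    return _wald_result(
        beta, se, n, n - len(res.params),
        predictor=predictor, outcome=outcome, model="binary", adjusted=False,
    )


def fit_adjusted(
    cohort: Cohort, predictor: str, outcome: str, confounders=None
) -> AssociationResult:
    """Characteristic-outcome OR conditional on a confounder set.

    The default confounder list equals the imputation informers; an empty
    list reduces to the univariable fit.
    """
    confounders = DEFAULT_CONFOUNDERS if confounders is None else list(confounders)
    y, X, _, n = _prepare(cohort, predictor, outcome, confounders)
    if outcome == "mrs":
        res = _fit_ordinal_core(y, X)
        beta, se = float(np.asarray(res.params)[0]), float(np.asarray(res.bse)[0])
        model = "ordinal"
    else:
        if y.nunique() < 2:
            raise ValidationError("outcome has fewer than 2 distinct levels")
        res = _fit_binary_core(y, X)
        beta, se = float(np.asarray(res.params)[1]), float(np.asarray(res.bse)[1])
        model = "binary"
    return _wald_result(
        beta, se, n, n - len(res.params),
        predictor=predictor, outcome=outcome, model=model,
        adjusted=bool(confounders),
    )


# ---------------------------------------------------------------------------
# multiple imputation


IMPUTABLE_EXTRA = ["mrs_90d", "fps", "etici", "prestroke_mrs", "aspects",
                   "collateral_score", "nihss_baseline"]


def _encode_for_imputation(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Numeric view of the cohort for regression: eTICI as ordered codes,
    occlusion location as one-hot columns."""
    enc = pd.DataFrame(index=df.index)
    meta = {}
    for col in df.columns:
        if col in ("id", "population"):
            continue
        if col == "etici":
            codes = df[col].map({g: i for i, g in enumerate(ETICI_GRADES)})
            enc[col] = codes.astype(float)
            meta[col] = "etici"
        elif col == "occlusion_location":
            dummies = pd.get_dummies(df[col], prefix="loc", dtype=float)
            for d in dummies.columns:
                enc[d] = dummies[d].where(df[col].notna(), np.nan)
            meta[col] = list(dummies.columns)
        else:
            enc[col] = df[col].astype(float)
            meta[col] = "numeric"
    return enc, meta


def impute_cohort(
    cohort: Cohort,
    m: int = 5,
    informers=None,
    seed: int = 0,
    n_burnin: int = 10,
    k_donors: int = 5,
) -> list[Cohort]:
    """Multiple imputation by chained equations with bootstrap PMM.

    For each of the ``m`` imputations, every incompletely observed column is
    visited in order of increasing missingness for ``n_burnin`` sweeps.  On
    each visit an additive (linear) regression of the column on the
    informers and the other analysis variables is fitted to a bootstrap
    resample of the observed rows; each missing cell then receives the
    observed value of one of the ``k_donors`` donors whose predicted means
    are closest to its own (predictive mean matching), so every imputed
    value is an observed value of its column.  eTICI is imputed as an
    ordered categorical (grade codes) and only binarized at analysis time.
    Observed cells are identical across the returned cohorts.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    informers = DEFAULT_CONFOUNDERS if informers is None else list(informers)
    df = cohort.df
    enc, meta = _encode_for_imputation(df)
    targets = [
        c for c in enc.columns
        if enc[c].isna().any() and not c.startswith("loc_")
    ]
    loc_missing = df["occlusion_location"].isna().any() if "occlusion_location" in df else False
    if loc_missing:
        raise ValidationError("imputation of occlusion_location is not supported")
    fully_missing = [c for c in targets if enc[c].isna().all()]
    if fully_missing:
        raise ValidationError(f"columns fully missing, cannot impute: {fully_missing}")
    if not targets:
        return [cohort.copy() for _ in range(m)]
    targets.sort(key=lambda c: (int(enc[c].isna().sum()), c))

    # predictor pool: informers (encoded) + other targets
    informer_cols = []
    for c in informers:
        if c == "occlusion_location":
            informer_cols.extend(meta[c])
        elif c in enc.columns:
            informer_cols.append(c)
        else:
            raise ValidationError(f"informer column {c!r} not in cohort")

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(m)
    completed: list[Cohort] = []
    for j in range(m):
        rng = np.random.default_rng(child_seeds[j])
        cur = enc.copy()
        # initial fill: random draws from the observed values
        for col in targets:
            obs_vals = enc[col].dropna().to_numpy()
            miss_idx = enc.index[enc[col].isna()]
            cur.loc[miss_idx, col] = rng.choice(obs_vals, size=len(miss_idx))
        for _ in range(n_burnin):
            for col in targets:
                obs_mask = enc[col].notna().to_numpy()
                predictors = [c for c in dict.fromkeys(informer_cols + targets) if c != col]
                X = cur[predictors].to_numpy(dtype=float)
                X = np.column_stack([np.ones(len(X)), X])
                y_obs = enc[col].to_numpy(dtype=float)[obs_mask]
                X_obs, X_mis = X[obs_mask], X[~obs_mask]
                boot = rng.integers(0, len(y_obs), size=len(y_obs))
                coef, *_ = np.linalg.lstsq(X_obs[boot], y_obs[boot], rcond=None)
                yhat_obs = X_obs @ coef
                yhat_mis = X_mis @ coef
                dist = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
                k = min(k_donors, len(y_obs))
                donors = np.argpartition(dist, k - 1, axis=1)[:, :k]
                pick = donors[np.arange(len(yhat_mis)), rng.integers(0, k, len(yhat_mis))]
                cur.loc[~obs_mask, col] = y_obs[pick]
        out = df.copy()
        for col in targets:
            miss_idx = df.index[enc[col].isna()]
            if meta.get(col) == "etici":
                out.loc[miss_idx, "etici"] = [
                    ETICI_GRADES[int(round(v))] for v in cur.loc[miss_idx, col]
                ]
            elif str(df[col].dtype) == "Int64":
                out.loc[miss_idx, col] = np.round(cur.loc[miss_idx, col]).astype(int)
            else:
                out.loc[miss_idx, col] = cur.loc[miss_idx, col].to_numpy()
        completed.append(Cohort(out, provenance=cohort.provenance,
                                ground_truth=dict(cohort.ground_truth)))
    return completed


def pool_rubin(results: list[AssociationResult]) -> AssociationResult:
    """Pool m fits of one model with Rubin's rules on the log-OR scale.

    Total variance is W + (1 + 1/m) B; the reference distribution is t with
    Barnard-Rubin degrees of freedom.  With zero between-imputation variance
    (or m = 1) this reduces exactly to the single-fit Wald inference.
    """
    if not results:
        raise ValidationError("no results to pool")
    first = results[0]
    for r in results[1:]:
        if (r.predictor, r.outcome, r.model, r.adjusted) != (
            first.predictor, first.outcome, first.model, first.adjusted
        ):
            raise ValidationError("cannot pool results of different model specs")
    m = len(results)
    if m == 1:
        return replace(first, pooled=True)
    q = np.array([r.log_or for r in results])
    w = np.array([r.se**2 for r in results])
    qbar = float(q.mean())
    W = float(w.mean())
    B = float(q.var(ddof=1))
    T = W + (1 + 1 / m) * B
    se = float(np.sqrt(T))
    if B <= 0:
        crit, p = Z975, float(2 * stats.norm.sf(abs(qbar) / se))
    else:
        lam = (1 + 1 / m) * B / T
        nu_old = (m - 1) / lam**2
        nu_com = float(min(r.df_resid for r in results))
        nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
        nu = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
        crit = float(stats.t.ppf(0.975, nu))
        p = float(2 * stats.t.sf(abs(qbar) / se, nu))
    return AssociationResult(
        predictor=first.predictor,
        scaling=first.scaling,
        outcome=first.outcome,
        model=first.model,
        adjusted=first.adjusted,
        or_=float(np.exp(qbar)),
        ci_low=float(np.exp(qbar - crit * se)),
        ci_high=float(np.exp(qbar + crit * se)),
        p_value=p,
        n_used=first.n_used,
        pooled=True,
        log_or=qbar,
        se=se,
        df_resid=first.df_resid,
    )


# ---------------------------------------------------------------------------
# cohort comparison and summaries

NUMERIC_COMPARE = CHARACTERISTIC_COLUMNS + [
    "age", "nihss_baseline", "onset_to_puncture_min",
]
CATEGORICAL_COMPARE = [
    "sex", "atherosclerosis", "diabetes", "hypertension", "antiplatelet",
    "ivt", "atrial_fibrillation", "prestroke_mrs", "aspects",
    "collateral_score", "occlusion_location", "fps", "etici", "mrs_90d",
]


def compare_populations(
    cohort_a: Cohort, cohort_b: Cohort, variables=None
) -> pd.DataFrame:
    """Per-variable two-population tests.

    Numerical variables are compared with the Mann-Whitney U test (normal
    approximation with tie and continuity correction); categorical variables
    with the chi-square test on the contingency table (Yates correction for
    2x2 tables only).  Returns a table with the statistic, p-value and a
    nominal-significance flag at p < 0.05.
    """
    if variables is None:
        variables = [v for v in NUMERIC_COMPARE + CATEGORICAL_COMPARE]
    rows = []
    for var in variables:
        if var not in cohort_a.df.columns or var not in cohort_b.df.columns:
            warnings.warn(f"variable {var!r} absent in one cohort; skipped")
            continue
        a = cohort_a.df[var].dropna()
        b = cohort_b.df[var].dropna()
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"variable {var!r} has no observed values; skipped")
            continue
        if var in NUMERIC_COMPARE:
            stat, p = stats.mannwhitneyu(
                a.astype(float), b.astype(float),
                alternative="two-sided", use_continuity=True, method="asymptotic",
            )
            test = "mann-whitney"
        else:
            levels = sorted(set(a) | set(b), key=str)
            table = np.array(
                [[int((a == lv).sum()) for lv in levels],
                 [int((b == lv).sum()) for lv in levels]]
            )
            table = table[:, table.sum(axis=0) > 0]
            yates = table.shape == (2, 2)
            stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
            test = "chi-square"
        rows.append(
            {"variable": var, "test": test, "statistic": float(stat),
             "p_value": float(p), "significant": bool(p < 0.05),
             "n_a": int(len(a)), "n_b": int(len(b))}
        )
    return pd.DataFrame(rows)


_PRESTROKE_GROUPS = (("0", (0, 0)), ("1", (1, 1)), (">=2", (2, 6)))
_ASPECTS_GROUPS = (("0-4", (0, 4)), ("5-7", (5, 7)), ("8-10", (8, 10)))


def summarize_cohort(cohort: Cohort, variables=None) -> pd.DataFrame:
    """Descriptive summary: median (IQR) for numerical variables, n (%) for
    categorical ones, with pre-stroke mRS grouped as {0, 1, >=2} and ASPECTS
    as {0-4, 5-7, 8-10}.  The available n is reported per variable."""
    if variables is None:
        variables = [v for v in NUMERIC_COMPARE + CATEGORICAL_COMPARE
                     if v in cohort.df.columns]
    if len(cohort.df) == 0:
        raise ValidationError("empty cohort")
    rows = []
    for var in variables:
        vals = cohort.df[var].dropna()
        n_avail = int(len(vals))
        if var in NUMERIC_COMPARE:
            x = vals.astype(float)
            med = float(np.median(x)) if n_avail else np.nan
            q1 = float(np.quantile(x, 0.25)) if n_avail else np.nan
            q3 = float(np.quantile(x, 0.75)) if n_avail else np.nan
            rows.append(
                {"variable": var, "level": "", "kind": "numeric",
                 "n_available": n_avail, "median": med, "q1": q1, "q3": q3,
                 "count": np.nan, "percent": np.nan}
            )
        else:
            if var == "prestroke_mrs":
                groups = [
                    (label, int(((vals >= lo) & (vals <= hi)).sum()))
                    for label, (lo, hi) in _PRESTROKE_GROUPS
                ]
            elif var == "aspects":
                groups = [
                    (label, int(((vals >= lo) & (vals <= hi)).sum()))
                    for label, (lo, hi) in _ASPECTS_GROUPS
                ]
            else:
                groups = [
                    (str(lv), int((vals == lv).sum()))
                    for lv in sorted(set(vals), key=str)
                ]
            for label, count in groups:
                rows.append(
                    {"variable": var, "level": label, "kind": "categorical",
                     "n_available": n_avail, "median": np.nan, "q1": np.nan,
                     "q3": np.nan, "count": count,
                     "percent": 100.0 * count / n_avail if n_avail else 0.0}
                )
    return pd.DataFrame(rows)


def complete_case(cohort: Cohort, required_columns) -> Cohort:
    """Keep only records with every required column observed."""
    required = list(required_columns)
    missing_cols = [c for c in required if c not in cohort.df.columns]
    if missing_cols:
        raise ValidationError(f"cohort lacks columns {missing_cols}")
    kept = cohort.df.dropna(subset=required)
    dropped = len(cohort.df) - len(kept)
    logger.info("complete_case: dropped %d of %d records", dropped, len(cohort.df))
    if len(kept) == 0:
        raise ValidationError("complete-case analysis leaves no records")
    return Cohort(kept.reset_index(drop=True), provenance=cohort.provenance,
                  ground_truth=dict(cohort.ground_truth))
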