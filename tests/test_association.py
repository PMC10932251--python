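import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import thrombochar as tc
from thrombochar.association import DEFAULT_CONFOUNDERS, OUTCOME_COLUMNS
from thrombochar.errors import ValidationError


# ---------------------------------------------------------------------------
# codings


@given(st.integers(0, 6))
def test_invert_mrs_involution(m):
    assert tc.invert_mrs(tc.invert_mrs(m)) == m


def test_invert_mrs_endpoints_and_domain():
    assert tc.invert_mrs(0) == 6
    assert tc.invert_mrs(6) == 0
    with pytest.raises(ValidationError):
        tc.invert_mrs(7)


@pytest.mark.parametrize(
    "grade, expected",
    [("2b", 1), ("2c", 1), ("3", 1), ("2a", 0), ("1", 0), ("0", 0)],
)
def test_binarize_reperfusion(grade, expected):
    assert tc.binarize_reperfusion(grade) == expected


def test_binarize_unknown_grade():
    with pytest.raises(ValidationError):
        tc.binarize_reperfusion("2d")


def test_scale_predictor():
    assert tc.scale_predictor("volume_mm3", 250.0) == 2.5
    assert tc.scale_predictor("tai_q2_hu", 15.0) == 1.5
    for name in ("volume_mm3", "ncct_sd_hu", "cta_median_hu"):
        assert tc.scale_predictor(name, 0.0) == 0.0
    with pytest.raises(ValidationError):
        tc.scale_predictor("nope", 1.0)


# ---------------------------------------------------------------------------
# univariable fits


def test_binary_label_flip_gives_reciprocal_or(registry_cohort):
    res = tc.fit_univariable_binary(registry_cohort, "ncct_sd_hu", "fps")
    flipped = registry_cohort.copy()
    flipped.df["fps"] = 1 - flipped.df["fps"]
    res_f = tc.fit_univariable_binary(flipped, "ncct_sd_hu", "fps")
    assert res_f.or_ == pytest.approx(1.0 / res.or_, rel=1e-6)


def test_constant_predictor_rejected(registry_cohort):
    frozen = registry_cohort.copy()
    frozen.df["tai_q1_hu"] = 5.0
    with pytest.raises(ValidationError):
        tc.fit_univariable_ordinal(frozen, "tai_q1_hu")


def test_direction_contract(registry_cohort):
    """A characteristic that improves outcome in simulation yields OR > 1
    after mRS inversion (the injected tai_q2 OR is 1.10 > 1)."""
    res = tc.fit_univariable_ordinal(registry_cohort, "tai_q2_hu")
    assert res.or_ > 1.0
    assert res.ci_low <= res.or_ <= res.ci_high


# ---------------------------------------------------------------------------
# adjusted fits


def test_empty_confounders_reduces_to_univariable(registry_cohort):
    uni = tc.fit_univariable_binary(registry_cohort, "ncct_sd_hu", "fps")
    adj = tc.fit_adjusted(registry_cohort, "ncct_sd_hu", "fps", confounders=[])
    assert adj.or_ == pytest.approx(uni.or_, rel=1e-8)
    assert adj.adjusted is False


def test_independent_confounders_leave_or_unchanged():
    cfg = tc.registry_like_config(
        n=8000, seed=17,
        odds_ratios={"mrs": {}, "fps": {"ncct_sd_hu": 0.7}, "etici": {}},
    )
    cohort = tc.simulate_cohort(cfg)
    uni = tc.fit_univariable_binary(cohort, "ncct_sd_hu", "fps")
    adj = tc.fit_adjusted(cohort, "ncct_sd_hu", "fps")
    assert adj.log_or == pytest.approx(uni.log_or, abs=0.05)


def test_adjustment_removes_injected_confounding():
    """Age drives both tai_q2 and FPS; there is no direct tai_q2 effect.
    The adjusted OR recovers the null, the unadjusted one does not."""
    cfg = tc.registry_like_config(
        n=8000, seed=23,
        odds_ratios={"mrs": {}, "fps": {}, "etici": {}},
        covariate_outcome_logor={"fps": {"age": 0.05}},
        covariate_char_slopes={"tai_q2_hu": {"age": 0.6}},
    )
    cohort = tc.simulate_cohort(cfg)
    uni = tc.fit_univariable_binary(cohort, "tai_q2_hu", "fps")
    adj = tc.fit_adjusted(cohort, "tai_q2_hu", "fps", confounders=["age"])
    assert not (uni.ci_low <= 1.0 <= uni.ci_high)  # confounded
    assert adj.ci_low <= 1.0 <= adj.ci_high        # deconfounded


def test_collinear_design_names_aliased_column(registry_cohort):
    cohort = registry_cohort.copy()
    cohort.df["nihss_baseline"] = (2 * cohort.df["age"]).astype(float).round(0).astype("Int64").clip(0, 42)
    # make an exact copy to force rank deficiency: diabetes := ivt
    cohort.df["diabetes"] = cohort.df["ivt"]
    with pytest.raises(tc.FittingError, match="aliased"):
        tc.fit_adjusted(cohort, "tai_q2_hu", "fps", confounders=["ivt", "diabetes"])


# ---------------------------------------------------------------------------
# imputation and pooling


def test_impute_no_missing_is_identity(registry_cohort):
    completed = tc.impute_cohort(registry_cohort, m=3, seed=1)
    assert len(completed) == 3
    for c in completed:
        assert c.df.equals(registry_cohort.df)


def test_pmm_donor_property_and_observed_cells_fixed(registry_cohort):
    cohort = tc.inject_missingness(
        registry_cohort, {"mrs_90d": 0.15, "fps": 0.25, "etici": 0.05}, seed=9
    )
    completed = tc.impute_cohort(cohort, m=2, seed=10)
    for comp in completed:
        assert not comp.df[["mrs_90d", "fps", "etici"]].isna().any().any()
        for col in ("mrs_90d", "fps", "etici"):
            observed = set(cohort.df[col].dropna())
            imputed_cells = comp.df.loc[cohort.df[col].isna(), col]
            assert set(imputed_cells).issubset(observed)  # PMM donor property
            # observed cells are untouched and identical across imputations
            obs_idx = cohort.df[col].notna()
            assert comp.df.loc[obs_idx, col].equals(cohort.df.loc[obs_idx, col])


def test_impute_fully_missing_column_rejected(registry_cohort):
    cohort = registry_cohort.copy()
    cohort.df["fps"] = pd.NA
    cohort.df["fps"] = cohort.df["fps"].astype("Int64")
    with pytest.raises(ValidationError):
        tc.impute_cohort(cohort, m=2, seed=0)


def test_mcar_imputed_mean_consistent():
    cfg = tc.registry_like_config(n=5000, seed=33)
    cohort = tc.inject_missingness(tc.simulate_cohort(cfg), {"mrs_90d": 0.2}, seed=34)
    comp = tc.impute_cohort(cohort, m=1, seed=35)[0]
    observed = cohort.df["mrs_90d"].dropna().astype(float)
    imputed = comp.df.loc[cohort.df["mrs_90d"].isna(), "mrs_90d"].astype(float)
    se = observed.std() / np.sqrt(len(imputed))
    assert abs(imputed.mean() - observed.mean()) < 3 * se


def test_rubin_toy_example():
    def toy(log_or, se):
        return tc.AssociationResult(
            predictor="tai_q2_hu", scaling="per 10 HU", outcome="fps",
            model="binary", adjusted=False, or_=float(np.exp(log_or)),
            ci_low=float(np.exp(log_or - 1.96 * se)),
            ci_high=float(np.exp(log_or + 1.96 * se)),
            p_value=0.5, n_used=100, log_or=log_or, se=se, df_resid=98,
        )

    pooled = tc.pool_rubin([toy(0.1, 0.05), toy(0.2, 0.05), toy(0.3, 0.05)])
    assert pooled.log_or == pytest.approx(0.2)
    assert pooled.se**2 == pytest.approx(0.0025 + (4 / 3) * 0.01)
    assert pooled.pooled

    # m identical fits: between-variance 0, pooled equals each input
    same = [toy(0.15, 0.07) for _ in range(4)]
    p = tc.pool_rubin(same)
    assert p.log_or == pytest.approx(0.15)
    assert p.se == pytest.approx(0.07)
    assert p.ci_low == pytest.approx(same[0].ci_low, rel=1e-3)

    # m = 1 is the identity
    single = tc.pool_rubin([toy(0.1, 0.05)])
    assert single.or_ == pytest.approx(toy(0.1, 0.05).or_)

    with pytest.raises(ValidationError):
        tc.pool_rubin([toy(0.1, 0.05),
                       tc.AssociationResult(
                           predictor="volume_mm3", scaling="per 0.1 mL",
                           outcome="fps", model="binary", adjusted=False,
                           or_=1.0, ci_low=0.9, ci_high=1.1, p_value=0.5,
                           n_used=10, log_or=0.0, se=0.05, df_resid=8)])


# ---------------------------------------------------------------------------
# population comparison and summaries


def test_compare_cohort_to_itself_nothing_significant(registry_cohort):
    table = tc.compare_populations(registry_cohort, registry_cohort)
    assert len(table) > 0
    assert not table["significant"].any()


def test_compare_detects_shifted_tai():
    from thrombochar.synthetic import REGISTRY_CHAR_MEANS

    a = tc.simulate_cohort(tc.registry_like_config(n=1000, seed=41))

    shifted = dict(REGISTRY_CHAR_MEANS)
    shifted["tai_q2_hu"] += 10.0
    b = tc.simulate_cohort(tc.registry_like_config(n=1000, seed=43, char_means=shifted))
    table = tc.compare_populations(a, b).set_index("variable")
    assert table.loc["tai_q2_hu", "significant"]


def test_compare_balanced_2x2_statistic_zero():
    df_a = pd.DataFrame({"fps": [1] * 50 + [0] * 50})
    df_b = pd.DataFrame({"fps": [1] * 50 + [0] * 50})
    a, b = tc.Cohort(df_a), tc.Cohort(df_b)
    row = tc.compare_populations(a, b, variables=["fps"]).iloc[0]
    assert row["statistic"] == 0.0
    assert row["p_value"] == 1.0


def test_compare_matches_r_reference_to_1e6():
    """p-values agree with R's wilcox.test (exact=FALSE, correct=TRUE) and
    chisq.test on fixed fixtures, values frozen from an independent run."""
    from scipy import stats

    x = [1, 2, 2, 3, 4, 5, 5, 6, 8, 10]
    y = [2, 3, 3, 4, 5, 6, 7, 7, 9, 12]
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 use_continuity=True, method="asymptotic")
    assert stat == 38.0 and p == pytest.approx(0.381975415360, abs=1e-6)

    x2, y2 = np.arange(1, 31.0), np.arange(5, 41.0)
    stat, p = stats.mannwhitneyu(x2, y2, alternative="two-sided",
                                 use_continuity=True, method="asymptotic")
    assert stat == 338.0 and p == pytest.approx(0.009443164359, abs=1e-6)

    stat, p, _, _ = stats.chi2_contingency([[12, 5], [9, 14]], correction=True)
    assert p == pytest.approx(0.099091839349, abs=1e-6)
    stat, p, _, _ = stats.chi2_contingency([[10, 20, 30], [15, 18, 12]],
                                           correction=False)
    assert p == pytest.approx(0.033110834071, abs=1e-6)


def test_summarize_groupings():
    df = pd.DataFrame({
        "aspects": pd.array([3, 6, 9, 10], dtype="Int64"),
        "prestroke_mrs": pd.array([0, 1, 2, 5], dtype="Int64"),
        "age": np.arange(1.0, 101.0)[:4],
    })
    summary = tc.summarize_cohort(tc.Cohort(df), variables=["aspects", "prestroke_mrs"])
    aspects = summary[summary["variable"] == "aspects"].set_index("level")["count"]
    assert list(aspects[["0-4", "5-7", "8-10"]]) == [1, 1, 2]
    pre = summary[summary["variable"] == "prestroke_mrs"].set_index("level")["count"]
    assert list(pre[["0", "1", ">=2"]]) == [1, 1, 2]


def test_summarize_numeric_median_iqr():
    df = pd.DataFrame({"age": np.arange(1.0, 101.0)})
    row = tc.summarize_cohort(tc.Cohort(df), variables=["age"]).iloc[0]
    assert row["median"] == 50.5
    assert row["q1"] == pytest.approx(25.75)
    assert row["q3"] == pytest.approx(75.25)
    assert row["n_available"] == 100


# ---------------------------------------------------------------------------
# complete case


def test_complete_case_counts(registry_cohort):
    cohort = tc.inject_missingness(registry_cohort, {"fps": 0.3}, seed=2)
    n_missing = int(cohort.df["fps"].isna().sum())
    cc = tc.complete_case(cohort, ["fps"])
    assert len(cc) == len(cohort) - n_missing
    full = tc.complete_case(registry_cohort, ["fps", "mrs_90d"])
    assert len(full) == len(registry_cohort)


def test_complete_case_empty_result_rejected(registry_cohort):
    cohort = registry_cohort.copy()
    cohort.df["fps"] = pd.array([pd.NA] * len(cohort.df), dtype="Int64")
    with pytest.raises(ValidationError):
        tc.complete_case(cohort, ["fps"])
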