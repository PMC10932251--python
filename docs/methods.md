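# Methods

## Problem and scope

In acute ischemic stroke caused by a large-vessel occlusion, the occluding
thrombus is visible on the baseline CT work-up: as a hyperdense structure on
non-contrast CT (NCCT) and as a filling defect on CT angiography (CTA).
First-order characteristics of the segmented thrombus — its volume, its
density, how much contrast penetrates it (perviousness), and how
heterogeneous its attenuation is — have been linked to functional outcome
and to the technical success of endovascular thrombectomy (EVT).

`thrombochar` implements the full chain from a co-registered NCCT/CTA pair
with a binary thrombus mask to a grid of odds ratios relating nine
entire-thrombus characteristics to three treatment outcomes, together with
a synthetic-data layer (phantoms and cohorts with known generating
parameters) that makes every stage testable without patient data.

## Thrombus characteristics

All characteristics are computed from the HU values of the foreground
voxels, traversed in lexicographic index order (bit-for-bit reproducible).

* **Volume** (mm³): foreground voxel count × dx·dy·dz, exactly.
* **Density**: median NCCT attenuation of the thrombus voxels (HU).
* **Perviousness** as thrombus attenuation increase (TAI) from NCCT to CTA:
  * `TAI_Qk` (k = 1, 2, 3): quantile_k/4(CTA) − quantile_k/4(NCCT), with
    linear-interpolation quantiles on the **raw** masked values. Raw
    quantiles are the fine-binning limit of histogram quartiles and avoid
    bin-width artefacts; no bin width needs to be chosen.
  * `TAI_MCC`: both modalities are binned into **1 HU** bins (CT's native
    quantization) on one shared edge grid running from floor(min) to
    ceil(max) of the pooled values; the reported value is the lag (in bins,
    converted to HU) that maximizes the raw, unnormalized cross-correlation
    `sum_i ncct[i]·cta[i+lag]` with zero-padding outside the support, over
    lags in ±100 HU. Ties are broken toward the smallest absolute lag, then
    toward the positive lag. Counts are kept as 64-bit integers so the
    argmax and tie detection are exact.
* **CTA median**: median CTA attenuation — contrast penetration
  irrespective of the thrombus's own density.
* **Heterogeneity**: population standard deviation (divide by n) of the
  masked values in each modality. With thousands of voxels the n vs n−1
  distinction is negligible; the population form is fixed and documented.

Shift behaviour, and a deliberate caveat: the quartile TAIs are exactly
invariant to a joint NCCT+CTA shift and exactly equivariant to a CTA-only
shift. `TAI_MCC` has these properties **for whole-HU shifts**, where the
1-HU-binned histograms translate exactly. Under fractional shifts the
histograms are rebinned rather than translated, and when the
cross-correlation peak is flat (mixed perviousness, noisy uplift) the
argmax can move by more than one bin. Since clinical CT stores integer HU,
the property tests use integer shifts.

## Scan-quality filter

A scan pair is excluded if any of: CTA slice thickness > 2 mm, NCCT slice
thickness > 5 mm, fewer than 8 slices, incomplete brain coverage, a sharp
reconstruction kernel, or motion artefacts. All thresholds are strict
inequalities (2.0 mm CTA and exactly 8 slices pass). Kernel and motion
flags are metadata inputs, not computed from the images. The filter is
monotone: worsening any single field never readmits an excluded scan.

## Outcome codings and association models

* 90-day modified Rankin Scale (mRS, 0–6) is **inverted** (6 − mRS) so
  higher = better; odds ratios below one then indicate a worse functional
  outcome.
* Successful reperfusion is eTICI ≥ 2b (grades 2b, 2c, 3); first-pass
  success (FPS) is that result after a single device pass.
* The inverted mRS is modelled with a proportional-odds cumulative-logit
  regression over all seven levels; FPS and eTICI ≥ 2b with binary logistic
  regression. Proportionality is assumed, not tested (a single OR per
  characteristic is reported).
* Predictors are scaled before fitting — volume per 0.1 mL (÷100 mm³),
  every HU characteristic per 10 HU — so exp(coefficient) is the reported
  per-unit OR.
* Inference is Wald (estimate, 95% CI, p) throughout; Wald keeps pooled
  inference under Rubin's rules tractable. The ordinal likelihood is
  maximized with BFGS (gradient tolerance 1e-8, max 500 iterations); a
  solution whose score norm is below 1e-3 is accepted even when the line
  search reports precision loss, and parameter magnitudes above 30 on the
  log-odds scale are treated as separation and rejected.
* Adjusted models add a confounder set to the design (default: the
  imputation informers below; occlusion location enters as dummy columns
  with the first level as reference). A rank-deficient design raises an
  error naming the aliased columns.
* No multiple-testing correction is applied anywhere; significance flags
  are nominal p < 0.05.

## Missing data

Multiple imputation by chained equations, m = 5 by default:

* columns are visited in order of increasing missingness, 10 burn-in
  sweeps;
* on each visit an additive (linear) regression of the column on the
  informers plus the other incomplete variables is fitted to a bootstrap
  resample of the observed rows (propagating parameter uncertainty);
* each missing cell receives the observed value of one of k = 5 donors
  with the closest predicted means (predictive mean matching), so every
  imputed value is an observed value of its column;
* eTICI is imputed as an ordered grade code and binarized only at analysis
  time; imputing the binarized flag directly would discard grade
  information.

The default informer list is: age, occlusion location, baseline NIHSS,
IVT, diabetes, onset-to-puncture time, antiplatelet use, atrial
fibrillation, atherosclerosis, and collateral score. When an imputed
cohort is used to estimate a characteristic–outcome association, the
analysis predictor should be added to the informers (congeniality);
otherwise the imputed outcome cells are independent of the predictor and
attenuate the pooled OR. The calibration tests and the acceptance script
do exactly that.

Pooling follows Rubin's rules on the log-OR scale: pooled point = mean,
total variance = within + (1 + 1/m)·between, reference distribution t with
Barnard–Rubin degrees of freedom. With zero between-imputation variance or
m = 1 the pooled result equals the single-fit Wald inference exactly.
A complete-case path (`complete_case`) is kept as the sensitivity analysis.

## Population comparison and summaries

Numerical variables: Mann–Whitney U, normal approximation with tie and
continuity correction. Categorical variables: chi-square on the
contingency table, Yates correction for 2×2 tables only. Both choices are
pinned against reference p-values computed independently in R
(`wilcox.test(exact=FALSE, correct=TRUE)`, `chisq.test`) to 1e-6.
Summaries report median (IQR) for numerical variables and n (%) for
categorical ones, with pre-stroke mRS grouped as {0, 1, ≥2} and ASPECTS as
{0–4, 5–7, 8–10}; available n is reported per variable.

## Synthetic data

**Phantoms.** An ellipsoidal thrombus (default semi-axes 6×4×4 mm on a
0.5 mm isotropic 64³ grid) in a uniform brain-like background
(35 ± 2 HU). NCCT thrombus voxels are Normal(50, 9) HU, matching observed
thrombus density/heterogeneity ranges. The CTA counterpart adds an uplift
δ (default 25 HU, with 5 HU noise) to a random fraction p (default 0.3) of
thrombus voxels. The mixture — rather than a uniform shift — produces the
distinct Q1/Q2/Q3 TAI behaviour that quartile metrics are designed to
resolve; a rigid shift is the degenerate p = 1 case. Ground truth is
computed from the generated voxel values by definition, with `TAI_MCC`
ground truth from an independent full-cross-correlation route
(`numpy.correlate`). Not modelled: vessel anatomy, beam hardening,
partial-volume effects, scanner noise spectra — so passing tests show the
estimators recover the generating model, not that they are robust to real
scanner physics.

**Cohorts.** Characteristics are drawn from a Gaussian copula (default:
independent margins; volume lognormal, everything else normal) with
marginal medians/spreads taken from published EVT registry and trial
distributions. One printed registry interquartile range for the CTA SD is
internally inconsistent (IQR not containing its median); the registry
config uses an 8 HU spread in line with the companion trial column.
Outcomes follow the exact models the estimators assume: inverted mRS from
a proportional-odds model whose cutpoints are anchored so the marginal
seven-level distribution at the mean linear predictor matches the
configured level probabilities; FPS and eTICI ≥ 2b from logistic models
anchored at configured marginal rates (registry defaults 34% and 65.8%);
the binary reperfusion success is expanded to a full eTICI grade with
fixed conditional probabilities. Injected odds ratios are per scaled unit,
so a fitted univariable model is correctly specified when a single
characteristic drives a given outcome. Confounding can be injected via
covariate→outcome log-OR terms and covariate→characteristic slopes (both
centred). Covariates (age, sex, NIHSS, times, comorbidities, ASPECTS,
collaterals, occlusion site) mirror published marginals; atrial
fibrillation prevalence is not published for these populations and is set
to a typical 25%.

**Missingness.** `inject_missingness` blanks outcome cells MCAR, or MAR
with the missingness odds depending on an observed informer (above-median
rows have a configurable odds multiple, overall rate preserved by solving
the two group probabilities). Registry-like defaults: 9% mRS, 25% FPS, 4%
eTICI; trial-like: 0%, 12%, 9%.

## Calibration and problem sizes

The test suite verifies, among others: exact agreement of `tai_mcc` with a
brute-force lag scan (200 random histogram pairs) and of the quartile TAIs
with a sort-and-interpolate oracle (1e-9); the shift laws on 100 random
phantoms; phantom ground-truth round trips; 95% Wald CI coverage in
[93%, 97%] per model type at n = 2000 (200 simulated cohorts per ordinal
configuration and 400 per binary one — replication counts chosen so the
Monte Carlo SE of the coverage estimate is small against that band);
ordinal/binary equality at two outcome levels to 1e-4 in OR; pooled and
complete-case coverage of an injected OR under MCAR at realistic
missingness (n = 4000, 20 replicates, ≥17/20 each, the binomially
consistent reading of full nominal coverage); and byte-identical reruns of
the two-population pipeline (n = 500 per population, 54 univariable
cells). `scripts/acceptance.py` recomputes the same quantities at reduced
replication (40 seeds per estimator) so a full run takes well under a
minute per block.

## Known limitations

* The proportional-odds assumption is inherited, not tested.
* PMM with linear mean models is crude for nominal variables; occlusion
  location is refused as an imputation target.
* The generator draws characteristics independently by default; real
  thrombus characteristics are correlated (a correlation matrix can be
  configured, but no published covariance structure exists to default to).
* Wald intervals undercover slightly for extreme ORs or small cohorts;
  calibration was verified at n ≥ 2000.
* Images and masks must already be co-registered; no resampling,
  registration or segmentation is provided.
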