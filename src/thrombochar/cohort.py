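"""Patient-level cohort container and its on-disk CSV dictionary.

A cohort is a flat table with one row per patient.  Columns fall into four
groups: identifiers, the nine entire-thrombus imaging characteristics,
clinical covariates, and treatment outcomes.  Missing values are encoded as
empty cells in CSV; no numeric sentinels are used, so a read/write round trip
preserves both values and the missingness pattern exactly.

Column dictionary
-----------------
id                    unique patient identifier (string)
population            cohort label (string)
volume_mm3            thrombus volume in mm^3
ncct_median_hu        median thrombus attenuation on NCCT (density), HU
tai_q1_hu             thrombus attenuation increase at the first quartile, HU
tai_q2_hu             ... at the second quartile (median), HU
tai_q3_hu             ... at the third quartile, HU
tai_mcc_hu            histogram-lag TAI at maximum cross-correlation, HU
cta_median_hu         median thrombus attenuation on CTA, HU
cta_sd_hu             SD of thrombus attenuation on CTA (heterogeneity), HU
ncct_sd_hu            SD of thrombus attenuation on NCCT (heterogeneity), HU
age                   years
sex                   1 = male, 0 = female
nihss_baseline        baseline NIHSS, 0..42
onset_to_puncture_min onset-to-arterial-puncture time, minutes
ivt, antiplatelet, diabetes, atrial_fibrillation, atherosclerosis,
hypertension          binary flags, 1 = yes
prestroke_mrs         pre-stroke modified Rankin Scale, 0..6
aspects               ASPECTS, 0..10
collateral_score      collateral filling grade, 0..3
occlusion_location    one of ICA, ICA-t, M1, M2
mrs_90d               modified Rankin Scale at 90 days, 0..6
fps                   first-pass success, 1 = eTICI 2b-3 after one pass
etici                 final eTICI grade, one of 0, 1, 2a, 2b, 2c, 3
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

CHARACTERISTIC_COLUMNS = [
    "volume_mm3",
    "ncct_median_hu",
    "tai_q1_hu",
    "tai_q2_hu",
    "tai_q3_hu",
    "tai_mcc_hu",
    "cta_median_hu",
    "cta_sd_hu",
    "ncct_sd_hu",
]

ETICI_GRADES = ["0", "1", "2a", "2b", "2c", "3"]
ETICI_SUCCESS = {"2b", "2c", "3"}
OCCLUSION_LOCATIONS = ["ICA", "ICA-t", "M1", "M2"]

# Per-model-unit scaling of each characteristic: volume is analysed per
# 0.1 mL (= 100 mm^3), every HU-valued characteristic per 10 HU.
SCALINGS: dict[str, tuple[float, str]] = {
    "volume_mm3": (100.0, "per 0.1 mL"),
    **{c: (10.0, "per 10 HU") for c in CHARACTERISTIC_COLUMNS if c != "volume_mm3"},
}

FLOAT_COLUMNS = CHARACTERISTIC_COLUMNS + ["age", "onset_to_puncture_min"]
INT_COLUMNS = [
    "sex",
    "nihss_baseline",
    "ivt",
    "antiplatelet",
    "diabetes",
    "atrial_fibrillation",
    "atherosclerosis",
    "hypertension",
    "prestroke_mrs",
    "aspects",
    "collateral_score",
    "mrs_90d",
    "fps",
]
STRING_COLUMNS = ["id", "population", "occlusion_location", "etici"]
ALL_COLUMNS = STRING_COLUMNS[:2] + CHARACTERISTIC_COLUMNS + [
    "age",
    "sex",
    "nihss_baseline",
    "onset_to_puncture_min",
    "ivt",
    "antiplatelet",
    "diabetes",
    "atrial_fibrillation",
    "atherosclerosis",
    "hypertension",
    "prestroke_mrs",
    "aspects",
    "collateral_score",
    "occlusion_location",
    "mrs_90d",
    "fps",
    "etici",
]

BINARY_COLUMNS = {
    "sex",
    "ivt",
    "antiplatelet",
    "diabetes",
    "atrial_fibrillation",
    "atherosclerosis",
    "hypertension",
    "fps",
}

_INT_DOMAINS = {
    "nihss_baseline": (0, 42),
    "prestroke_mrs": (0, 6),
    "aspects": (0, 10),
    "collateral_score": (0, 3),
    "mrs_90d": (0, 6),
}


def _check_domain(name: str, series: pd.Series) -> None:
    vals = series.dropna()
    if len(vals) == 0:
        return
    if name in BINARY_COLUMNS:
        bad = ~vals.isin([0, 1])
        if bad.any():
            raise ValidationError(f"column {name!r}: values outside {{0, 1}}")
    elif name in _INT_DOMAINS:
        lo, hi = _INT_DOMAINS[name]
        if ((vals < lo) | (vals > hi)).any():
            raise ValidationError(f"column {name!r}: values outside {lo}..{hi}")
    elif name == "etici":
        bad = ~vals.isin(ETICI_GRADES)
        if bad.any():
            raise ValidationError(
                f"column 'etici': unknown grades {sorted(set(vals[bad]))}"
            )
    elif name == "occlusion_location":
        bad = ~vals.isin(OCCLUSION_LOCATIONS)
        if bad.any():
            raise ValidationError(
                f"column 'occlusion_location': unknown values {sorted(set(vals[bad]))}"
            )


def validate_cohort_df(df: pd.DataFrame) -> None:
    """Check column names, dtypes and coded domains; raise ValidationError."""
    unknown = [c for c in df.columns if c not in ALL_COLUMNS]
    if unknown:
        raise ValidationError(f"unknown columns: {unknown}")
    if "id" in df.columns and df["id"].notna().any():
        if df["id"].dropna().duplicated().any():
            raise ValidationError("duplicate patient ids")
    for col in df.columns:
        _check_domain(col, df[col])


@dataclass
class Cohort:
    """A patient cohort: a typed DataFrame plus provenance metadata.

    ``ground_truth`` carries the generating parameters when the cohort is
    simulated (injected odds ratios, distribution parameters), so downstream
    tests can compare estimates against the truth.
    """

    df: pd.DataFrame
    provenance: str = "real"
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_cohort_df(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), self.provenance, dict(self.ground_truth))


def read_cohort(path) -> Cohort:
    """Read a cohort CSV.

    Only the empty cell is treated as missing.  Integer-coded columns are
    stored as nullable integers so that a write/read round trip is the
    identity on both values and the missingness pattern.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    unknown = [c for c in raw.columns if c not in ALL_COLUMNS]
    if unknown:
        raise ValidationError(f"unknown columns: {unknown}")
    out = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        if col in STRING_COLUMNS:
            out[col] = raw[col].astype("object").where(raw[col].notna(), other=pd.NA)
        else:
            try:
                # float() round-trips shortest-repr values exactly, unlike
                # pandas' default csv float parser
                num = pd.Series(
                    [float(x) if isinstance(x, str) else np.nan for x in raw[col]],
                    index=raw.index,
                )
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"column {col!r}: non-numeric value ({exc})")
            if col in INT_COLUMNS:
                vals = num.dropna()
                if len(vals) and not np.allclose(vals, np.round(vals)):
                    raise ValidationError(f"column {col!r}: non-integer value")
                out[col] = num.astype("Int64")
            else:
                out[col] = num.astype(float)
    validate_cohort_df(out)
    return Cohort(out)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort table as CSV with empty cells for missing values."""
    cohort.df.to_csv(path, index=False, na_rep="")
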