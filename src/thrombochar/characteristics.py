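"""Entire-thrombus imaging characteristics.

Nine first-order characteristics are computed from an NCCT/CTA pair and a
thrombus mask:

* volume (mm^3): foreground voxel count times the voxel volume;
* density: median thrombus attenuation on NCCT (HU);
* perviousness, quantified as the thrombus attenuation increase (TAI) from
  NCCT to CTA — the differences of the first, second and third quartiles of
  the two intensity distributions (TAI_Q1/Q2/Q3), and the histogram lag that
  maximizes the cross-correlation of the two intensity histograms (TAI_MCC);
* the median CTA attenuation, a density-independent contrast-penetration
  measure;
* heterogeneity: the standard deviation of the thrombus intensities in each
  modality.

Quartile TAIs are computed on the raw masked voxel values with
linear-interpolation quantiles (the fine-binning limit of histogram
quartiles).  TAI_MCC uses 1-HU-wide histogram bins — CT's native
quantization — on a bin grid shared by both modalities, raw (unnormalized)
count products with zero-padding outside the support, and a lag search over
[-max_lag, +max_lag]; ties are broken toward the smallest absolute lag, then
toward the positive lag.  Standard deviations are population SDs (divide by
n).  Voxels are traversed in lexicographic index order so every derived list
and histogram is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .errors import ValidationError
from .imaging_io import VoxelVolumePair

DEFAULT_BIN_WIDTH_HU = 1.0
DEFAULT_MAX_LAG_HU = 100.0


@dataclass(frozen=True)
class IntensityHistogram:
    """Uniformly binned HU histogram of the masked voxels of one modality."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        if len(edges) < 2 or len(counts) != len(edges) - 1:
            raise ValidationError("histogram needs n+1 edges for n bins")
        widths = np.diff(edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0]):
            raise ValidationError("bin edges must be strictly increasing and uniform")
        if np.any(counts < 0):
            raise ValidationError("negative bin count")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", np.asarray(counts, dtype=np.int64))

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ThrombusCharacteristics:
    """The nine derived biomarkers of one thrombus."""

    volume_mm3: float
    ncct_median_hu: float
    tai_q1_hu: float
    tai_q2_hu: float
    tai_q3_hu: float
    tai_mcc_hu: float
    cta_median_hu: float
    cta_sd_hu: float
    ncct_sd_hu: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def mask_values(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extract one HU value per foreground voxel, in lexicographic index order."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValidationError("image and mask shapes differ")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValidationError("mask has no foreground voxels")
    return image[mask]  # boolean indexing is C-order, hence deterministic


def compute_volume(mask: np.ndarray, spacing) -> float:
    """Thrombus volume in mm^3: foreground count times dx*dy*dz, exactly."""
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValidationError("spacing must be positive")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValidationError("mask has no foreground voxels")
    return float(int(mask.sum()) * spacing[0] * spacing[1] * spacing[2])


def tai_quartile(ncct_values, cta_values, q: int) -> float:
    """TAI at quartile ``q``: quantile_q(CTA) - quantile_q(NCCT).

    Quantiles use linear interpolation on the raw masked values.
    """
    if q not in (1, 2, 3):
        raise ValidationError(f"q must be 1, 2 or 3, got {q}")
    ncct = np.asarray(ncct_values, dtype=float)
    cta = np.asarray(cta_values, dtype=float)
    if ncct.size == 0 or cta.size == 0:
        raise ValidationError("empty value list")
    p = q / 4.0
    return float(np.quantile(cta, p) - np.quantile(ncct, p))


def build_histograms(
    ncct_values, cta_values, bin_width: float = DEFAULT_BIN_WIDTH_HU
) -> tuple[IntensityHistogram, IntensityHistogram]:
    """Bin both modalities on one shared uniform grid.

    Edges run from floor(min) to ceil(max) of the pooled values in steps of
    ``bin_width``, so a rigid shift of one modality by a multiple of the bin
    width translates its histogram exactly.
    """
    if bin_width <= 0:
        raise ValidationError("bin width must be positive")
    ncct = np.asarray(ncct_values, dtype=float)
    cta = np.asarray(cta_values, dtype=float)
    if ncct.size == 0 or cta.size == 0:
        raise ValidationError("empty value list")
    lo = bin_width * math.floor(min(ncct.min(), cta.min()) / bin_width)
    hi = bin_width * math.ceil(max(ncct.max(), cta.max()) / bin_width)
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts_n, _ = np.histogram(ncct, bins=edges)
    counts_c, _ = np.histogram(cta, bins=edges)
    return IntensityHistogram(edges, counts_n), IntensityHistogram(edges, counts_c)


def tai_mcc(
    hist_ncct: IntensityHistogram,
    hist_cta: IntensityHistogram,
    max_lag_bins: int = 100,
) -> float:
    """TAI as the histogram lag maximizing the raw cross-correlation.

    The lag is the shift (in bins) applied to the NCCT histogram that
    maximizes sum_i ncct[i] * cta[i + lag] over lags in
    [-max_lag_bins, +max_lag_bins], with zero-padding outside the support.
    Ties go to the smallest absolute lag, then to the positive lag.  The
    returned value is the lag converted to HU (lag * bin_width).
    """
    if max_lag_bins < 0:
        raise ValidationError("max_lag_bins must be >= 0")
    if hist_ncct.n == 0 or hist_cta.n == 0:
        raise ValidationError("empty histogram")
    if len(hist_ncct.bin_edges) != len(hist_cta.bin_edges) or not np.allclose(
        hist_ncct.bin_edges, hist_cta.bin_edges
    ):
        raise ValidationError("histograms must share one bin grid")
    a = hist_ncct.counts  # int64: exact products, exact tie detection
    b = hist_cta.counts
    n = len(a)

    def corr(lag: int) -> int:
        if lag >= 0:
            return int(a[: n - lag] @ b[lag:]) if lag < n else 0
        return int(a[-lag:] @ b[: n + lag]) if -lag < n else 0

    # Visit lags in tie-break priority order: 0, +1, -1, +2, -2, ...
    best_lag, best_val = 0, corr(0)
    for mag in range(1, max_lag_bins + 1):
        for lag in (mag, -mag):
            v = corr(lag)
            if v > best_val:
                best_lag, best_val = lag, v
    return float(best_lag * hist_ncct.bin_width)


def compute_characteristics(
    pair: VoxelVolumePair,
    bin_width: float = DEFAULT_BIN_WIDTH_HU,
    max_lag_hu: float = DEFAULT_MAX_LAG_HU,
) -> ThrombusCharacteristics:
    """Compute all nine characteristics from a co-registered pair."""
    ncct = mask_values(pair.ncct, pair.mask)
    cta = mask_values(pair.cta, pair.mask)
    hist_n, hist_c = build_histograms(ncct, cta, bin_width)
    max_lag_bins = int(round(max_lag_hu / bin_width))
    return ThrombusCharacteristics(
        volume_mm3=compute_volume(pair.mask, pair.spacing),
        ncct_median_hu=float(np.median(ncct)),
        tai_q1_hu=tai_quartile(ncct, cta, 1),
        tai_q2_hu=tai_quartile(ncct, cta, 2),
        tai_q3_hu=tai_quartile(ncct, cta, 3),
        tai_mcc_hu=tai_mcc(hist_n, hist_c, max_lag_bins),
        cta_median_hu=float(np.median(cta)),
        cta_sd_hu=float(np.std(cta)),
        ncct_sd_hu=float(np.std(ncct)),
    )
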