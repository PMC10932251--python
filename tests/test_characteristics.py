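import math

import numpy as np
import pytest

import thrombochar as tc
from thrombochar.characteristics import build_histograms
from thrombochar.errors import ValidationError


def quantile_oracle(values, p):
    """Independent sort-and-interpolate quantile (linear interpolation)."""
    s = sorted(float(v) for v in values)
    h = (len(s) - 1) * p
    lo, hi = math.floor(h), math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def mcc_oracle(counts_n, counts_c, bin_width, max_lag):
    """Exhaustive lag scan with explicit tie-breaking (smallest |lag|, then +)."""
    n = len(counts_n)
    scored = []
    for lag in range(-max_lag, max_lag + 1):
        tot = sum(
            int(counts_n[i]) * int(counts_c[i + lag])
            for i in range(n)
            if 0 <= i + lag < n
        )
        scored.append((tot, lag))
    best = max(t for t, _ in scored)
    winners = [lag for t, lag in scored if t == best]
    winners.sort(key=lambda l: (abs(l), -l))
    return winners[0] * bin_width


# ---------------------------------------------------------------------------
# mask_values / compute_volume


def test_mask_values_basic():
    img = np.arange(27, dtype=float).reshape(3, 3, 3)
    mask = np.zeros((3, 3, 3), dtype=int)
    mask[0, 0, 0] = mask[1, 1, 1] = mask[2, 2, 2] = 1
    vals = tc.mask_values(img, mask)
    assert len(vals) == 3
    np.testing.assert_array_equal(vals, [0.0, 13.0, 26.0])  # lexicographic order


def test_mask_values_empty_mask_errors():
    with pytest.raises(ValidationError):
        tc.mask_values(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))


def test_checkerboard_mask_on_constant_image():
    img = np.full((4, 4, 4), 42.0)
    idx = np.indices((4, 4, 4)).sum(axis=0)
    mask = (idx % 2).astype(int)
    assert np.all(tc.mask_values(img, mask) == 42.0)


def test_compute_volume_arithmetic():
    mask = np.zeros((10, 10, 10), dtype=int)
    mask.flat[:1000] = 1
    assert tc.compute_volume(mask, (0.5, 0.5, 0.5)) == 125.0
    one = np.zeros((2, 2, 2), dtype=int)
    one[0, 0, 0] = 1
    assert tc.compute_volume(one, (1, 1, 1)) == 1.0


def test_compute_volume_random_mask_oracle(rng):
    mask = (rng.random((8, 9, 10)) < 0.3).astype(int)
    if not mask.any():
        mask[0, 0, 0] = 1
    count = sum(int(v) for v in mask.ravel())  # brute-force count
    assert tc.compute_volume(mask, (0.4, 0.6, 1.1)) == pytest.approx(
        count * 0.4 * 0.6 * 1.1
    )


def test_compute_volume_scales_with_spacing(rng):
    mask = (rng.random((6, 6, 6)) < 0.5).astype(int)
    mask[0, 0, 0] = 1
    v1 = tc.compute_volume(mask, (0.5, 0.5, 0.5))
    v2 = tc.compute_volume(mask, (1.0, 0.5, 0.5))
    assert v2 == 2 * v1


def test_compute_volume_rejects_bad_spacing():
    mask = np.ones((2, 2, 2), dtype=int)
    with pytest.raises(ValidationError):
        tc.compute_volume(mask, (0.5, -1.0, 0.5))


# ---------------------------------------------------------------------------
# quartile TAIs


def test_tai_quartile_identity_and_shift(rng):
    vals = rng.normal(50, 10, 500)
    for q in (1, 2, 3):
        assert tc.tai_quartile(vals, vals, q) == 0.0
        assert tc.tai_quartile(vals, vals + 10.0, q) == pytest.approx(10.0, abs=1e-9)


def test_tai_quartile_matches_quantile_oracle(rng):
    for _ in range(50):
        a = rng.normal(48, 9, rng.integers(5, 200))
        b = rng.normal(60, 14, rng.integers(5, 200))
        for q in (1, 2, 3):
            expect = quantile_oracle(b, q / 4) - quantile_oracle(a, q / 4)
            assert tc.tai_quartile(a, b, q) == pytest.approx(expect, abs=1e-9)


def test_tai_quartile_rejects_empty_and_bad_q():
    with pytest.raises(ValidationError):
        tc.tai_quartile([], [1.0], 2)
    with pytest.raises(ValidationError):
        tc.tai_quartile([1.0], [1.0], 4)


# ---------------------------------------------------------------------------
# TAI_MCC


def test_tai_mcc_identical_histograms_is_zero(rng):
    vals = rng.normal(50, 8, 2000)
    h_n, h_c = build_histograms(vals, vals)
    assert tc.tai_mcc(h_n, h_c) == 0.0


def test_tai_mcc_exact_shift(rng):
    vals = rng.normal(50, 8, 5000)
    h_n, h_c = build_histograms(vals, vals + 12.0)
    assert tc.tai_mcc(h_n, h_c) == 12.0


def test_tai_mcc_matches_bruteforce_oracle(rng):
    from thrombochar.characteristics import IntensityHistogram

    for _ in range(60):
        n_bins = int(rng.integers(5, 120))
        edges = np.arange(n_bins + 1, dtype=float)
        counts_n = rng.poisson(3.0, n_bins)
        counts_c = rng.poisson(3.0, n_bins)
        counts_n[int(rng.integers(0, n_bins))] += 5  # ensure non-empty
        counts_c[int(rng.integers(0, n_bins))] += 5
        max_lag = int(rng.integers(1, 40))
        got = tc.tai_mcc(
            IntensityHistogram(edges, counts_n),
            IntensityHistogram(edges, counts_c),
            max_lag,
        )
        assert got == mcc_oracle(counts_n, counts_c, 1.0, max_lag)


def test_tai_mcc_requires_common_grid(rng):
    from thrombochar.characteristics import IntensityHistogram

    h1 = IntensityHistogram(np.arange(11.0), np.ones(10, dtype=int))
    h2 = IntensityHistogram(np.arange(5.0, 16.0), np.ones(10, dtype=int))
    with pytest.raises(ValidationError):
        tc.tai_mcc(h1, h2)


# ---------------------------------------------------------------------------
# full characteristic extraction


def test_identity_pair_all_tais_zero(small_pair):
    pair, _ = small_pair
    same = tc.VoxelVolumePair(pair.ncct, pair.ncct, pair.mask, pair.spacing)
    ch = tc.compute_characteristics(same)
    assert ch.tai_q1_hu == ch.tai_q2_hu == ch.tai_q3_hu == ch.tai_mcc_hu == 0.0
    assert ch.cta_median_hu == ch.ncct_median_hu
    assert ch.cta_sd_hu == ch.ncct_sd_hu


def test_joint_shift_invariance(small_pair):
    pair, _ = small_pair
    base = tc.compute_characteristics(pair)
    shifted = tc.VoxelVolumePair(pair.ncct + 50.0, pair.cta + 50.0, pair.mask, pair.spacing)
    ch = tc.compute_characteristics(shifted)
    for f in ("tai_q1_hu", "tai_q2_hu", "tai_q3_hu"):
        assert getattr(ch, f) == pytest.approx(getattr(base, f), abs=1e-9)
    assert abs(ch.tai_mcc_hu - base.tai_mcc_hu) <= 1.0
    assert ch.ncct_median_hu == pytest.approx(base.ncct_median_hu + 50.0, abs=1e-9)
    assert ch.cta_median_hu == pytest.approx(base.cta_median_hu + 50.0, abs=1e-9)
    assert ch.ncct_sd_hu == pytest.approx(base.ncct_sd_hu, abs=1e-9)
    assert ch.cta_sd_hu == pytest.approx(base.cta_sd_hu, abs=1e-9)


def test_rigid_shift_phantom_recovery():
    cfg = tc.ImagingSimConfig(
        shape=(24, 24, 24), spacing=(0.5, 0.5, 0.5), semi_axes_mm=(4, 3, 3),
        pervious_fraction=1.0, uplift_hu=10.0, uplift_noise_sd=0.0, seed=3,
    )
    pair, _ = tc.simulate_thrombus_pair(cfg)
    ch = tc.compute_characteristics(pair)
    for f in ("tai_q1_hu", "tai_q2_hu", "tai_q3_hu"):
        assert getattr(ch, f) == pytest.approx(10.0, abs=1e-9)
    assert abs(ch.tai_mcc_hu - 10.0) <= 1.0
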