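"""SBR image generation, threshold ROIs, summed SBR and the ratio."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sertquant import (
    CountVolume,
    SummedSBRResult,
    build_label_volume,
    derive_threshold,
    midbrain_pons_ratio,
    sbr_image,
    simulate_counts,
    split_by_plane,
    summed_sbr,
    threshold_roi,
)
from sertquant.sbr import ReferenceError

VOX = (2.0, 2.0, 2.0)


def _random_case(rng, shape=(6, 6, 6)):
    counts = CountVolume(rng.uniform(1.0, 100.0, size=shape), VOX)
    occ = rng.random(shape) < 0.3
    if not occ.any():
        occ[0, 0, 0] = True
    return counts, occ


# ---------------------------------------------------------------- sbr_image

def test_sbr_uniform_at_reference_level_is_zero(rng):
    counts = CountVolume(np.full((5, 5, 5), 42.0), VOX)
    occ = np.zeros((5, 5, 5), dtype=bool)
    occ[:2] = True
    sbr = sbr_image(counts, occ)
    assert np.allclose(sbr.values, 0.0)
    assert sbr.reference_mean == 42.0


def test_sbr_double_reference_gives_one(rng):
    counts = CountVolume(np.full((4, 4, 4), 10.0), VOX)
    counts.values[2, 2, 2] = 20.0
    occ = np.zeros((4, 4, 4), dtype=bool)
    occ[0] = True
    sbr = sbr_image(counts, occ)
    assert sbr.values[2, 2, 2] == pytest.approx(1.0)


def test_sbr_matches_elementwise_loop_oracle(rng):
    counts, occ = _random_case(rng)
    sbr = sbr_image(counts, occ)
    ref = counts.values[occ].mean()
    for i in range(6):
        for j in range(6):
            for k in range(6):
                expected = (counts.values[i, j, k] - ref) / ref
                assert sbr.values[i, j, k] == pytest.approx(expected, rel=1e-12)


def test_sbr_preserves_negative_values(rng):
    counts, occ = _random_case(rng)
    counts.values[occ] = 50.0
    counts.values[0, 0, 0] = 1.0
    sbr = sbr_image(counts, occ | (np.zeros_like(occ)))
    assert (sbr.values < 0).any()


def test_sbr_reference_errors():
    counts = CountVolume(np.zeros((3, 3, 3)), VOX)
    with pytest.raises(ReferenceError):
        sbr_image(counts, np.zeros((3, 3, 3), dtype=bool))
    with pytest.raises(ReferenceError):
        sbr_image(counts, np.ones((3, 3, 3), dtype=bool))


def test_reference_centering(rng):
    """Mean SBR over the reference mask is zero by construction."""
    counts, occ = _random_case(rng, shape=(8, 8, 8))
    sbr = sbr_image(counts, occ)
    assert sbr.values[occ].mean() == pytest.approx(0.0, abs=1e-12)


def test_scale_equivariance(rng):
    """Multiplying all counts by c > 0 leaves the SBR volume unchanged."""
    counts, occ = _random_case(rng)
    sbr1 = sbr_image(counts, occ)
    scaled = CountVolume(counts.values * 7.3, VOX)
    sbr2 = sbr_image(scaled, occ)
    assert np.allclose(sbr1.values, sbr2.values, rtol=1e-12, atol=1e-12)


# ---------------------------------------------------------- derive_threshold

@pytest.mark.parametrize(
    "maxima, fraction, expected",
    [
        ([1.71], 0.05, 0.08),   # calibration mean printed in the source study
        ([2.00], 0.05, 0.10),
        ([1.6, 1.8], 0.05, 0.08),  # floor_2dp(0.085)
        ([1.0, 2.0, 3.0], 0.05, 0.10),
    ],
)
def test_derive_threshold_truncates_at_two_decimals(maxima, fraction, expected):
    assert derive_threshold(maxima, fraction) == pytest.approx(expected, abs=1e-12)


def test_derive_threshold_validation():
    with pytest.raises(ValueError):
        derive_threshold([], 0.05)
    with pytest.raises(ValueError):
        derive_threshold([1.0], 0.0)
    with pytest.raises(ValueError):
        derive_threshold([1.0], 1.0)


# ------------------------------------------------------------- threshold_roi

def test_threshold_roi_very_low_tau_returns_search_region(rng):
    counts, occ = _random_case(rng)
    sbr = sbr_image(counts, occ)
    search = rng.random(counts.values.shape) < 0.5
    search[1, 1, 1] = True
    roi = threshold_roi(sbr, -1e30, search)
    assert (roi == search).all()


def test_threshold_roi_above_max_is_empty(rng):
    counts, occ = _random_case(rng)
    sbr = sbr_image(counts, occ)
    search = np.ones(counts.values.shape, dtype=bool)
    roi = threshold_roi(sbr, sbr.values.max() + 1.0, search)
    assert not roi.any()


def test_threshold_roi_matches_set_comprehension_oracle(rng):
    counts, occ = _random_case(rng)
    sbr = sbr_image(counts, occ)
    search = rng.random(counts.values.shape) < 0.6
    search[0, 0, 0] = True
    roi = threshold_roi(sbr, 0.08, search)
    expected = {
        (i, j, k)
        for i in range(6)
        for j in range(6)
        for k in range(6)
        if search[i, j, k] and sbr.values[i, j, k] >= 0.08
    }
    assert set(zip(*np.nonzero(roi))) == expected


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    tau1=st.floats(-2.0, 2.0, allow_nan=False),
    tau2=st.floats(-2.0, 2.0, allow_nan=False),
    seed=st.integers(0, 2**16),
)
def test_threshold_roi_monotone_in_tau(tau1, tau2, seed):
    """Raising the threshold never adds voxels (set inclusion)."""
    lo, hi = min(tau1, tau2), max(tau1, tau2)
    g = np.random.default_rng(seed)
    counts = CountVolume(g.uniform(1, 100, size=(5, 5, 5)), VOX)
    occ = np.zeros((5, 5, 5), dtype=bool)
    occ[0] = True
    sbr = sbr_image(counts, occ)
    search = np.ones((5, 5, 5), dtype=bool)
    roi_hi = threshold_roi(sbr, hi, search)
    roi_lo = threshold_roi(sbr, lo, search)
    assert not (roi_hi & ~roi_lo).any()


def test_threshold_roi_includes_voxels_exactly_at_tau():
    counts = CountVolume(np.full((3, 3, 3), 10.0), VOX)
    counts.values[1, 1, 1] = 10.8  # SBR exactly 0.08
    occ = np.zeros((3, 3, 3), dtype=bool)
    occ[0] = True
    sbr = sbr_image(counts, occ)
    roi = threshold_roi(sbr, sbr.values[1, 1, 1], np.ones((3, 3, 3), dtype=bool))
    assert roi[1, 1, 1]


# ---------------------------------------------------------------- summed_sbr

def test_summed_sbr_hand_case():
    values = np.zeros((2, 2, 2))
    values[0, 0, 0], values[0, 0, 1], values[0, 1, 0] = 0.1, 0.2, 0.3
    sbr = _fake_sbr(values)
    roi = values > 0
    res = summed_sbr(sbr, roi, "brainstem", 0.08)
    assert res.summed_sbr == pytest.approx(0.6)
    assert res.mean_sbr == pytest.approx(0.2)
    assert res.voxel_count == 3
    assert res.summed_sbr == pytest.approx(res.mean_sbr * res.voxel_count)


def _fake_sbr(values):
    from sertquant import SBRVolume

    return SBRVolume(values, VOX, 1.0)


def test_summed_sbr_empty_roi_is_zero():
    res = summed_sbr(_fake_sbr(np.ones((3, 3, 3))), np.zeros((3, 3, 3), dtype=bool))
    assert (res.summed_sbr, res.mean_sbr, res.voxel_count) == (0.0, 0.0, 0)


def test_summed_sbr_matches_accumulation_oracle(rng):
    values = rng.normal(size=(6, 6, 6))
    roi = rng.random((6, 6, 6)) < 0.4
    res = summed_sbr(_fake_sbr(values), roi)
    total, n = 0.0, 0
    for i in range(6):
        for j in range(6):
            for k in range(6):
                if roi[i, j, k]:
                    total += values[i, j, k]
                    n += 1
    assert res.summed_sbr == pytest.approx(total, rel=1e-12, abs=1e-12)
    assert res.voxel_count == n


# ------------------------------------------------------------- split_by_plane

def test_split_at_grid_top_puts_everything_in_pons(rng):
    roi = rng.random((5, 5, 5)) < 0.5
    mid, pons = split_by_plane(roi, 4)
    assert not mid.any()
    assert (pons == roi).all()


def test_split_below_grid_puts_everything_in_midbrain(rng):
    roi = rng.random((5, 5, 5)) < 0.5
    mid, pons = split_by_plane(roi, -1)
    assert (mid == roi).all()
    assert not pons.any()


def test_split_out_of_range_rejected(rng):
    roi = np.ones((5, 5, 5), dtype=bool)
    for bad in (-2, 5):
        with pytest.raises(ValueError):
            split_by_plane(roi, bad)


def test_split_partition_additivity(rng):
    """Summed SBR is additive over the plane partition; mean SBR is not."""
    values = rng.normal(size=(7, 7, 7))
    roi = rng.random((7, 7, 7)) < 0.5
    sbr = _fake_sbr(values)
    mid, pons = split_by_plane(roi, 3)
    assert not (mid & pons).any()
    assert ((mid | pons) == roi).all()
    res_all = summed_sbr(sbr, roi)
    res_mid, res_pons = summed_sbr(sbr, mid), summed_sbr(sbr, pons)
    assert res_mid.summed_sbr + res_pons.summed_sbr == pytest.approx(
        res_all.summed_sbr, rel=1e-10, abs=1e-10
    )
    assert res_mid.voxel_count + res_pons.voxel_count == res_all.voxel_count
    if res_mid.voxel_count and res_pons.voxel_count:
        # means only add up when the side counts happen to be equal
        assert res_mid.mean_sbr + res_pons.mean_sbr != pytest.approx(
            res_all.mean_sbr, rel=1e-6
        )


# ------------------------------------------------------- midbrain_pons_ratio

@pytest.mark.parametrize(
    "mid, pons, expected",
    [(1.0, 1.0, 1.0), (0.0, 2.0, 0.0), (1.2, 0.8, 1.5)],
)
def test_ratio_arithmetic(mid, pons, expected):
    r_mid = SummedSBRResult("midbrain", mid, mid, 1)
    r_pons = SummedSBRResult("pons", pons, pons, 1)
    assert midbrain_pons_ratio(r_mid, r_pons) == pytest.approx(expected)


def test_ratio_undefined_for_zero_pons():
    r_mid = SummedSBRResult("midbrain", 1.0, 1.0, 1)
    r_pons = SummedSBRResult("pons", 0.0, 0.0, 0)
    with pytest.raises(ZeroDivisionError):
        midbrain_pons_ratio(r_mid, r_pons)


# ------------------------------------------------- model-level SBR recovery

def test_mean_sbr_recovers_binding_potential(small_spec, small_masks):
    """On a blur- and noise-free phantom with activities C_ref*(1+BP), the
    mean SBR of each region equals its BP exactly."""
    labels, masks = small_masks
    cv = simulate_counts(labels, small_spec, poisson=False)
    sbr = sbr_image(cv, masks["occipital"])
    for region, bp in (("midbrain", 1.7), ("pons", 1.2), ("striatum", 3.0)):
        res = summed_sbr(sbr, masks[region])
        assert res.mean_sbr == pytest.approx(bp, abs=1e-9)
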