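"""Synthetic stained sections, color deconvolution and SERT density."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sertquant import (
    HistologySpec,
    StainVectors,
    classify_pixels,
    compose_rgb,
    deconvolve,
    optical_density,
    region_density_ratio,
    sert_density,
    simulate_histology,
)
from sertquant.ihc import DensityResult


# ------------------------------------------------------------ stain vectors

def test_default_stain_vectors_are_valid_basis():
    v = StainVectors()
    assert np.allclose(np.linalg.norm(v.matrix, axis=1), 1.0)
    assert abs(np.linalg.det(v.matrix)) > 1e-3


def test_non_unit_rows_rejected():
    with pytest.raises(ValueError):
        StainVectors(np.eye(3) * 2.0)


def test_singular_matrix_rejected():
    m = np.array([[1.0, 0, 0], [1.0, 0, 0], [0, 0, 1.0]])
    with pytest.raises(ValueError):
        StainVectors(m)


# ---------------------------------------------------------- optical density

def test_white_pixel_has_zero_od():
    img = np.full((2, 2, 3), 255, dtype=np.uint8)
    assert np.all(optical_density(img) <= 2e-3)


def test_tenth_intensity_gives_unit_od():
    img = np.full((1, 1, 3), 255, dtype=np.uint8)
    img[0, 0, 1] = 25  # ~I0/10 in the green channel
    od = optical_density(img)
    assert od[0, 0, 1] == pytest.approx(1.0, rel=0.01)


def test_od_requires_rgb():
    with pytest.raises(ValueError):
        optical_density(np.zeros((4, 4), dtype=np.uint8))


def test_simulated_image_od_matches_simulated_field():
    spec = HistologySpec(image_shape=(64, 64), noise_sd=0.0, seed=3)
    image, truth = simulate_histology(spec)
    od = optical_density(image.rgb)
    conc = np.zeros((64, 64, 3))
    conc[..., 0] = spec.dab_amplitude * truth["immunopositive"]
    conc[..., 1] = spec.myelin_amplitude * truth["myelin"]
    expected = conc @ image.stain_vectors.matrix
    assert np.max(np.abs(od - expected)) < 1e-2


# ------------------------------------------------------------- deconvolve

def test_deconvolve_recovers_pure_dab_direction():
    v = StainVectors()
    od = 0.7 * v.matrix[0]
    conc = deconvolve(od.reshape(1, 1, 3), v)
    assert conc[0, 0] == pytest.approx([0.7, 0.0, 0.0], abs=1e-10)


def test_deconvolve_zero_od_gives_zero_concentration():
    v = StainVectors()
    assert np.all(deconvolve(np.zeros((2, 2, 3)), v) == 0.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**16))
def test_compose_deconvolve_round_trip(seed):
    """Deconvolution is the exact linear inverse of stain composition."""
    g = np.random.default_rng(seed)
    v = StainVectors()
    conc = g.uniform(0.0, 1.2, size=(8, 8, 3))
    od = conc @ v.matrix
    recovered = deconvolve(od, v)
    assert np.allclose(recovered, conc, atol=1e-6)


# ---------------------------------------------------------- classification

def test_zero_dab_threshold_selects_all_pixels():
    conc = np.zeros((4, 4, 3))
    conc[0, 0, 0] = 0.5
    cls = classify_pixels(conc, dab_thresh=0.0, myelin_thresh=1.0)
    assert cls.immunopositive.all()  # >= 0 holds everywhere after clipping


def test_huge_myelin_threshold_makes_everything_gray():
    conc = np.ones((4, 4, 3))
    cls = classify_pixels(conc, dab_thresh=0.5, myelin_thresh=1e30)
    assert cls.gray_matter.all()


def test_classification_f1_on_noise_free_section():
    spec = HistologySpec(image_shape=(128, 128), noise_sd=0.0, seed=11)
    image, truth = simulate_histology(spec)
    conc = deconvolve(optical_density(image.rgb), image.stain_vectors)
    cls = classify_pixels(
        conc,
        dab_thresh=spec.dab_amplitude / 2,
        myelin_thresh=spec.myelin_amplitude / 2,
    )
    for pred, true in (
        (cls.immunopositive, truth["immunopositive"]),
        (~cls.gray_matter, truth["myelin"]),
    ):
        tp = (pred & true).sum()
        f1 = 2 * tp / (pred.sum() + true.sum())
        assert f1 >= 0.95


# --------------------------------------------------------------- density

def test_density_one_when_all_gray_is_positive():
    m = np.ones((5, 5), dtype=bool)
    res = sert_density(m, m, m)
    assert res.density == 1.0


def test_density_zero_without_positives():
    gm = np.ones((5, 5), dtype=bool)
    res = sert_density(np.zeros_like(gm), gm, gm)
    assert res.density == 0.0


def test_density_matches_counting_oracle(rng):
    pos = rng.random((16, 16)) < 0.3
    gm = rng.random((16, 16)) < 0.7
    region = rng.random((16, 16)) < 0.8
    if not (gm & region).any():
        gm[:] = True
    res = sert_density(pos, gm, region)
    n_gm, n_pos = 0, 0
    for i in range(16):
        for j in range(16):
            if gm[i, j] and region[i, j]:
                n_gm += 1
                if pos[i, j]:
                    n_pos += 1
    assert res.gray_matter_pixels == n_gm
    assert res.immunopositive_pixels == n_pos
    assert res.density == pytest.approx(n_pos / n_gm)


def test_density_undefined_without_gray_matter():
    with pytest.raises(ValueError):
        sert_density(
            np.ones((3, 3), dtype=bool),
            np.zeros((3, 3), dtype=bool),
            np.ones((3, 3), dtype=bool),
        )


@pytest.mark.parametrize(
    "sn, raphe, expected", [(0.08, 0.08, 1.0), (0.0, 0.08, 0.0), (0.04, 0.08, 0.5)]
)
def test_density_ratio_arithmetic(sn, raphe, expected):
    r1 = DensityResult("substantia_nigra", 0, 1, sn)
    r2 = DensityResult("raphe", 0, 1, raphe)
    assert region_density_ratio(r1, r2) == pytest.approx(expected)


def test_density_ratio_undefined_for_zero_raphe():
    r1 = DensityResult("substantia_nigra", 0, 1, 0.1)
    r2 = DensityResult("raphe", 0, 1, 0.0)
    with pytest.raises(ZeroDivisionError):
        region_density_ratio(r1, r2)


# ------------------------------------------------------- simulator contract

def test_blank_section_has_empty_truth_masks():
    spec = HistologySpec(
        image_shape=(32, 32), neurite_density=0.0, myelin_fraction=0.0, noise_sd=0.0
    )
    image, truth = simulate_histology(spec)
    assert not truth["immunopositive"].any()
    assert not truth["myelin"].any()
    assert np.all(image.rgb == 255)


def test_full_density_covers_all_pixels():
    spec = HistologySpec(
        image_shape=(32, 32), neurite_density=1.0, myelin_fraction=0.0, noise_sd=0.0
    )
    _, truth = simulate_histology(spec)
    assert truth["immunopositive"].all()


def test_histology_reproducible_from_seed():
    spec = HistologySpec(image_shape=(48, 48), seed=5)
    img1, t1 = simulate_histology(spec)
    img2, t2 = simulate_histology(spec)
    assert np.array_equal(img1.rgb, img2.rgb)
    assert np.array_equal(t1["immunopositive"], t2["immunopositive"])


def test_density_recovery_and_brightness_invariance():
    """The full density pipeline recovers ground truth at zero noise and is
    invariant to a uniform change of the white level when OD uses the
    matching I0."""
    densities = {}
    for i0 in (255.0, 200.0):
        spec = HistologySpec(
            image_shape=(128, 128),
            neurite_density=0.07,
            myelin_fraction=0.25,
            noise_sd=0.0,
            background_intensity=i0,
            seed=21,
        )
        image, truth = simulate_histology(spec)
        conc = deconvolve(optical_density(image.rgb, i0=i0), image.stain_vectors)
        cls = classify_pixels(conc, dab_thresh=0.5, myelin_thresh=0.4)
        res = sert_density(cls.immunopositive, cls.gray_matter)
        true_density = truth["immunopositive"].sum() / (~truth["myelin"]).sum()
        assert abs(res.density - true_density) < 0.01
        densities[i0] = res.density
    assert densities[255.0] == pytest.approx(densities[200.0], abs=0.005)
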