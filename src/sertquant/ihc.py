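"""Immunohistochemical SERT density via optical-density color deconvolution.

Photomicrographs are dual-stained: DAB (brown chromogen) marks
SERT-immunopositive structures and a Luxol-fast-blue myelin stain marks
white matter, so gray matter is the Luxol-fast-blue-negative area.
Per-pixel RGB intensities are converted to optical densities by
Beer-Lambert (OD_c = -log10((I_c + eps)/I0)) and unmixed into per-stain
concentrations with the inverse of a unit-norm stain-vector matrix.
SERT density is the immunopositive fraction of the gray-matter area, and
disease burden is compared via the substantia-nigra-to-raphe density ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "StainVectors",
    "StainedImage",
    "PixelClassification",
    "DensityResult",
    "optical_density",
    "compose_rgb",
    "deconvolve",
    "classify_pixels",
    "sert_density",
    "region_density_ratio",
]

# Standard published DAB optical-density vector and a blue counterstain
# vector standing in for Luxol fast blue (strong red/green absorption,
# weak blue); the residual row completes an invertible basis.
_DAB = np.array([0.268, 0.570, 0.776])
_BLUE = np.array([0.875, 0.458, 0.158])


def _default_matrix() -> np.ndarray:
    dab = _DAB / np.linalg.norm(_DAB)
    blue = _BLUE / np.linalg.norm(_BLUE)
    residual = np.cross(dab, blue)
    residual /= np.linalg.norm(residual)
    return np.stack([dab, blue, residual])


@dataclass(frozen=True)
class StainVectors:
    """3x3 matrix of unit-norm optical-density stain vectors.

    Rows: DAB, myelin (Luxol-fast-blue-like) stain, residual.
    """

    matrix: np.ndarray = field(default_factory=_default_matrix)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain vector rows must have unit norm, got {norms}")
        if abs(np.linalg.det(m)) < 1e-8:
            raise ValueError("stain matrix is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass(frozen=True)
class StainedImage:
    """8-bit RGB photomicrograph with its stain-vector matrix."""

    rgb: np.ndarray
    stain_vectors: StainVectors

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError(f"expected HxWx3 RGB image, got {self.rgb.shape}")
        if self.rgb.dtype != np.uint8:
            raise ValueError(f"expected 8-bit image, got dtype {self.rgb.dtype}")


@dataclass(frozen=True)
class PixelClassification:
    """Stain-threshold pixel classes: immunopositive (raw and restricted to
    gray matter) and gray matter (myelin-stain-negative)."""

    immunopositive: np.ndarray
    gray_matter: np.ndarray
    immunopositive_gray: np.ndarray
    dab_threshold: float
    myelin_threshold: float


@dataclass(frozen=True)
class DensityResult:
    """SERT density: immunopositive area over gray matter area in a region."""

    region_name: str
    immunopositive_pixels: int
    gray_matter_pixels: int
    density: float


def optical_density(rgb: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Beer-Lambert optical density per channel, OD = -log10((I+1)/I0).

    The +1 offset keeps zero intensities finite; negative ODs (intensities
    above the white level) are clipped to 0.
    """
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {arr.shape}")
    od = -np.log10((arr.astype(float) + 1.0) / i0)
    return np.clip(od, 0.0, None)


def compose_rgb(
    concentrations: np.ndarray,
    vectors: StainVectors,
    i0: float = 255.0,
    quantize: bool = True,
) -> np.ndarray:
    """Forward Beer-Lambert model: stain concentrations -> RGB image.

    OD = C . V, then I = I0 * 10**(-OD); with ``quantize`` the result is
    rounded to 8 bits.  The exact inverse of :func:`deconvolve` up to
    quantization.
    """
    od = np.asarray(concentrations, dtype=float) @ vectors.matrix
    img = i0 * np.power(10.0, -od)
    if quantize:
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img


def deconvolve(od: np.ndarray, vectors: StainVectors) -> np.ndarray:
    """Unmix per-pixel optical densities into per-stain concentrations.

    Solves OD = C . V by right-multiplying with V^-1; negative
    concentrations (noise leaking past the basis) are clipped to 0 after
    solving.
    """
    conc = np.asarray(od, dtype=float) @ vectors.inverse
    return np.clip(conc, 0.0, None)


def _resolve_threshold(channel: np.ndarray, thresh: float | str) -> float:
    if isinstance(thresh, str):
        if thresh != "otsu":
            raise ValueError(f"unknown threshold rule {thresh!r}")
        return float(threshold_otsu(channel))
    t = float(thresh)
    if t < 0:
        raise ValueError(f"threshold must be >= 0, got {t}")
    return t


def classify_pixels(
    conc: np.ndarray,
    dab_thresh: float | str = "otsu",
    myelin_thresh: float | str = "otsu",
) -> PixelClassification:
    """Threshold stain concentrations into immunopositive and gray matter.

    immunopositive: DAB concentration >= dab_thresh (note dab_thresh = 0
    therefore selects *every* pixel, since concentrations are clipped at 0);
    gray matter: myelin concentration < myelin_thresh.  Thresholds may be
    numbers in concentration (OD) units or ``"otsu"`` for a per-image Otsu
    threshold on the concentration histogram.
    """
    dab = conc[..., 0]
    myelin = conc[..., 1]
    t_dab = _resolve_threshold(dab, dab_thresh)
    t_mye = _resolve_threshold(myelin, myelin_thresh)
    immuno = dab >= t_dab
    gray = myelin < t_mye
    return PixelClassification(immuno, gray, immuno & gray, t_dab, t_mye)


def sert_density(
    immunopositive: np.ndarray,
    gray_matter: np.ndarray,
    region: np.ndarray | None = None,
    region_name: str = "",
) -> DensityResult:
    """SERT density = |immunopositive ∩ gray matter ∩ region| / |gray matter ∩ region|.

    Raises ValueError when the region contains no gray matter (density
    undefined).
    """
    if region is None:
        region = np.ones(gray_matter.shape, dtype=bool)
    gm = gray_matter & region
    n_gm = int(gm.sum())
    if n_gm == 0:
        raise ValueError(f"no gray matter in region {region_name!r}; density undefined")
    n_pos = int((immunopositive & gm).sum())
    return DensityResult(region_name, n_pos, n_gm, n_pos / n_gm)


def region_density_ratio(sn: DensityResult, raphe: DensityResult) -> float:
    """Substantia-nigra-to-raphe SERT density ratio.

    Undefined (raises ZeroDivisionError) for zero raphe density.
    """
    if raphe.density == 0:
        raise ZeroDivisionError("raphe density is zero; ratio undefined")
    return sn.density / raphe.density
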