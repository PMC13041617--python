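"""Synthetic dual-stained (DAB + myelin) photomicrographs with ground truth.

Emulates the quantification substrate, not tissue realism: white matter is a
smooth random blob field occupying an exact target fraction of the image
(myelin-stain positive); SERT-immunopositive neurites are thin random line
segments restricted to gray matter and topped up/trimmed to an exact pixel
count, so the ground-truth density is controllable to one pixel.  Per-pixel
stain concentrations are rendered to RGB through the Beer-Lambert forward
model and optional Gaussian camera noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line

from .ihc import StainVectors, StainedImage, compose_rgb

__all__ = ["HistologySpec", "IhcCohortSpec", "simulate_histology", "simulate_ihc_cohort"]


@dataclass(frozen=True)
class HistologySpec:
    """Parameters of one synthetic dual-stained section.

    ``neurite_density`` is the expected immunopositive fraction of gray
    matter; ``myelin_fraction`` the white-matter fraction of the field.
    Stain amplitudes are peak concentrations in OD units along each stain
    vector; ``noise_sd`` is additive per-channel Gaussian noise in 8-bit
    intensity units.
    """

    image_shape: tuple[int, int] = (256, 256)
    neurite_density: float = 0.05
    myelin_fraction: float = 0.30
    stain_vectors: StainVectors = field(default_factory=StainVectors)
    background_intensity: float = 255.0
    noise_sd: float = 2.0
    dab_amplitude: float = 0.9
    myelin_amplitude: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.neurite_density <= 1:
            raise ValueError("neurite_density must lie in [0, 1]")
        if not 0 <= self.myelin_fraction <= 1:
            raise ValueError("myelin_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.background_intensity > 0:
            raise ValueError("background_intensity must be > 0")


def _exact_fraction_mask(
    field_: np.ndarray, fraction: float
) -> np.ndarray:
    """Boolean mask selecting the top `fraction` of pixels of a scalar field."""
    n = field_.size
    k = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    if k > 0:
        order = np.argsort(field_.ravel(), kind="stable")
        mask[order[n - k:]] = True
    return mask.reshape(field_.shape)


def _neurite_mask(
    rng: np.random.Generator, gray: np.ndarray, density: float
) -> np.ndarray:
    """Random line-segment mask inside gray matter at an exact pixel count."""
    h, w = gray.shape
    n_gray = int(gray.sum())
    target = int(round(density * n_gray))
    mask = np.zeros_like(gray)
    if target == 0 or n_gray == 0:
        return mask
    gray_idx = np.flatnonzero(gray.ravel())
    for _ in range(200_000):
        if int(mask.sum()) >= target:
            break
        r0 = rng.integers(0, h)
        c0 = rng.integers(0, w)
        if not gray[r0, c0]:
            continue
        length = rng.uniform(5, 20)
        theta = rng.uniform(0, 2 * math.pi)
        r1 = int(np.clip(round(r0 + length * math.sin(theta)), 0, h - 1))
        c1 = int(np.clip(round(c0 + length * math.cos(theta)), 0, w - 1))
        rr, cc = line(r0, c0, r1, c1)
        keep = gray[rr, cc]
        mask[rr[keep], cc[keep]] = True
    # adjust to the exact target count
    flat = mask.ravel()
    n_on = int(flat.sum())
    if n_on > target:
        on = np.flatnonzero(flat)
        off = rng.choice(on, size=n_on - target, replace=False)
        flat[off] = False
    elif n_on < target:
        candidates = gray_idx[~flat[gray_idx]]
        add = rng.choice(candidates, size=target - n_on, replace=False)
        flat[add] = True
    return flat.reshape(gray.shape)


def simulate_histology(
    spec: HistologySpec,
) -> tuple[StainedImage, dict[str, np.ndarray]]:
    """Render one synthetic section; returns the image and truth masks.

    Truth masks: ``"immunopositive"`` (DAB-bearing neurite pixels, all within
    gray matter) and ``"myelin"`` (white-matter pixels).  Reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    blob_field = ndimage.gaussian_filter(
        rng.standard_normal((h, w)), sigma=max(2.0, min(h, w) / 16.0)
    )
    myelin = _exact_fraction_mask(blob_field, spec.myelin_fraction)
    gray = ~myelin
    neurites = _neurite_mask(rng, gray, spec.neurite_density)

    conc = np.zeros((h, w, 3), dtype=float)
    conc[..., 0] = spec.dab_amplitude * neurites
    conc[..., 1] = spec.myelin_amplitude * myelin
    img = compose_rgb(
        conc, spec.stain_vectors, i0=spec.background_intensity, quantize=False
    )
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    rgb = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = {"immunopositive": neurites, "myelin": myelin}
    return StainedImage(rgb, spec.stain_vectors), truth


@dataclass(frozen=True)
class IhcCohortSpec:
    """Two-group histology cohort over two anatomical regions.

    Emulates the autopsy comparison: per subject one substantia-nigra and
    one pontine-raphe section; the disease group scales the SN neurite
    density down and the raphe density up.  Subject variability is a
    lognormal factor (mean 1) with the given CV per region.
    """

    n_per_group: tuple[int, int] = (5, 5)
    base_density: dict[str, float] = field(
        default_factory=lambda: {"substantia_nigra": 0.06, "raphe": 0.04}
    )
    group_effects: dict[str, float] = field(
        default_factory=lambda: {"substantia_nigra": 0.4, "raphe": 1.5}
    )
    between_subject_cv: float = 0.1
    section: HistologySpec = field(default_factory=HistologySpec)
    seed: int = 0
    group_names: tuple[str, str] = ("MSA-P", "HC")


def simulate_ihc_cohort(
    spec: IhcCohortSpec,
) -> list[dict]:
    """Per-subject synthetic sections for both regions and groups.

    Returns records with subject id, group, region, the StainedImage, truth
    masks and the true density used.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.between_subject_cv**2))
    records = []
    for gi in (1, 0):  # controls first, disease second
        group = spec.group_names[gi]
        for si in range(spec.n_per_group[gi]):
            for region, base in spec.base_density.items():
                eff = spec.group_effects[region] if gi == 0 else 1.0
                factor = float(rng.lognormal(-0.5 * sigma * sigma, sigma))
                density = min(1.0, base * eff * factor)
                sec = HistologySpec(
                    image_shape=spec.section.image_shape,
                    neurite_density=density,
                    myelin_fraction=spec.section.myelin_fraction,
                    stain_vectors=spec.section.stain_vectors,
                    background_intensity=spec.section.background_intensity,
                    noise_sd=spec.section.noise_sd,
                    dab_amplitude=spec.section.dab_amplitude,
                    myelin_amplitude=spec.section.myelin_amplitude,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                image, truth = simulate_histology(sec)
                records.append(
                    {
                        "subject_id": f"{group}-{si + 1:02d}",
                        "group": group,
                        "region": region,
                        "image": image,
                        "truth": truth,
                        "true_density": density,
                    }
                )
    return records
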