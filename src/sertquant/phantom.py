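"""Digital brain phantoms and simulated subject cohorts.

Phantoms are axis-aligned parametric geometries (ellipsoids and slabs) on a
regular voxel grid: an occipital reference slab, midbrain and pons ellipsoids
stacked along the inferior-superior axis (axis 2), and a bilateral striatum.
Regional activities follow the equilibrium binding model — a region with
binding potential BP carries activity C_ref * (1 + BP) over a nonspecific
background at the occipital level C_ref — so voxel-wise specific binding
ratios of a noise-free, blur-free phantom recover BP exactly.

Acquisition is emulated by an isotropic Gaussian point-spread function
(default 7 mm FWHM, the resolution of the triple-head system modeled here)
followed by Poisson counting noise.  No projection/reconstruction, scatter
or attenuation is modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import numpy as np
from scipy import ndimage

__all__ = [
    "Ellipsoid",
    "Slab",
    "PhantomSpec",
    "CohortSpec",
    "CountVolume",
    "Subject",
    "GeometryError",
    "default_phantom_spec",
    "build_label_volume",
    "simulate_counts",
    "simulate_cohort",
    "boundary_index_from_masks",
    "FWHM_TO_SIGMA",
]

# FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class GeometryError(ValueError):
    """A region falls outside the grid or overlaps another region."""


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid; center and radii in mm (world units)."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]

    def contains(self, coords_mm: Sequence[np.ndarray]) -> np.ndarray:
        if any(r < 0 for r in self.radii_mm):
            raise GeometryError(f"negative radii {self.radii_mm}")
        if any(r == 0 for r in self.radii_mm):
            return np.zeros(np.broadcast(*coords_mm).shape, dtype=bool)
        q = sum(
            ((c - c0) / r) ** 2
            for c, c0, r in zip(coords_mm, self.center_mm, self.radii_mm)
        )
        return q <= 1.0

    def bounds_mm(self) -> tuple[tuple[float, float], ...]:
        return tuple(
            (c - r, c + r) for c, r in zip(self.center_mm, self.radii_mm)
        )


@dataclass(frozen=True)
class Slab:
    """Axis-aligned box; inclusive lower/upper corners in mm."""

    lo_mm: tuple[float, float, float]
    hi_mm: tuple[float, float, float]

    def contains(self, coords_mm: Sequence[np.ndarray]) -> np.ndarray:
        out = np.ones(np.broadcast(*coords_mm).shape, dtype=bool)
        for c, lo, hi in zip(coords_mm, self.lo_mm, self.hi_mm):
            out &= (c >= lo) & (c <= hi)
        return out

    def bounds_mm(self) -> tuple[tuple[float, float], ...]:
        return tuple(zip(self.lo_mm, self.hi_mm))


Shape = Union[Ellipsoid, Slab]


@dataclass(frozen=True)
class CountVolume:
    """3D nonnegative grid of detected counts with voxel spacing in mm."""

    values: np.ndarray
    voxel_size: tuple[float, float, float]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, activity and acquisition parameters of a digital phantom.

    ``region_geometry`` maps region names to tuples of primitive shapes;
    ``region_activity`` maps the same names (plus ``"background"``) to true
    activity concentrations in arbitrary kBq/mL-like units.  Voxel centers
    sit at ``index * voxel_size`` (0-based), orientation RAS-like with
    axis 2 running inferior to superior.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    region_geometry: Mapping[str, tuple[Shape, ...]] = field(default_factory=dict)
    region_activity: Mapping[str, float] = field(default_factory=dict)
    psf_fwhm: float = 7.0
    counts_scale: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm < 0:
            raise ValueError(f"psf_fwhm must be >= 0, got {self.psf_fwhm}")
        if not self.counts_scale > 0:
            raise ValueError(f"counts_scale must be > 0, got {self.counts_scale}")
        for name, act in self.region_activity.items():
            if act < 0:
                raise ValueError(f"negative activity for region {name!r}: {act}")
        occ = self.region_activity.get("occipital", None)
        if occ is not None and not occ > 0:
            raise ValueError("occipital reference activity must be > 0")


# Default HC binding potentials (free parameters of the generator; the SBR of
# a blur-free phantom region equals its BP by construction).
_DEFAULT_BP = {"midbrain": 1.7, "pons": 1.2, "striatum": 3.0}
_DEFAULT_C_REF = 1.0


def default_phantom_spec(**overrides) -> PhantomSpec:
    """Phantom with occipital slab, midbrain/pons stack and bilateral striatum.

    128 mm cubic field of view at 2 mm isotropic voxels.  The pons ellipsoid
    tops out at z = 66 mm and the midbrain starts at z = 68 mm, so the true
    inter-structure boundary plane is voxel index 33 along axis 2.
    """
    geometry = {
        "occipital": (Slab((20.0, 16.0, 40.0), (104.0, 40.0, 88.0)),),
        "midbrain": (Ellipsoid((64.0, 64.0, 76.0), (10.0, 10.0, 8.0)),),
        "pons": (Ellipsoid((64.0, 64.0, 56.0), (12.0, 12.0, 10.0)),),
        "striatum": (
            Ellipsoid((44.0, 86.0, 80.0), (9.0, 13.0, 9.0)),
            Ellipsoid((84.0, 86.0, 80.0), (9.0, 13.0, 9.0)),
        ),
    }
    activity = {"background": _DEFAULT_C_REF, "occipital": _DEFAULT_C_REF}
    for name, bp in _DEFAULT_BP.items():
        activity[name] = _DEFAULT_C_REF * (1.0 + bp)
    spec = PhantomSpec(region_geometry=geometry, region_activity=activity)
    return replace(spec, **overrides) if overrides else spec


REGION_LABELS = {"occipital": 1, "midbrain": 2, "pons": 3, "striatum": 4}


def _voxel_coords_mm(spec: PhantomSpec) -> list[np.ndarray]:
    axes = [
        np.arange(n, dtype=float) * dv
        for n, dv in zip(spec.grid_shape, spec.voxel_size)
    ]
    return list(np.meshgrid(*axes, indexing="ij", sparse=True))


def build_label_volume(
    spec: PhantomSpec,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Rasterize the phantom geometry into an integer label grid and masks.

    Returns the label volume (0 = background) and a dict of boolean masks,
    one per named region plus the derived ``"brainstem"`` (midbrain | pons)
    and ``"background"``.  Deterministic; raises :class:`GeometryError` if a
    region extends beyond the grid or two regions overlap.
    """
    coords = _voxel_coords_mm(spec)
    extent = [
        (n - 1) * dv for n, dv in zip(spec.grid_shape, spec.voxel_size)
    ]
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    masks: dict[str, np.ndarray] = {}
    for idx, (name, shapes) in enumerate(spec.region_geometry.items(), start=1):
        mask = np.zeros(spec.grid_shape, dtype=bool)
        for shape in shapes:
            for ax, (lo, hi) in enumerate(shape.bounds_mm()):
                if lo < 0 or hi > extent[ax]:
                    raise GeometryError(
                        f"region {name!r} exceeds grid along axis {ax}: "
                        f"[{lo}, {hi}] mm vs [0, {extent[ax]}] mm"
                    )
            mask |= shape.contains(coords)
        if (labels[mask] != 0).any():
            raise GeometryError(f"region {name!r} overlaps a previous region")
        label = REGION_LABELS.get(name, idx)
        labels[mask] = label
        masks[name] = mask
    if "midbrain" in masks and "pons" in masks:
        masks["brainstem"] = masks["midbrain"] | masks["pons"]
    masks["background"] = labels == 0
    return labels, masks


def activity_volume(labels: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Per-voxel true activity implied by the label grid and region_activity."""
    act = np.full(labels.shape, spec.region_activity.get("background", 0.0))
    for name in spec.region_geometry:
        label = REGION_LABELS.get(name, None)
        if label is None:
            continue
        a = spec.region_activity.get(name, 0.0)
        act[labels == label] = a
    if (act < 0).any():
        raise ValueError("negative activity in phantom")
    return act


def _blur(act: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.psf_fwhm == 0:
        return act
    sigma_vox = [
        spec.psf_fwhm * FWHM_TO_SIGMA / dv for dv in spec.voxel_size
    ]
    return ndimage.gaussian_filter(act, sigma=sigma_vox, truncate=4.0,
                                   mode="constant", cval=0.0)


def simulate_counts(
    labels: np.ndarray,
    spec: PhantomSpec,
    *,
    rng: np.random.Generator | None = None,
    poisson: bool = True,
) -> CountVolume:
    """Emulate acquisition: PSF blur, count scaling, Poisson sampling.

    The activity map is convolved with an isotropic Gaussian of FWHM
    ``spec.psf_fwhm`` mm (sigma = FWHM / 2.3548 converted to voxels per
    axis, kernel truncated at 4 sigma), scaled by ``counts_scale`` and
    Poisson-sampled per voxel.  ``poisson=False`` is a test hook returning
    the expected counts exactly.  Reproducible for a fixed seed.
    """
    act = activity_volume(labels, spec)
    expected = _blur(act, spec) * spec.counts_scale
    if not poisson:
        return CountVolume(expected, spec.voxel_size)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(expected).astype(np.float64)
    return CountVolume(counts, spec.voxel_size)


def boundary_index_from_masks(pons_mask: np.ndarray) -> int:
    """True midbrain/pons boundary plane: the topmost pons voxel index (axis 2).

    ``split_by_plane`` assigns voxels at or below this index to the pons.
    """
    zs = np.nonzero(pons_mask)[2]
    if zs.size == 0:
        raise ValueError("empty pons mask has no boundary plane")
    return int(zs.max())


@dataclass(frozen=True)
class CohortSpec:
    """Simulated two-group cohort: a parkinsonian MSA-like disease group
    with reduced midbrain and elevated pontine activity, versus healthy
    controls.

    Parameters
    ----------
    n_per_group : (int, int)
        Subjects in the (disease, control) groups; at least 2 each.
    group_effects : (float, float)
        Multiplicative (midbrain, pons) activity factors applied to the
        disease group.
    between_subject_cv : float
        Coefficient of variation of regional activity across subjects
        (lognormal subject factors, mean 1).
    age_model : ((mean, sd), (mean, sd))
        Per-group normal age distributions in years, truncated at 0.
    female_fraction : (float, float)
        Probability a subject in each group is female.
    """

    n_per_group: tuple[int, int] = (20, 20)
    group_effects: tuple[float, float] = (0.6, 1.4)
    between_subject_cv: float = 0.15
    age_model: tuple[tuple[float, float], tuple[float, float]] = (
        (62.6, 9.4),
        (71.9, 10.3),
    )
    female_fraction: tuple[float, float] = (0.53, 0.53)
    seed: int = 0
    group_names: tuple[str, str] = ("MSA-P", "HC")

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.between_subject_cv < 0:
            raise ValueError("between_subject_cv must be >= 0")
        for mean, sd in self.age_model:
            if mean <= 0 or sd < 0:
                raise ValueError("age model requires mean > 0 and sd >= 0")


@dataclass(frozen=True)
class Subject:
    """One simulated subject: counts, anatomy masks and metadata record."""

    subject_id: str
    group: str
    age: float
    sex: str
    counts: CountVolume
    masks: dict[str, np.ndarray]
    boundary_index: int
    true_activity: dict[str, float]


def _truncated_normal_age(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        a = rng.normal(mean, sd)
        if a > 0:
            return float(a)
    raise RuntimeError("age sampling failed to produce a positive value")


def simulate_cohort(
    phantom: PhantomSpec, cohort: CohortSpec
) -> list[Subject]:
    """Generate per-subject count volumes for a two-group cohort.

    Controls are generated first (they serve as the threshold-calibration
    subjects downstream), then the disease group.  Per subject, each named
    region's activity is base activity x group effect x an independent
    lognormal factor with the requested CV (the nonspecific background is
    tied to the occipital factor so the reference level stays coherent).
    Fully reproducible from ``cohort.seed``.
    """
    labels, masks = build_label_volume(phantom)
    boundary = boundary_index_from_masks(masks["pons"])
    rng = np.random.default_rng(cohort.seed)
    cv = cohort.between_subject_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    mid_eff, pons_eff = cohort.group_effects

    subjects: list[Subject] = []
    # control group first, disease second
    order = [1, 0]
    for gi in order:
        name = cohort.group_names[gi]
        mean_age, sd_age = cohort.age_model[gi]
        for si in range(cohort.n_per_group[gi]):
            factors = {
                region: float(rng.lognormal(-0.5 * sigma * sigma, sigma))
                for region in ("occipital", "midbrain", "pons", "striatum")
            }
            act = dict(phantom.region_activity)
            for region, f in factors.items():
                if region in act:
                    act[region] = act[region] * f
            if "background" in act:
                act["background"] = act["background"] * factors["occipital"]
            if gi == 0:  # disease group
                act["midbrain"] = act.get("midbrain", 0.0) * mid_eff
                act["pons"] = act.get("pons", 0.0) * pons_eff
            subj_spec = replace(phantom, region_activity=act)
            counts = simulate_counts(labels, subj_spec, rng=rng, poisson=True)
            age = _truncated_normal_age(rng, mean_age, sd_age)
            sex = "F" if rng.random() < cohort.female_fraction[gi] else "M"
            subjects.append(
                Subject(
                    subject_id=f"{name}-{si + 1:02d}",
                    group=name,
                    age=age,
                    sex=sex,
                    counts=counts,
                    masks=masks,
                    boundary_index=boundary,
                    true_activity=act,
                )
            )
    return subjects
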