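"""Voxel-wise SBR images, threshold-derived 3D ROIs and summed voxel SBR.

The specific binding ratio of a voxel is its count excess over the mean of
an occipital reference region, normalized by that mean:

    SBR = (counts - mean_occipital) / mean_occipital

an equilibrium estimate of the binding potential.  Because the brainstem's
transporter distribution is spatially irregular, regional burden is
summarized by the *summed* voxel-based SBR — the sum over all voxels of a
threshold-defined 3D ROI — rather than the ROI mean, which is more
sensitive to partial-volume dilution.  The lower SBR threshold is derived
once from a calibration set as a fixed fraction (5%) of the mean per-subject
maximum SBR, truncated to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .phantom import CountVolume

__all__ = [
    "SBRVolume",
    "SummedSBRResult",
    "sbr_image",
    "derive_threshold",
    "threshold_roi",
    "summed_sbr",
    "split_by_plane",
    "midbrain_pons_ratio",
]

INFERIOR_SUPERIOR_AXIS = 2


class ReferenceError(ValueError):
    """Reference region empty or with nonpositive mean counts."""


@dataclass(frozen=True)
class SBRVolume:
    """Voxel-wise specific binding ratio grid (dimensionless).

    ``reference_mean`` is the occipital mean count (counts/voxel) every
    voxel was normalized by; negative SBR values are preserved.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    reference_mean: float


@dataclass(frozen=True)
class SummedSBRResult:
    """Summed and mean SBR over a 3D ROI.

    ``summed_sbr = mean_sbr * voxel_count`` to numerical precision; an
    empty ROI yields zeros by convention.
    """

    region_name: str
    summed_sbr: float
    mean_sbr: float
    voxel_count: int
    threshold_used: float = math.nan


def sbr_image(counts: CountVolume, occipital: np.ndarray) -> SBRVolume:
    """Compute the voxel-wise SBR volume against the occipital reference.

    Raises :class:`ReferenceError` for an empty mask or nonpositive
    reference mean.  Negative SBRs are kept (thresholding removes them
    downstream).
    """
    if occipital.shape != counts.values.shape:
        raise ValueError("occipital mask shape does not match counts")
    if not occipital.any():
        raise ReferenceError("occipital reference mask is empty")
    ref = float(counts.values[occipital].mean())
    if not ref > 0:
        raise ReferenceError(f"occipital mean counts must be > 0, got {ref}")
    values = (counts.values - ref) / ref
    return SBRVolume(values, counts.voxel_size, ref)


def _floor_2dp(x: float) -> float:
    # round at 1e-9 first so float representation noise cannot flip the floor
    return math.floor(round(x * 100.0, 9)) / 100.0


def derive_threshold(max_sbrs: Sequence[float], fraction: float = 0.05) -> float:
    """Lower SBR threshold from calibration subjects' maximum brainstem SBRs.

    threshold = floor_2dp(fraction * mean(max_sbrs)), truncating toward zero
    at two decimals (a calibration mean of 1.71 at fraction 0.05 gives 0.08).
    """
    arr = np.asarray(max_sbrs, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one calibration maximum SBR")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    return _floor_2dp(fraction * float(arr.mean()))


def threshold_roi(
    sbr: SBRVolume, tau: float, search_region: np.ndarray
) -> np.ndarray:
    """3D ROI: voxels of ``search_region`` with SBR >= tau.

    ``search_region`` is the programmatic stand-in for the anatomical,
    MRI-guided manual boundary adjustment; voxels exactly at tau are
    included.
    """
    if not math.isfinite(tau):
        raise ValueError(f"tau must be finite, got {tau}")
    if not search_region.any():
        raise ValueError("search region is empty")
    return search_region & (sbr.values >= tau)


def summed_sbr(
    sbr: SBRVolume,
    roi: np.ndarray,
    region_name: str = "",
    threshold_used: float = math.nan,
) -> SummedSBRResult:
    """Summed voxel-based SBR, mean SBR and voxel count over an ROI."""
    if roi.shape != sbr.values.shape:
        raise ValueError("ROI shape does not match SBR volume")
    n = int(roi.sum())
    if n == 0:
        return SummedSBRResult(region_name, 0.0, 0.0, 0, threshold_used)
    total = float(sbr.values[roi].sum())
    return SummedSBRResult(region_name, total, total / n, n, threshold_used)


def split_by_plane(
    roi: np.ndarray, boundary_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Partition an ROI at a transverse plane into (midbrain, pons) masks.

    Voxels with inferior-superior index (axis 2) strictly above
    ``boundary_index`` go to the midbrain, those at or below to the pons.
    ``boundary_index = -1`` puts everything in the midbrain, the top index
    everything in the pons.
    """
    nz = roi.shape[INFERIOR_SUPERIOR_AXIS]
    if not -1 <= boundary_index <= nz - 1:
        raise ValueError(
            f"boundary index {boundary_index} outside grid extent [-1, {nz - 1}]"
        )
    z = np.arange(nz).reshape(1, 1, nz)
    midbrain = roi & (z > boundary_index)
    pons = roi & (z <= boundary_index)
    return midbrain, pons


def midbrain_pons_ratio(
    midbrain_result: SummedSBRResult, pons_result: SummedSBRResult
) -> float:
    """Midbrain-to-pons ratio of summed voxel-based SBRs.

    Undefined (raises ZeroDivisionError) when the pons sum is zero; callers
    report it as missing rather than 0.
    """
    if pons_result.summed_sbr == 0:
        raise ZeroDivisionError("pons summed SBR is zero; ratio undefined")
    return midbrain_result.summed_sbr / pons_result.summed_sbr
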