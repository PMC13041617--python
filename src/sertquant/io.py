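"""File I/O: NIfTI-1 volumes, CSV tables, 8-bit RGB images.

Volumes round-trip values and per-axis voxel sizes through the NIfTI
affine; tables are validated against required column sets on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "read_volume",
    "write_volume",
    "read_table",
    "write_table",
    "read_image",
    "write_image",
]


class FormatError(ValueError):
    """A file does not conform to the expected format/schema."""


def write_volume(
    path: str | Path,
    values: np.ndarray,
    voxel_size: Sequence[float],
) -> None:
    """Write a 3D volume as NIfTI-1 with a diagonal mm affine."""
    arr = np.asarray(values)
    if arr.ndim != 3:
        raise FormatError(f"expected a 3D volume, got ndim={arr.ndim}")
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    affine = np.diag([*voxel_size, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (values, per-axis voxel size in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI volume, got ndim={data.ndim}")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, voxel_size


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(
    path: str | Path, required_columns: Sequence[str] = ()
) -> pd.DataFrame:
    """Read a CSV table, raising :class:`FormatError` for missing columns."""
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise FormatError(f"table {path} is missing required columns {missing}")
    return df


def write_image(path: str | Path, rgb: np.ndarray) -> None:
    if rgb.dtype != np.uint8:
        raise FormatError(f"images must be 8-bit, got dtype {rgb.dtype}")
    iio.imwrite(str(path), rgb)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (alpha stripped if present)."""
    arr = iio.imread(str(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"expected an RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise FormatError(f"expected an 8-bit image, got dtype {arr.dtype}")
    return arr
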