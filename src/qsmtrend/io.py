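"""NIfTI-1 volume I/O.

Volumes travel as 3-D float32 NIfTI (plain or gzipped) with the voxel
size in the header zooms and the array-axis / B0-axis convention noted
in the header description.  Label volumes use integer dtypes.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeFormatError", "read_volume", "write_volume"]

_DESCRIP = b"qsmtrend: axes (x,y,z), B0 along axis 2"


class VolumeFormatError(ValueError):
    """Input file is not a 3-D NIfTI volume."""


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3-D NIfTI volume; returns (data, voxel_size in mm).

    Float images come back as float32, integer images keep their dtype.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise VolumeFormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    if img.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D volume, got {img.ndim}-D")
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def write_volume(
    data: np.ndarray,
    path: str | Path,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Path:
    """Write a 3-D volume as NIfTI-1 (float32 for floats, native for ints)."""
    path = Path(path)
    arr = np.asarray(data)
    if arr.ndim != 3:
        raise VolumeFormatError(f"can only write 3-D volumes, got {arr.ndim}-D")
    if np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8)
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(voxel_size)
    img.header["descrip"] = _DESCRIP
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path
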