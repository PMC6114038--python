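"""NIfTI volume I/O and small text sidecars (echo times, JSON settings).

Thin wrappers over nibabel that pair every voxel array with its
:class:`GridGeometry` and keep the round trip lossless to float32.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import GridGeometry
from .images import RoiMask


class VolumeFormatError(ValueError):
    """File exists but is not a readable 3-D/4-D volume."""


def _geometry_from_nifti(img: nib.Nifti1Image) -> GridGeometry:
    zooms = img.header.get_zooms()[:3]
    return GridGeometry(shape=tuple(img.shape[:3]),
                        voxel_size=tuple(float(z) for z in zooms),
                        affine=np.asarray(img.affine, dtype=float))


def read_volume(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    """Read a 3-D or 4-D NIfTI volume.

    Returns the voxel array (float unless the on-disk dtype is integer) and
    the grid geometry of the first three axes. A 4th (echo/frame) axis is
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises ImageFileError and friends
        raise VolumeFormatError(f"not a readable NIfTI volume: {path} ({exc})") from exc
    if img.ndim < 3 or img.ndim > 4:
        raise VolumeFormatError(
            f"unsupported dimensionality {img.ndim} for {path}; need 3-D or 4-D")
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64)
    return data, _geometry_from_nifti(img)


def write_volume(array: np.ndarray, geometry: GridGeometry, path: str | Path,
                 dtype: np.dtype | type | None = None) -> Path:
    """Write a volume as NIfTI-1; values round-trip to float32 precision.

    Masks should be passed with ``dtype=np.uint8`` so they re-read exactly.
    """
    path = Path(path)
    array = np.asarray(array)
    if array.shape[:3] != geometry.shape:
        raise ValueError(
            f"array shape {array.shape} inconsistent with grid {geometry.shape}")
    if array.ndim not in (3, 4):
        raise ValueError(f"only 3-D/4-D volumes are written, got ndim={array.ndim}")
    if dtype is None:
        dtype = np.uint8 if array.dtype == bool else np.float32
    img = nib.Nifti1Image(array.astype(dtype), geometry.affine)
    img.header.set_zooms(tuple(geometry.voxel_size) + ((1.0,) if array.ndim == 4 else ()))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, path)
    return path


def read_mask(path: str | Path, label: str, week: int | None = None) -> RoiMask:
    """Read a binary ROI mask (0/1 NIfTI volume)."""
    data, geom = read_volume(path)
    if data.ndim != 3:
        raise VolumeFormatError(f"mask must be 3-D: {path}")
    return RoiMask(mask=data > 0, label=label, geometry=geom, week=week)


def write_mask(mask: RoiMask, path: str | Path) -> Path:
    return write_volume(mask.mask.astype(np.uint8), mask.geometry, path, dtype=np.uint8)


def read_echo_times(path: str | Path) -> np.ndarray:
    """Echo times in ms from a JSON list or whitespace-separated text file."""
    path = Path(path)
    text = path.read_text().strip()
    try:
        values = json.loads(text)
        if isinstance(values, dict):
            values = values["echo_times_ms"]
    except json.JSONDecodeError:
        values = [float(tok) for tok in text.split()]
    te = np.asarray(values, dtype=float)
    if te.ndim != 1 or te.size == 0:
        raise ValueError(f"no echo times found in {path}")
    return te


def write_echo_times(echo_times: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"echo_times_ms": [float(t) for t in echo_times]}, indent=1))
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))
    return path
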