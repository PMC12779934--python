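"""Volumetric and tabular I/O.

Grids and masks are stored as NRRD (spacing and origin in the header),
DVH curves as CSV with columns ``dose_Gy, volume_pct``, and metric reports
as JSON.  SimpleITK handles the NRRD codec; this module only adapts between
its ``(z, y, x)`` array order and the package's ``(x, y, z)`` convention.
Only axis-aligned (identity-direction) volumes are supported.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .core import StructureMask, VoxelGrid, VolumeError


class VolumeIOError(VolumeError):
    """Read/write failure or unsupported volume metadata."""


def write_nrrd(path, obj: VoxelGrid | StructureMask) -> Path:
    """Write a grid (float64) or mask (uint8 0/1) to NRRD."""
    path = Path(path)
    if isinstance(obj, StructureMask):
        arr = obj.mask.astype(np.uint8)
    elif isinstance(obj, VoxelGrid):
        if not np.all(np.isfinite(obj.values)):
            raise VolumeIOError("refusing to write non-finite dose values")
        arr = obj.values
    else:
        raise VolumeIOError(f"cannot write object of type {type(obj).__name__}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(obj.spacing))
    img.SetOrigin(tuple(obj.origin))
    sitk.WriteImage(img, str(path), useCompression=False)
    return path


def _read_image(path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps parse errors in RuntimeError
        raise VolumeIOError(f"failed to parse {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeIOError(
            f"{path}: expected a 3D volume, got {img.GetDimension()} dimensions"
        )
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise VolumeIOError(f"{path}: non-axis-aligned volumes are not supported")
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def read_nrrd(path, pad_mm: float | None = None) -> VoxelGrid:
    """Read a scalar volume as a VoxelGrid (values coerced to float64)."""
    arr, spacing, origin = _read_image(path)
    if not np.all(np.isfinite(arr)):
        raise VolumeIOError(f"{path}: volume contains non-finite values")
    return VoxelGrid(arr.astype(np.float64), spacing, origin, pad_mm=pad_mm)


def read_mask(path, name: str | None = None) -> StructureMask:
    """Read a binary (0/1) volume as a StructureMask."""
    arr, spacing, origin = _read_image(path)
    if not np.all(np.isin(arr, (0, 1))):
        raise VolumeIOError(f"{path}: mask values must be 0/1")
    return StructureMask(name or Path(path).stem, arr.astype(bool), spacing, origin)


def write_dvh_csv(path, dvh) -> Path:
    """Write a DVHCurve as ``dose_Gy, volume_pct`` rows."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame({"dose_Gy": dvh.dose_gy, "volume_pct": dvh.volume_pct}).to_csv(
        path, index=False
    )
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json_report(path, obj) -> Path:
    """Serialize a dataclass / dict report (numpy-aware) to JSON."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)
    return path
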