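"""Voxel-grid and structure-mask primitives shared by the whole package.

Conventions
-----------
Arrays are indexed ``(ix, iy, iz)`` with the physical axes ``x = left-right
(LR)``, ``y = anterior-posterior (AP)`` and ``z = superior-inferior (SI/CC)``.
All coordinates, spacings and distances are in millimetres; dose values are
in Gy.  Voxel values live at voxel *centers*; positive z displacement means
motion toward superior.

Two grids are *aligned* iff their shape, spacing and origin match; the
package never resamples between mismatched geometries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


class VolumeError(ValueError):
    """Base error for grid/mask operations."""


class AlignmentError(VolumeError):
    """Grids/masks do not share shape, spacing and origin."""


class PaddingError(VolumeError):
    """Requested shift exceeds the grid's declared padding budget."""


#: Accepted axis identifiers, mapped to array axis index.
AXES = {
    "x": 0, "lr": 0,
    "y": 1, "ap": 1,
    "z": 2, "si": 2, "cc": 2,
    0: 0, 1: 1, 2: 2,
}


def resolve_axis(axis) -> int:
    try:
        return AXES[axis.lower() if isinstance(axis, str) else axis]
    except (KeyError, AttributeError):
        raise VolumeError(f"invalid axis identifier: {axis!r}") from None


@dataclass
class VoxelGrid:
    """A 3D scalar field (dose in Gy, or unitless) on a regular grid.

    Parameters
    ----------
    values
        ``(nx, ny, nz)`` array of finite, non-negative scalars.
    spacing
        Per-axis voxel size in mm, all > 0.
    origin
        Physical position (mm) of the center of voxel (0, 0, 0).
    pad_mm
        Optional padding budget: the largest |displacement| (mm) for which
        ``shift_volume`` along z is considered valid.  ``None`` disables the
        check (used for small scratch grids in tests).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pad_mm: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise VolumeError(f"grid values must be 3D, got {self.values.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise VolumeError("spacing and origin must have three components")
        if any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise VolumeError("grid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis) -> np.ndarray:
        """Physical voxel-center coordinates along one axis."""
        a = resolve_axis(axis)
        return self.origin[a] + self.spacing[a] * np.arange(self.shape[a])

    def copy(self) -> "VoxelGrid":
        return replace(self, values=self.values.copy())


@dataclass
class StructureMask:
    """A named binary region sharing a VoxelGrid geometry."""

    name: str
    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise VolumeError(f"mask must be 3D, got {self.mask.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def volume_mm3(self) -> float:
        """Structure volume = voxel count x voxel volume (exact counting)."""
        return self.voxel_count * self.voxel_volume_mm3

    def copy(self) -> "StructureMask":
        return replace(self, mask=self.mask.copy())


def _geometry(obj) -> tuple:
    return (obj.shape, obj.spacing, obj.origin)


def is_aligned(a, b, atol: float = 1e-9) -> bool:
    sa, spa, oa = _geometry(a)
    sb, spb, ob = _geometry(b)
    return (
        sa == sb
        and np.allclose(spa, spb, atol=atol)
        and np.allclose(oa, ob, atol=atol)
    )


def require_aligned(a, b) -> None:
    if not is_aligned(a, b):
        raise AlignmentError(
            f"geometries differ: {_geometry(a)} vs {_geometry(b)}"
        )


def shift_volume(grid: VoxelGrid, displacement_mm: float, axis="z") -> VoxelGrid:
    """Rigidly translate a scalar field by ``displacement_mm`` along an axis.

    The output value at physical point ``p`` equals the input value at
    ``p - displacement * e_axis``, evaluated by tri-linear interpolation with
    edge-value padding outside the domain.  This is the rigid-translation
    surrogate the package uses in place of deformable dose warping.
    """
    a = resolve_axis(axis)
    d = float(displacement_mm)
    if grid.pad_mm is not None and abs(d) > grid.pad_mm + 1e-9:
        raise PaddingError(
            f"shift of {abs(d):.3f} mm exceeds the grid's padding budget of "
            f"{grid.pad_mm:.3f} mm; pad the grid to at least {abs(d):.1f} mm"
        )
    if d == 0.0:
        return grid.copy()
    shift_idx = [0.0, 0.0, 0.0]
    shift_idx[a] = d / grid.spacing[a]
    out = ndimage.shift(grid.values, shift_idx, order=1, mode="nearest")
    return replace(grid, values=out)


def _distance_to_mask(mask: StructureMask) -> np.ndarray:
    """Euclidean distance (mm) from every voxel center to the nearest
    mask-true voxel center (0 inside the mask)."""
    return ndimage.distance_transform_edt(~mask.mask, sampling=mask.spacing)


def dilate_mask(mask: StructureMask, distance_mm: float) -> StructureMask:
    """Euclidean dilation: true iff a voxel center lies within
    ``distance_mm`` of any input-true voxel center."""
    d = float(distance_mm)
    if d < 0:
        raise VolumeError(f"dilation distance must be >= 0, got {d}")
    if d == 0 or not mask.mask.any():
        return mask.copy()
    out = _distance_to_mask(mask) <= d + 1e-9
    return replace(mask, mask=out)


def shell_mask(mask: StructureMask, inner_mm: float, outer_mm: float) -> StructureMask:
    """Shell between two Euclidean dilations of a structure.

    Returns ``dilate(mask, outer) AND NOT dilate(mask, inner)``; always
    disjoint from the source mask.  A degenerate width smaller than the
    voxel size may yield an empty shell, which is returned without error.
    """
    inner, outer = float(inner_mm), float(outer_mm)
    if not (0 <= inner < outer):
        raise VolumeError(
            f"shell bounds must satisfy 0 <= inner < outer, got ({inner}, {outer})"
        )
    if not mask.mask.any():
        return replace(mask, name=f"{mask.name}_shell", mask=mask.mask.copy())
    dist = _distance_to_mask(mask)
    out = (dist <= outer + 1e-9) & ~(dist <= inner + 1e-9)
    return replace(mask, name=f"{mask.name}_shell_{inner:g}_{outer:g}", mask=out)


def crop_xy(dose: VoxelGrid, mask: StructureMask, margin_voxels: int = 1):
    """Crop a dose grid and mask to the mask's x-y bounding box.

    Motion in this package is purely along z, so accumulation commutes with
    an x-y crop; cropping makes GTV-only amplitude sweeps cheap.
    """
    require_aligned(dose, mask)
    if not mask.mask.any():
        raise VolumeError("cannot crop to an empty mask")
    ix = np.nonzero(mask.mask.any(axis=(1, 2)))[0]
    iy = np.nonzero(mask.mask.any(axis=(0, 2)))[0]
    x0, x1 = max(ix[0] - margin_voxels, 0), min(ix[-1] + margin_voxels + 1, dose.shape[0])
    y0, y1 = max(iy[0] - margin_voxels, 0), min(iy[-1] + margin_voxels + 1, dose.shape[1])
    origin = (
        dose.origin[0] + x0 * dose.spacing[0],
        dose.origin[1] + y0 * dose.spacing[1],
        dose.origin[2],
    )
    sub_dose = VoxelGrid(
        dose.values[x0:x1, y0:y1, :].copy(), dose.spacing, origin, pad_mm=dose.pad_mm
    )
    sub_mask = StructureMask(mask.name, mask.mask[x0:x1, y0:y1, :].copy(), mask.spacing, origin)
    return sub_dose, sub_mask
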