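"""Grid-aware 3D image containers and NIfTI round-tripping.

Everything downstream works on :class:`Volume3D` (the LGE intensities
``I(x)``) and :class:`BinaryMask` (endocardium, wall, scar, region and
artefact labels).  Both carry voxel spacing in millimetres so that all
distances and volumes are physical; combining objects that live on
different grids is an error, never a silent resample.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Tolerance (mm) for spacing equality between grids; NIfTI headers store
#: spacing as float32 so exact comparison is too strict.
GRID_TOL_MM = 1e-4

MASK_ROLES = ("endocardium", "wall", "scar", "region", "artefact")


class GridMismatchError(ValueError):
    """Two objects do not share a voxel grid (shape or spacing)."""


def _as_tuple3(x, name):
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 components, got {len(t)}")
    return t


@dataclass(frozen=True)
class Volume3D:
    """A 3D scalar image with voxel spacing and origin in mm.

    Voxel index ``(i, j, k)`` maps to the physical point
    ``origin + index * spacing``.  The data array is made read-only on
    construction.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
        data = data.copy()
        data.flags.writeable = False
        object.__setattr__(self, "data", data)
        spacing = _as_tuple3(self.spacing, "spacing")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", _as_tuple3(self.origin, "origin"))

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def same_grid(self, other, tol: float = GRID_TOL_MM) -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing)
        )

    def check_same_grid(self, other, tol: float = GRID_TOL_MM) -> None:
        if not self.same_grid(other, tol):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}@{self.spacing} vs "
                f"{other.shape}@{other.spacing}"
            )

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """New volume on this grid with different intensities."""
        return Volume3D(data, self.spacing, self.origin)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean label field on a :class:`Volume3D` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "region"

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
        data = data.astype(bool).copy()
        data.flags.writeable = False
        object.__setattr__(self, "data", data)
        spacing = _as_tuple3(self.spacing, "spacing")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", _as_tuple3(self.origin, "origin"))
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; one of {MASK_ROLES}")

    # grid protocol shared with Volume3D
    shape = Volume3D.shape
    voxel_volume_mm3 = Volume3D.voxel_volume_mm3
    same_grid = Volume3D.same_grid
    check_same_grid = Volume3D.check_same_grid

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * self.voxel_volume_mm3

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / 1000.0

    def with_data(self, data: np.ndarray, role: str | None = None) -> "BinaryMask":
        return BinaryMask(data, self.spacing, self.origin, role or self.role)


def _affine(spacing, origin):
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _load(path):
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:  # common trailing singleton
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, spacing, origin


def read_volume(path) -> Volume3D:
    """Read a 3D NIfTI volume; spacing taken from the file header."""
    data, spacing, origin = _load(path)
    return Volume3D(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(vol: Volume3D, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32),
                          _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path, reference, role: str = "region") -> BinaryMask:
    """Read a mask and check it lives on ``reference``'s grid.

    Any nonzero voxel becomes True.
    """
    data, spacing, origin = _load(path)
    mask = BinaryMask(data != 0, spacing, origin, role)
    reference.check_same_grid(mask)
    return mask


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as unsigned 8-bit {0, 1} NIfTI."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8),
                          _affine(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
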