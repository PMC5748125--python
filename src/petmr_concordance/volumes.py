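"""Volume data model, world-coordinate geometry, resampling and NIfTI I/O.

A volume is an axis-aligned 3D scalar grid. World coordinates follow the
voxel-center convention: the center of voxel ``(i, j, k)`` lies at
``origin + index * spacing`` (mm), with 0-based indices and axes ordered
``(x, y, z)``. Only diagonal (axis-aligned, positive-spacing) NIfTI affines
are supported; the study procedure this package models uses pure rigid
translations, so oblique orientations are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

Modality = Literal["SUV", "ADC", "DWI_B800"]

__all__ = [
    "ImageVolume",
    "LesionMask",
    "TranslationVector",
    "world_coords",
    "world_to_index",
    "nearest_index",
    "apply_translation",
    "resample",
    "read_nifti",
    "write_nifti",
    "voxel_diagonal",
]


class UnsupportedOrientationError(ValueError):
    """Raised for NIfTI affines that are not positive-diagonal."""


def _as_triple(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a length-3 sequence, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {arr}")
    return arr


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image on a regular axis-aligned grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar field. SUV is unitless; ADC is in 1e-6 mm^2/s; DWI is in
        arbitrary units.
    spacing : (3,) float
        Per-axis voxel size in mm; strictly positive.
    origin : (3,) float
        World position (mm) of the *center* of voxel (0, 0, 0).
    modality : {"SUV", "ADC", "DWI_B800"}
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    modality: Modality

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or min(values.shape) < 1:
            raise ValueError(f"values must be a 3D array, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        spacing = _as_triple(self.spacing, "spacing")
        origin = _as_triple(self.origin, "origin")
        if np.any(spacing <= 0):
            raise ValueError(f"spacing must be positive, got {spacing}")
        if self.modality not in ("SUV", "ADC", "DWI_B800"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "ADC" and np.any(values < 0):
            raise ValueError("ADC volumes must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        return replace(self, values=values)


@dataclass(frozen=True)
class LesionMask:
    """Binary VOI aligned to a parent :class:`ImageVolume` grid."""

    mask: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {mask.shape}")
        if not mask.any():
            raise ValueError("mask must contain at least one voxel")
        spacing = _as_triple(self.spacing, "spacing")
        if np.any(spacing <= 0):
            raise ValueError("spacing must be positive")
        origin = _as_triple(self.origin, "origin")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @classmethod
    def from_volume(cls, volume: ImageVolume, mask: np.ndarray) -> "LesionMask":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != volume.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume shape {volume.shape}"
            )
        return cls(mask=mask, spacing=volume.spacing, origin=volume.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass(frozen=True)
class TranslationVector:
    """Rigid translation (mm) mapping MRI world coordinates into the PET frame."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self):
        if not all(np.isfinite([self.dx, self.dy, self.dz])):
            raise ValueError("translation components must be finite")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz], dtype=float)

    def __neg__(self) -> "TranslationVector":
        return TranslationVector(-self.dx, -self.dy, -self.dz)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.as_array))


def world_coords(volume, index: Sequence[int]) -> np.ndarray:
    """World coordinates (mm) of the center of the voxel at ``index``.

    Works for :class:`ImageVolume` and :class:`LesionMask` alike.
    """
    idx = np.asarray(index)
    shape = volume.shape
    if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
        raise IndexError(f"index {tuple(idx)} out of bounds for shape {shape}")
    return volume.origin + idx * volume.spacing


def world_to_index(volume, point: Sequence[float]) -> np.ndarray:
    """Continuous (fractional) voxel index of a world point."""
    p = _as_triple(point, "point")
    return (p - volume.origin) / volume.spacing


def nearest_index(volume, point: Sequence[float]) -> tuple[int, int, int]:
    """Nearest in-bounds voxel index for a world point."""
    frac = world_to_index(volume, point)
    idx = np.clip(np.round(frac).astype(int), 0, np.asarray(volume.shape) - 1)
    return tuple(int(i) for i in idx)


def apply_translation(point: Sequence[float], t: TranslationVector) -> np.ndarray:
    """Map a point from the MRI world frame into the PET world frame."""
    return _as_triple(point, "point") + t.as_array


def voxel_diagonal(volume) -> float:
    """Length (mm) of a voxel's space diagonal."""
    return float(np.linalg.norm(volume.spacing))


def resample(
    volume: ImageVolume,
    target_spacing: Sequence[float],
    target_shape: Sequence[int],
    method: Literal["trilinear", "nearest"] = "trilinear",
    target_origin: Sequence[float] | None = None,
) -> ImageVolume:
    """Resample a volume onto a new axis-aligned grid.

    ``trilinear`` is used for intensities and ``nearest`` for masks. Target
    voxels outside the source extent are filled with 0 (air/lung background).
    """
    spacing = _as_triple(target_spacing, "target_spacing")
    if np.any(spacing <= 0):
        raise ValueError(f"target spacing must be positive, got {spacing}")
    shape = np.asarray(target_shape, dtype=int)
    if shape.shape != (3,) or np.any(shape < 1):
        raise ValueError(f"target shape must be 3 positive ints, got {target_shape}")
    origin = (
        volume.origin if target_origin is None else _as_triple(target_origin, "target_origin")
    )
    if method not in ("trilinear", "nearest"):
        raise ValueError(f"unknown method {method!r}")

    # identity resample: same grid in, same values out, exactly
    if (
        tuple(shape) == volume.shape
        and np.array_equal(spacing, volume.spacing)
        and np.array_equal(origin, volume.origin)
    ):
        return volume.with_values(volume.values.copy())

    # target voxel centers expressed as fractional indices into the source grid
    axes = [
        (origin[a] + np.arange(shape[a]) * spacing[a] - volume.origin[a])
        / volume.spacing[a]
        for a in range(3)
    ]
    ix, iy, iz = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([ix, iy, iz])
    order = 1 if method == "trilinear" else 0
    out = ndimage.map_coordinates(
        volume.values, coords, order=order, mode="constant", cval=0.0
    )
    if volume.modality == "ADC":
        out = np.clip(out, 0.0, None)
    return ImageVolume(values=out, spacing=spacing, origin=origin, modality=volume.modality)


def write_nifti(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine (float32 storage)."""
    affine = np.diag([*volume.spacing, 1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    img.header.set_xyzt_units("mm")
    img.header["descrip"] = volume.modality.encode()
    nib.save(img, str(path))


def read_nifti(path: str | Path, modality: Modality | None = None) -> ImageVolume:
    """Read an axis-aligned NIfTI volume.

    The affine must be positive-diagonal (no rotation/shear); anything else
    raises :class:`UnsupportedOrientationError`. The modality is taken from
    the ``descrip`` header field unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=float)
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.any(np.abs(off_diag) > 1e-5 * max(1.0, np.abs(rot).max())):
        raise UnsupportedOrientationError(
            f"{path}: only axis-aligned (diagonal-affine) volumes are supported"
        )
    if np.any(np.diag(rot) <= 0):
        raise UnsupportedOrientationError(
            f"{path}: negative/zero affine diagonal (flipped axes) not supported"
        )
    if modality is None:
        descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="replace")
        modality = descrip if descrip in ("SUV", "ADC", "DWI_B800") else "SUV"
    values = np.asanyarray(img.dataobj, dtype=np.float64)
    if values.ndim == 4 and values.shape[3] == 1:
        values = values[..., 0]
    if modality == "ADC":
        values = np.clip(values, 0.0, None)  # float32 round-off can dip below 0
    return ImageVolume(
        values=values,
        spacing=np.diag(rot),
        origin=affine[:3, 3],
        modality=modality,
    )
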