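"""Extremum localization, inter-extremum distance, match classification and
1 cm^3-sphere cross-parameter statistics.

The central quantity is the world-frame distance between the hottest PET
voxel (SUV_max) and the lowest ADC voxel (ADC_min) of a lesion after rigid
coregistration. A lesion is a spatial *match* when that distance does not
exceed the registration-accuracy threshold (12 mm for the study conditions
this package models) and a *mismatch* otherwise. Cross-parameter readouts
(ADC at/around the SUV_max position and vice versa) are computed over a
sphere of volume 1 cm^3 (radius 6.2035 mm) restricted to the lesion VOI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

from .volumes import (
    ImageVolume,
    LesionMask,
    TranslationVector,
    apply_translation,
    nearest_index,
    world_coords,
)

__all__ = [
    "ExtremumLocus",
    "SphereStats",
    "LesionRecord",
    "locate_extremum",
    "extrema_distance",
    "classify_match",
    "sphere_radius_mm",
    "sphere_stats",
    "lesion_report",
]


@dataclass(frozen=True)
class ExtremumLocus:
    """Location and value of a masked extremum (SUV_max or ADC_min)."""

    index: tuple[int, int, int]
    world: np.ndarray          # mm, native frame of the volume
    value: float
    tie_count: int


@dataclass(frozen=True)
class SphereStats:
    """Statistics of a volume over a sphere-in-VOI neighborhood."""

    value_at_center: float
    min_in_sphere: float
    max_in_sphere: float
    mean_in_sphere: float
    n_voxels: int
    radius_mm: float
    fallback_nearest: bool = False  # empty sphere/VOI intersection fallback


@dataclass
class LesionRecord:
    """All per-lesion outcome parameters (one row per lesion and reader)."""

    lesion_id: int | str
    reader_id: int | str
    suv_max: float
    suv_mean: float
    v_pet_cm3: float
    diameter_mm: float
    adc_min: float
    adc_mean: float
    v_mri_cm3: float
    adc_at_suvmax: float
    adc_min_at_suvmax: float
    adc_mean_at_suvmax: float
    suv_at_adcmin: float
    suv_max_at_adcmin: float
    suv_mean_at_adcmin: float
    distance_mm: float        # inter-extremum distance D
    match: bool
    threshold_mm: float
    adc_outliers_removed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def locate_extremum(
    volume: ImageVolume, mask: LesionMask, kind: Literal["max", "min"]
) -> ExtremumLocus:
    """Masked extremum voxel; ties broken toward the lowest linear index
    (x fastest), with the tie count recorded."""
    if kind not in ("max", "min"):
        raise ValueError(f"kind must be 'max' or 'min', got {kind!r}")
    if mask.shape != volume.shape:
        raise ValueError("mask and volume grids differ")
    vals = volume.values[mask.mask]
    if vals.size == 0:
        raise ValueError("mask is empty")
    ext = vals.max() if kind == "max" else vals.min()
    where = np.argwhere(mask.mask & (volume.values == ext))
    # lowest linearized index with x fastest <=> lexicographic (z, y, x)
    order = np.lexsort((where[:, 0], where[:, 1], where[:, 2]))
    idx = tuple(int(i) for i in where[order[0]])
    return ExtremumLocus(
        index=idx,
        world=world_coords(volume, idx),
        value=float(ext),
        tie_count=int(len(where)),
    )


def extrema_distance(
    pet_locus: ExtremumLocus, mri_locus: ExtremumLocus, t: TranslationVector
) -> float:
    """World-frame distance (mm) between the SUV_max voxel (PET frame) and
    the ADC_min voxel (MRI frame) after applying the MRI->PET translation."""
    return float(
        np.linalg.norm(pet_locus.world - apply_translation(mri_locus.world, t))
    )


def classify_match(distance: float, threshold: float) -> str:
    """'match' iff distance <= threshold (boundary inclusive), else 'mismatch'."""
    if distance < 0 or threshold <= 0:
        raise ValueError("distance must be >= 0 and threshold > 0")
    return "match" if distance <= threshold else "mismatch"


def sphere_radius_mm(volume_cm3: float = 1.0) -> float:
    """Radius (mm) of a sphere of the given volume; 6.2035 mm for 1 cm^3."""
    if volume_cm3 <= 0:
        raise ValueError("sphere volume must be positive")
    return float((3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def sphere_stats(
    volume: ImageVolume,
    mask: LesionMask,
    center,
    sphere_volume_cm3: float = 1.0,
) -> SphereStats:
    """Min/max/mean of the volume over voxels within a sphere around
    ``center`` (world mm) AND inside the lesion mask.

    Restricting the sphere to the VOI keeps background and rim voxels out of
    the cross-parameter statistics. If the sphere/VOI intersection is empty
    the single nearest in-mask voxel is used, with a warning.
    """
    center = np.asarray(center, dtype=float)
    frac = (center - volume.origin) / volume.spacing
    if np.any(frac < -0.5) or np.any(frac > np.asarray(volume.shape) - 0.5):
        raise ValueError(f"center {center} lies outside the volume extent")
    radius = sphere_radius_mm(sphere_volume_cm3)

    # search only the bounding box of the sphere
    lo = np.maximum(np.floor(frac - radius / volume.spacing).astype(int), 0)
    hi = np.minimum(
        np.ceil(frac + radius / volume.spacing).astype(int) + 1, volume.shape
    )
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    grids = np.ogrid[box]
    d2 = sum(
        ((g * sp + o) - c) ** 2
        for g, sp, o, c in zip(grids, volume.spacing, volume.origin, center)
    )
    sel = (d2 <= radius**2) & mask.mask[box]
    fallback = False
    if not sel.any():
        warnings.warn("sphere/VOI intersection empty; using nearest in-mask voxel")
        idx = np.argwhere(mask.mask)
        pts = mask.origin + idx * mask.spacing
        nearest = idx[np.argmin(np.sum((pts - center) ** 2, axis=1))]
        vals = np.array([volume.values[tuple(nearest)]])
        fallback = True
    else:
        vals = volume.values[box][sel]

    cidx = nearest_index(volume, center)
    return SphereStats(
        value_at_center=float(volume.values[cidx]),
        min_in_sphere=float(vals.min()),
        max_in_sphere=float(vals.max()),
        mean_in_sphere=float(vals.mean()),
        n_voxels=int(vals.size),
        radius_mm=radius,
        fallback_nearest=fallback,
    )


def lesion_report(
    suv: ImageVolume,
    adc: ImageVolume,
    pet_mask: LesionMask,
    adc_mask: LesionMask,
    translation: TranslationVector,
    threshold_mm: float,
    sphere_volume_cm3: float = 1.0,
    lesion_id: int | str = 0,
    reader_id: int | str = 1,
    adc_outliers_removed: int = 0,
) -> LesionRecord:
    """Populate the full per-lesion record.

    Cross-modal lookups convert world coordinates with the MRI->PET
    translation and sample the nearest voxel in the target grid (values are
    reported per voxel, not interpolated).
    """
    from .segmentation import max_diameter, tumor_volume

    suv_locus = locate_extremum(suv, pet_mask, "max")
    adc_locus = locate_extremum(adc, adc_mask, "min")

    distance = extrema_distance(suv_locus, adc_locus, translation)
    match = classify_match(distance, threshold_mm) == "match"

    # SUV_max position expressed in the MRI frame; ADC readouts around it
    p_suvmax_mri = suv_locus.world - translation.as_array
    adc_sphere = sphere_stats(adc, adc_mask, p_suvmax_mri, sphere_volume_cm3)
    # ADC_min position expressed in the PET frame; SUV readouts around it
    p_adcmin_pet = apply_translation(adc_locus.world, translation)
    suv_sphere = sphere_stats(suv, pet_mask, p_adcmin_pet, sphere_volume_cm3)

    return LesionRecord(
        lesion_id=lesion_id,
        reader_id=reader_id,
        suv_max=suv_locus.value,
        suv_mean=float(suv.values[pet_mask.mask].mean()),
        v_pet_cm3=tumor_volume(pet_mask),
        diameter_mm=max_diameter(pet_mask),
        adc_min=adc_locus.value,
        adc_mean=float(adc.values[adc_mask.mask].mean()),
        v_mri_cm3=tumor_volume(adc_mask),
        adc_at_suvmax=adc_sphere.value_at_center,
        adc_min_at_suvmax=adc_sphere.min_in_sphere,
        adc_mean_at_suvmax=adc_sphere.mean_in_sphere,
        suv_at_adcmin=suv_sphere.value_at_center,
        suv_max_at_adcmin=suv_sphere.max_in_sphere,
        suv_mean_at_adcmin=suv_sphere.mean_in_sphere,
        distance_mm=distance,
        match=match,
        threshold_mm=float(threshold_mm),
        adc_outliers_removed=adc_outliers_removed,
    )
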