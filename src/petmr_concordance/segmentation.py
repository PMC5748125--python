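"""Lesion delineation: adaptive-threshold PET VOI, DWI->ADC mask transfer,
histogram-based ADC ROI refinement, and mask-derived volume/diameter metrics.

The PET VOI grower is an iterative source-to-background adaptive threshold:
the cutoff is ``background + beta * (peak - background)`` with the
background estimated in a shell around the current mask, iterated until the
mask stabilizes. The exact threshold parameters of clinical workstations
vary; ``beta`` (default 0.41) and the shell width are exposed in the config
rather than asserted as any particular vendor's values.

The ADC refinement automates the manual "remove low-value outliers from the
ROI histogram" step: contaminating near-zero voxels (aerated lung at the
lesion rim) are separated from the tumor-tissue distribution by the widest
run of empty histogram bins below the mode; everything below that gap is
dropped. A percentile floor is the fallback when no gap exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .volumes import ImageVolume, LesionMask, nearest_index, resample

__all__ = [
    "AdaptiveThresholdConfig",
    "HistogramRefineConfig",
    "SegmentationError",
    "segment_pet_voi",
    "segment_dwi_lesion",
    "transfer_mask",
    "refine_adc_roi",
    "tumor_volume",
    "max_diameter",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


class SegmentationError(RuntimeError):
    """Raised when a VOI cannot be segmented (e.g. seed in background)."""


@dataclass
class AdaptiveThresholdConfig:
    """Parameters of the iterative adaptive-threshold PET segmentation."""

    beta: float = 0.41            # threshold fraction between background and peak
    shell_width_mm: float = 10.0  # background-estimation shell around the mask
    seed_radius_mm: float = 10.0  # neighborhood used for the initial peak estimate
    max_iterations: int = 25

    def __post_init__(self):
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must be in (0, 1)")
        if self.shell_width_mm <= 0:
            raise ValueError("shell width must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class HistogramRefineConfig:
    """Parameters of the low-ADC-outlier histogram refinement."""

    bin_width: float = 50.0   # 1e-6 mm^2/s
    p_low: float = 0.01       # fallback percentile floor when no empty-bin gap exists
    min_gap_bins: int = 2     # gaps narrower than this are sampling noise, not outliers

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if not 0.0 <= self.p_low < 0.5:
            raise ValueError("p_low must be in [0, 0.5)")
        if self.min_gap_bins < 1:
            raise ValueError("min_gap_bins must be >= 1")


def _dilate_mm(mask: np.ndarray, spacing, width_mm: float) -> np.ndarray:
    iters = max(1, int(np.ceil(width_mm / float(np.min(spacing)))))
    return ndimage.binary_dilation(mask, structure=_STRUCT26, iterations=iters)


def _ball_mask(shape, spacing, center_idx, radius_mm) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) * sp) ** 2 for g, c, sp in zip(grids, center_idx, spacing))
    return r2 <= radius_mm**2


def _seed_component(above: np.ndarray, seed_idx) -> np.ndarray:
    labels, _ = ndimage.label(above, structure=_STRUCT26)
    lab = labels[seed_idx]
    if lab == 0:
        return np.zeros_like(above)
    return labels == lab


def segment_pet_voi(
    suv: ImageVolume,
    seed_point,
    cfg: AdaptiveThresholdConfig | None = None,
) -> LesionMask:
    """Grow a PET VOI around ``seed_point`` (world mm) by adaptive thresholding.

    Iterates ``T_{k+1} = bg_k + beta * (peak_k - bg_k)`` where ``peak_k`` is
    the mask maximum and ``bg_k`` the mean SUV in a shell around the mask,
    taking at each step the 26-connected component of supra-threshold voxels
    that contains the seed. Stops when the mask stabilizes (a ``converged``
    attribute is set on the returned mask; non-convergence returns the last
    mask with a warning).
    """
    cfg = cfg or AdaptiveThresholdConfig()
    seed_idx = nearest_index(suv, seed_point)
    vals = suv.values

    # initial peak from a ball around the seed; initial background from the
    # far field (low quantile of the whole volume, i.e. lung/air), so the
    # first isocontour is not anchored to tissue adjacent to the seed
    seed_ball = _ball_mask(suv.shape, suv.spacing, seed_idx, cfg.seed_radius_mm)
    peak = float(vals[seed_ball].max())
    bg = float(np.quantile(vals, 0.25))  # far field: lung/air
    if vals[seed_idx] <= bg:
        raise SegmentationError(
            f"seed SUV {vals[seed_idx]:.3g} is not above background {bg:.3g}"
        )

    mask = None
    converged = False
    for _ in range(cfg.max_iterations):
        threshold = bg + cfg.beta * (peak - bg)
        new_mask = _seed_component(vals >= threshold, seed_idx)
        if not new_mask.any():
            raise SegmentationError("adaptive threshold excluded the seed voxel")
        if mask is not None and np.array_equal(new_mask, mask):
            converged = True
            break
        mask = new_mask
        peak = float(vals[mask].max())
        shell = _dilate_mm(mask, suv.spacing, cfg.shell_width_mm) & ~mask
        if shell.any():
            # median, not mean: the shell can clip adjacent non-background
            # tissue, which would otherwise drag the threshold upward
            bg = float(np.median(vals[shell]))
    if not converged:
        warnings.warn("adaptive threshold did not converge; returning last mask")
    out = LesionMask.from_volume(suv, mask)
    object.__setattr__(out, "converged", converged)
    return out


def segment_dwi_lesion(dwi: ImageVolume, seed_point, box_halfwidth_mm: float = 60.0) -> LesionMask:
    """Delineate the lesion on the b=800 volume by Otsu thresholding.

    Stands in for manual 2D ROI stacks: Otsu's threshold inside a bounding
    box around the seed, then the 26-connected component containing the
    seed. Ties in the Otsu cut go to the larger foreground (``>=``).
    """
    from skimage.filters import threshold_otsu

    seed_idx = nearest_index(dwi, seed_point)
    lo = [max(0, seed_idx[a] - int(np.ceil(box_halfwidth_mm / dwi.spacing[a]))) for a in range(3)]
    hi = [
        min(dwi.shape[a], seed_idx[a] + int(np.ceil(box_halfwidth_mm / dwi.spacing[a])) + 1)
        for a in range(3)
    ]
    box = tuple(slice(lo[a], hi[a]) for a in range(3))
    thr = threshold_otsu(dwi.values[box])
    above = np.zeros(dwi.shape, dtype=bool)
    above[box] = dwi.values[box] >= thr
    comp = _seed_component(above, seed_idx)
    if not comp.any():
        raise SegmentationError("Otsu delineation produced no component at the seed")
    return LesionMask.from_volume(dwi, comp)


def transfer_mask(dwi_mask: LesionMask, adc: ImageVolume) -> LesionMask:
    """Copy a DWI-drawn lesion mask onto the ADC map.

    Identity copy when the grids match (the usual case: ADC is computed on
    the DWI grid); nearest-neighbor resample otherwise.
    """
    if dwi_mask.same_grid(adc):
        return LesionMask.from_volume(adc, dwi_mask.mask)
    src = ImageVolume(
        dwi_mask.mask.astype(float), dwi_mask.spacing, dwi_mask.origin, "DWI_B800"
    )
    res = resample(src, adc.spacing, adc.shape, method="nearest", target_origin=adc.origin)
    out = res.values > 0.5
    if not out.any():
        raise SegmentationError("mask transfer produced an empty mask")
    return LesionMask.from_volume(adc, out)


def _gap_cutoff(values: np.ndarray, bin_width: float, min_gap_bins: int = 1) -> float | None:
    """Upper edge of the widest run of empty bins below the histogram mode.

    Bins are aligned to zero. Returns None when no empty bin lies between
    occupied bins below the mode (i.e. no low-outlier gap).
    """
    first = int(np.floor(values.min() / bin_width))
    last = int(np.floor(values.max() / bin_width))
    edges = np.arange(first, last + 2) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    mode_bin = int(np.argmax(counts))  # ties -> lowest bin
    best_len, best_end = 0, None
    run_len = 0
    for b in range(mode_bin):
        if counts[b] == 0:
            run_len += 1
            # only a gap if wide enough and preceded by an occupied (outlier) bin
            if (
                run_len > best_len
                and run_len >= min_gap_bins
                and np.any(counts[: b - run_len + 1] > 0)
            ):
                best_len, best_end = run_len, b + 1
        else:
            run_len = 0
    if best_end is None:
        return None
    return float(edges[best_end])


def refine_adc_roi(
    adc: ImageVolume,
    mask: LesionMask,
    cfg: HistogramRefineConfig | None = None,
) -> tuple[LesionMask, int]:
    """Drop low-ADC outlier voxels from the ROI via histogram-gap analysis.

    Removes only voxels strictly below the computed cutoff; the histogram
    mode always survives. Returns the refined mask and the number of voxels
    removed.
    """
    cfg = cfg or HistogramRefineConfig()
    vals = adc.values[mask.mask]
    if vals.size == 0:
        raise SegmentationError("refine_adc_roi requires a nonempty mask")

    cutoff = _gap_cutoff(vals, cfg.bin_width, cfg.min_gap_bins)
    if cutoff is None:
        cutoff = float(np.quantile(vals, cfg.p_low)) if cfg.p_low > 0 else -np.inf
    # never remove the mode: cap the cutoff at the mode bin's lower edge
    first = int(np.floor(vals.min() / cfg.bin_width))
    last = int(np.floor(vals.max() / cfg.bin_width))
    edges = np.arange(first, last + 2) * cfg.bin_width
    counts, _ = np.histogram(vals, bins=edges)
    mode_lower_edge = float(edges[int(np.argmax(counts))])
    cutoff = min(cutoff, mode_lower_edge)

    keep = mask.mask & ~(adc.values < cutoff)
    removed = int(mask.mask.sum() - keep.sum())
    if not keep.any():
        raise SegmentationError("refinement would empty the mask")
    return LesionMask(keep, mask.spacing, mask.origin), removed


def tumor_volume(mask: LesionMask) -> float:
    """Mask volume in cm^3 (voxel count x voxel volume)."""
    return float(mask.n_voxels * np.prod(mask.spacing) / 1000.0)


def max_diameter(mask: LesionMask) -> float:
    """Maximum 3D diameter (mm): largest pairwise distance between voxel centers.

    Exact: computed over convex-hull vertices (all points for small or
    degenerate masks).
    """
    idx = np.argwhere(mask.mask)
    pts = mask.origin + idx * mask.spacing
    if len(pts) == 1:
        return 0.0
    if len(pts) > 500:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # coplanar/collinear: fall through to brute force
    return float(pdist(pts).max())
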