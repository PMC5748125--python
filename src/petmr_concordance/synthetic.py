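"""Synthetic paired SUV/ADC/DWI lung-lesion phantoms with known ground truth.

Each phantom is an ellipsoidal lesion on a near-zero background, carrying a
hypermetabolic SUV focus (Gaussian bump at ``p_S``) and a low-ADC,
high-cellularity focus (Gaussian trough at ``p_A``) at a controllable
spatial offset. The ADC/DWI volumes live in an MRI frame displaced from the
PET frame by a known rigid translation; "readers" are emulated as noisy
copies of that translation. A fraction of boundary-adjacent ADC voxels is
set to near-zero values to mimic aerated-lung contamination of the lesion
rim, which is what the histogram refinement step has to remove.

Cohorts additionally draw lesion-level SUV amplitude and minimum-ADC level
from a bivariate normal with a configurable correlation, so the cohort-level
SUV_max vs ADC_min coupling is a known generating parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .volumes import ImageVolume, TranslationVector

__all__ = [
    "PET_SPACING",
    "MRI_SPACING",
    "SyntheticLesionSpec",
    "LesionTruth",
    "CohortScenario",
    "make_lesion_pair",
    "make_cohort",
]

# clinical voxel geometries: PET OSEM grid and b=800 ss-EPI / ADC grid
PET_SPACING = (5.0, 5.0, 3.27)
MRI_SPACING = (2.6, 2.6, 5.0)

RIM_OUTLIER_MAX_ADC = 100.0  # 1e-6 mm^2/s; "near-zero" aerated-lung values


@dataclass
class SyntheticLesionSpec:
    """Generating parameters for a single paired SUV/ADC/DWI phantom.

    Positions are world coordinates (mm) in the PET frame. ADC values are in
    1e-6 mm^2/s; SUV is unitless.
    """

    semi_axes: tuple[float, float, float] = (25.0, 20.0, 15.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    suv_background: float = 6.0        # baseline uptake inside the lesion
    suv_amplitude: float = 5.0         # focal excess; peak SUV = background + amplitude
    suv_focus: tuple[float, float, float] | None = None   # p_S; default: lesion center
    suv_focus_width: float | None = None                  # Gaussian sigma (mm)
    adc_plateau: float = 1400.0
    adc_depth: float = 900.0           # trough depth; ADC_min = plateau - depth
    adc_trough: tuple[float, float, float] | None = None  # p_A; default: lesion center
    adc_trough_width: float | None = None
    suv_lung: float = 0.2              # background uptake outside the lesion
    adc_outside: float = 150.0         # noisy aerated-lung ADC outside the lesion
    dwi_lesion: float = 100.0
    dwi_outside: float = 5.0
    rim_outlier_fraction: float = 0.1  # fraction of boundary ADC voxels set near zero
    noise_sd_suv: float = 0.3
    noise_sd_adc: float = 50.0
    noise_sd_dwi: float = 3.0
    translation: TranslationVector = field(
        default_factory=lambda: TranslationVector(8.0, -5.0, 4.0)
    )
    reader_noise_sd: float = 2.66      # per-axis sd (mm) of reader translation error
    reader_noise_scale_sigma: float = 0.36  # per-case lognormal spread of that sd
    n_readers: int = 2
    margin: float = 15.0               # grid padding around the ellipsoid (mm)
    seed: int | tuple = 0

    def __post_init__(self):
        axes = np.asarray(self.semi_axes, dtype=float)
        if np.any(axes <= 0):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")
        if self.suv_focus is None:
            self.suv_focus = tuple(self.center)
        if self.adc_trough is None:
            self.adc_trough = tuple(self.center)
        if self.suv_focus_width is None:
            self.suv_focus_width = float(axes.min()) / 3.0
        if self.adc_trough_width is None:
            self.adc_trough_width = float(axes.min()) / 3.0
        if not 0.0 <= self.rim_outlier_fraction <= 1.0:
            raise ValueError("rim_outlier_fraction must be in [0, 1]")
        if self.adc_depth < 0 or self.adc_plateau - self.adc_depth < 0:
            raise ValueError("ADC trough must stay non-negative (plateau >= depth >= 0)")
        for name, p in (("suv_focus", self.suv_focus), ("adc_trough", self.adc_trough)):
            if self._ellipsoid_coord(p) > 1.0:
                raise ValueError(f"{name} {p} lies outside the ellipsoid")

    def _ellipsoid_coord(self, point) -> float:
        d = (np.asarray(point, float) - np.asarray(self.center, float)) / np.asarray(
            self.semi_axes, float
        )
        return float(np.sum(d * d))


@dataclass(frozen=True)
class LesionTruth:
    """Ground truth of one phantom, in the PET world frame."""

    p_suv: np.ndarray            # true SUV focus position (mm)
    p_adc: np.ndarray            # true ADC trough position (mm)
    offset_mm: float             # |p_suv - p_adc|
    volume_cm3: float            # analytic ellipsoid volume
    translation: TranslationVector          # true MRI->PET translation
    reader_translations: tuple[TranslationVector, ...]

    def __post_init__(self):
        d = float(np.linalg.norm(np.asarray(self.p_suv) - np.asarray(self.p_adc)))
        if not np.isclose(d, self.offset_mm, atol=1e-9):
            raise ValueError("offset_mm must equal |p_suv - p_adc|")


@dataclass
class CohortScenario:
    """Generating parameters for a whole phantom cohort.

    ``coupling`` is the target Pearson correlation between the lesion-level
    SUV amplitude and the lesion-level minimum-ADC level, i.e. (up to
    clipping) the correlation the pipeline should recover between SUV_max
    and ADC_min. ``offset_range`` bounds the true inter-focus distance;
    with ``size_dependent_offset`` the upper bound additionally scales with
    the lesion diameter, so only large tumors can mismatch.
    """

    n_lesions: int = 25
    diameter_mean: float = 50.0        # mm; lognormal, matching a ~50 +/- 30 mm cohort
    diameter_sd: float = 25.0
    diameter_range: tuple[float, float] = (18.0, 110.0)
    offset_range: tuple[float, float] = (0.0, 30.0)
    size_dependent_offset: bool = True
    offset_diameter_fraction: float = 0.3  # size-dependent cap: offset <= frac * diameter
    coupling: float = -0.5             # target corr(SUV amplitude, ADC_min level)
    suv_amplitude_mean: float = 5.0
    suv_amplitude_sd: float = 2.0
    adc_min_mean: float = 550.0        # 1e-6 mm^2/s, trough floor level
    adc_min_sd: float = 200.0
    translation_sd: float = 6.0        # per-axis sd of the true MRI->PET translation
    reader_noise_sd: float = 2.66
    reader_noise_scale_sigma: float = 0.36
    n_readers: int = 2
    noise_sd_suv: float = 0.3
    noise_sd_adc: float = 50.0
    rim_outlier_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        if not -1.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [-1, 1]")


def _grid(center: np.ndarray, semi_axes: np.ndarray, spacing, margin: float):
    """Axis-aligned grid covering the ellipsoid plus a margin."""
    spacing = np.asarray(spacing, float)
    extent = semi_axes + margin
    shape = np.ceil(2 * extent / spacing).astype(int) + 1
    origin = center - (shape - 1) * spacing / 2.0
    return origin, tuple(int(n) for n in shape)


def _coords(origin: np.ndarray, shape, spacing) -> list[np.ndarray]:
    """World-coordinate meshgrid (sparse) of voxel centers."""
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _gaussian(coords, center, sigma) -> np.ndarray:
    r2 = sum((c - mu) ** 2 for c, mu in zip(coords, center))
    return np.exp(-r2 / (2.0 * sigma**2))


def make_lesion_pair(
    spec: SyntheticLesionSpec,
) -> tuple[ImageVolume, ImageVolume, ImageVolume, LesionTruth]:
    """Generate one paired phantom: (SUV on PET grid, ADC, DWI on MRI grid, truth).

    The ADC/DWI grids live in the MRI frame: a point at MRI world
    coordinates ``p`` corresponds to the physical point ``p + translation``
    in the PET frame. Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    center = np.asarray(spec.center, float)
    semi = np.asarray(spec.semi_axes, float)
    t = spec.translation.as_array

    # --- SUV on the PET grid (PET frame) ---
    pet_origin, pet_shape = _grid(center, semi, PET_SPACING, spec.margin)
    cx = _coords(pet_origin, pet_shape, PET_SPACING)
    inside_pet = sum(((c - mu) / a) ** 2 for c, mu, a in zip(cx, center, semi)) <= 1.0
    suv = np.full(pet_shape, spec.suv_lung, dtype=float)
    bump = spec.suv_background - spec.suv_lung + spec.suv_amplitude * _gaussian(
        cx, spec.suv_focus, spec.suv_focus_width
    )
    suv = np.where(inside_pet, spec.suv_lung + bump, suv)
    if spec.noise_sd_suv > 0:
        suv = suv + rng.normal(0.0, spec.noise_sd_suv, pet_shape)
    suv = np.clip(suv, 0.0, None)

    # --- ADC / DWI on the MRI grid (MRI frame = PET frame shifted by -t) ---
    mri_center = center - t
    mri_origin, mri_shape = _grid(mri_center, semi, MRI_SPACING, spec.margin)
    cm = _coords(mri_origin, mri_shape, MRI_SPACING)
    phys = [c + ti for c, ti in zip(cm, t)]  # PET-frame coordinates of MRI voxels
    inside_mri = sum(((c - mu) / a) ** 2 for c, mu, a in zip(phys, center, semi)) <= 1.0

    trough = spec.adc_plateau - spec.adc_depth * _gaussian(
        phys, spec.adc_trough, spec.adc_trough_width
    )
    adc = np.where(inside_mri, trough, spec.adc_outside)
    if spec.noise_sd_adc > 0:
        adc = adc + rng.normal(0.0, spec.noise_sd_adc, mri_shape)

    dwi = np.where(inside_mri, spec.dwi_lesion, spec.dwi_outside)
    if spec.noise_sd_dwi > 0:
        dwi = dwi + rng.normal(0.0, spec.noise_sd_dwi, mri_shape)
    dwi = np.clip(dwi, 0.0, None)

    # rim outliers: boundary shell of the lesion gets near-zero ADC voxels
    if spec.rim_outlier_fraction > 0:
        from scipy import ndimage

        shell = inside_mri & ~ndimage.binary_erosion(inside_mri)
        shell_idx = np.flatnonzero(shell)
        n_out = int(round(spec.rim_outlier_fraction * shell_idx.size))
        if n_out > 0:
            chosen = rng.choice(shell_idx, size=n_out, replace=False)
            flat = adc.reshape(-1)
            flat[chosen] = rng.uniform(0.0, RIM_OUTLIER_MAX_ADC, size=n_out)
            adc = flat.reshape(mri_shape)
    adc = np.clip(adc, 0.0, None)

    # per-case error magnitude varies lognormally: with per-axis sd 2.66 mm
    # and sigma 0.36 the inter-reader difference norms have mean ~6 mm and
    # sd ~3.5 mm, the registration accuracy the analysis assumes
    sig = spec.reader_noise_scale_sigma
    case_scale = rng.lognormal(-(sig**2) / 2.0, sig) if sig > 0 else 1.0
    readers = tuple(
        TranslationVector(*(t + rng.normal(0.0, spec.reader_noise_sd * case_scale, 3)))
        for _ in range(spec.n_readers)
    )
    truth = LesionTruth(
        p_suv=np.asarray(spec.suv_focus, float),
        p_adc=np.asarray(spec.adc_trough, float),
        offset_mm=float(
            np.linalg.norm(np.asarray(spec.suv_focus) - np.asarray(spec.adc_trough))
        ),
        volume_cm3=float(4.0 / 3.0 * np.pi * np.prod(semi) / 1000.0),
        translation=spec.translation,
        reader_translations=readers,
    )
    suv_vol = ImageVolume(suv, PET_SPACING, pet_origin, "SUV")
    adc_vol = ImageVolume(adc, MRI_SPACING, mri_origin, "ADC")
    dwi_vol = ImageVolume(dwi, MRI_SPACING, mri_origin, "DWI_B800")
    return suv_vol, adc_vol, dwi_vol, truth


def _truncated_lognormal(rng, mean, sd, lo, hi, size):
    """Lognormal with the requested arithmetic mean/sd, rejection-clipped."""
    s2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    out = rng.lognormal(mu, np.sqrt(s2), size)
    return np.clip(out, lo, hi)


def make_cohort(scenario: CohortScenario):
    """Generate a phantom cohort: list of (suv, adc, dwi, truth) plus a truth table.

    Per-lesion voxel noise uses a seed derived from (master seed, lesion
    index); cohort-level draws (diameters, offsets, coupled amplitudes,
    translations) use the master seed directly, so the cohort structure and
    individual phantoms are independently reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    n = scenario.n_lesions

    diam = _truncated_lognormal(
        rng,
        scenario.diameter_mean,
        scenario.diameter_sd,
        *scenario.diameter_range,
        size=n,
    )

    # coupled lesion-level draws: SUV amplitude and ADC_min level
    rho = scenario.coupling
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    amp = np.clip(
        scenario.suv_amplitude_mean + scenario.suv_amplitude_sd * z[:, 0], 1.5, 12.0
    )
    adc_min_level = np.clip(
        scenario.adc_min_mean + scenario.adc_min_sd * z[:, 1], 300.0, 1100.0
    )

    lo, hi = scenario.offset_range
    if scenario.size_dependent_offset:
        # larger tumors can separate further: offset uniform up to a fixed
        # fraction of the diameter (and never beyond the scenario range)
        caps = np.minimum(hi, scenario.offset_diameter_fraction * diam)
        offsets = rng.uniform(np.minimum(lo, caps), caps, size=n)
    else:
        offsets = rng.uniform(lo, hi, size=n)
    translations = rng.normal(0.0, scenario.translation_sd, size=(n, 3))

    pairs, rows = [], []
    for i in range(n):
        a = diam[i] / 2.0
        semi = (a, 0.8 * a, 0.7 * a)
        # foci symmetric about the center along the major axis; keep inside
        offsets[i] = min(offsets[i], 1.7 * a)
        half = offsets[i] / 2.0
        spec = SyntheticLesionSpec(
            semi_axes=semi,
            suv_focus=(half, 0.0, 0.0),
            adc_trough=(-half, 0.0, 0.0),
            suv_amplitude=float(amp[i]),
            # baseline uptake scales with the focal excess so the whole
            # lesion clears the adaptive threshold regardless of amplitude
            suv_background=1.0 + 0.9 * float(amp[i]),
            adc_depth=1400.0 - float(adc_min_level[i]),
            rim_outlier_fraction=scenario.rim_outlier_fraction,
            noise_sd_suv=scenario.noise_sd_suv,
            noise_sd_adc=scenario.noise_sd_adc,
            translation=TranslationVector(*translations[i]),
            reader_noise_sd=scenario.reader_noise_sd,
            reader_noise_scale_sigma=scenario.reader_noise_scale_sigma,
            n_readers=scenario.n_readers,
            seed=(scenario.seed, 1 + i),
        )
        suv, adc, dwi, truth = make_lesion_pair(spec)
        pairs.append((suv, adc, dwi, truth))
        row = {
            "lesion_id": i,
            "true_distance_mm": truth.offset_mm,
            "diameter_mm": diam[i],
            "true_volume_cm3": truth.volume_cm3,
            "suv_amplitude": amp[i],
            "adc_min_level": adc_min_level[i],
            "t_dx": truth.translation.dx,
            "t_dy": truth.translation.dy,
            "t_dz": truth.translation.dz,
        }
        for r, tr in enumerate(truth.reader_translations, start=1):
            row[f"reader{r}_dx"], row[f"reader{r}_dy"], row[f"reader{r}_dz"] = (
                tr.dx,
                tr.dy,
                tr.dz,
            )
        rows.append(row)
    return pairs, pd.DataFrame(rows)
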