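# Methods

This note documents the measurement model, the defaults and why they were
chosen, what the synthetic phantoms do and do not emulate, and the
numerical conventions.

## Geometry and coordinate conventions

Volumes are axis-aligned regular grids. World coordinates use the
voxel-center convention `world = origin + index · spacing` with 0-based
indices ordered (x, y, z); NIfTI affines must be positive-diagonal.
Whether clinical workstations report voxel-center or voxel-corner
coordinates varies by vendor; voxel-center is a package convention, not a
claim about any particular system. The MRI→PET rigid translation `t` maps
MRI world coordinates into the PET frame, `p_PET = p_MRI + t`; applying
`t` then `−t` is the identity. Only translations are modeled — the
clinical alignment procedure this mirrors is a manual rigid translation,
and rotational or deformable registration is out of scope.

Resampling between the PET grid (default 5.0 × 5.0 × 3.27 mm) and the MRI
grid (2.6 × 2.6 × 5 mm) is trilinear for intensities and nearest-neighbor
for masks, with out-of-extent voxels filled with 0 (air/lung). Trilinear
interpolation cannot overshoot the source range; an identity resample
returns the input values exactly.

## Registration accuracy and the match threshold

For each case two readers supply translations; the registration difference
is `‖t₁ − t₂‖` (mm). The accuracy summary is the sample mean and sd
(n − 1) of these differences, and the match threshold is the one-sided 95%
normal upper limit

```
threshold = round_half_up(mean + 1.645 · sd)   [mm]
```

With differences of 6.0 ± 3.5 mm this yields 11.7575 → **12 mm**. The
"upper limit of the 95% confidence interval" is interpreted as this
one-sided population limit because confidence-interval-of-the-mean
formulas cannot produce 12 mm from those moments; the interpretation is a
documented package decision, and the z-factor and rounding are fixed in
code rather than configurable by stealth. Automated translation estimation
(mask-centroid difference, optionally refined by an exhaustive ±10 mm
normalized-cross-correlation grid search at 1 mm steps) replaces the
manual visual alignment for synthetic runs.

## PET VOI segmentation

Iterative source-to-background adaptive thresholding:

* initial peak = maximum SUV within 10 mm of the seed; initial background
  = 25th percentile of the whole volume (far-field lung/air);
* iterate: `T = bg + β(peak − bg)`; the mask is the 26-connected
  supra-threshold component containing the seed; `peak` is the mask
  maximum and `bg` the **median** SUV in a 10 mm shell around the mask;
* stop when the mask repeats (converged) or after 25 iterations (the last
  mask is returned with a warning flag).

β defaults to 0.41, in the range used by source-to-background adaptive
methods on clinical workstations; the exact vendor variant behind any
given scanner is generally unpublished, so β and the shell width are
explicit configuration, not claims. The shell *median* (rather than mean)
is used because the shell can clip adjacent non-background structures,
which would drag the threshold upward and erode the VOI; with a homogeneous
background the two coincide. A seed whose SUV does not exceed the
background raises a segmentation error.

## ADC ROI and histogram refinement

The lesion is delineated on the b=800 volume (Otsu threshold in a bounding
box around the seed, 26-connected seed component — an automated surrogate
for manually drawn 2D ROI stacks; externally drawn masks can be supplied
as NIfTI instead), then copied onto the ADC map (identity copy on a shared
grid, nearest-neighbor otherwise).

Low-ADC outliers — aerated-lung voxels at the lesion rim with ADC near
zero — are removed by an automated histogram rule standing in for the
manual "inspect the ROI histogram and exclude low outliers" step: with
50 · 10⁻⁶ mm²/s bins aligned at zero, find the widest run of empty bins
below the histogram mode (at least `min_gap_bins = 2` bins wide, so
single-bin sampling gaps in a sparse low tail do not trigger it) and drop
all voxels strictly below that run's upper edge. If no such gap exists, a
percentile floor `p_low` (default 1%) applies. The refinement is a pure
filter: the refined mask is a subset of the input, the masked minimum can
only rise, and the histogram mode always survives.

Volume is voxel count × voxel volume (cm³); the maximum 3D diameter is the
largest pairwise distance between voxel centers (exact, computed over
convex-hull vertices for large masks).

## Extremum concordance and sphere statistics

SUV_max and ADC_min are masked voxel extrema; ties are broken toward the
lowest linearized index (x fastest) and the tie count is recorded. The
inter-extremum distance is `D = ‖p_SUVmax − (p_ADCmin + t)‖`, and a lesion
is a spatial match iff `D ≤ threshold` (boundary inclusive).

Cross-parameter statistics (ADC@SUV_max, ADC_min@SUV_max,
ADC_mean@SUV_max, and the SUV analogues around ADC_min) are computed over
voxels whose centers lie within a sphere of volume 1 cm³ — radius
`(3V/4π)^{1/3} = 6.2035 mm` — *and* inside the lesion mask. "1 cm³
sphere" is read as a sphere of that volume, not of 1 cm radius. Clipping
to the VOI keeps rim and background voxels out of the statistics (whether
the original clinical measurements were clipped is unknown; this is a
package decision) and guarantees the orderings
`ADC_min ≤ ADC_min@SUV_max` and `SUV_max ≥ SUV_max@ADC_min`. If the
sphere misses the VOI entirely, the single nearest in-mask voxel is used
and flagged. Cross-modal lookups sample the nearest voxel without
interpolation, since the quantities are reported per voxel.

## Synthetic phantoms

Each phantom is an ellipsoidal lesion on near-zero background with

* SUV = baseline + amplitude · Gaussian bump at `p_S` inside the
  ellipsoid (lung ≈ 0.2 outside), Gaussian widths defaulting to one third
  of the smallest semi-axis — a deliberately simple unimodal
  heterogeneity model chosen for unambiguous ground truth, not a tumor
  biology model;
* ADC = plateau (1400 · 10⁻⁶ mm²/s) − depth · Gaussian trough at `p_A`,
  clipped at 0, with a configurable fraction (default 10%) of
  boundary-shell voxels set uniformly on [0, 100) · 10⁻⁶ mm²/s to emulate
  aerated-lung rim contamination — the feature the histogram refinement
  must remove;
* DWI b=800 high inside / low outside, used only for delineation;
* additive Gaussian noise per modality (SUV sd 0.3, ADC sd 50 by
  default). Rician magnitude bias is deliberately not modeled: noise only
  needs to perturb extrema, not reproduce MR physics.

ADC/DWI are generated in an MRI frame displaced from the PET frame by a
known translation; readers are emulated as that translation plus per-axis
Gaussian error (sd 2.66 mm) whose magnitude varies lognormally across
cases (σ = 0.36). These two numbers are chosen so the inter-reader
difference norms have mean ≈ 6 mm and sd ≈ 3.5 mm — the registration
accuracy the analysis assumes — which a purely isotropic Gaussian cannot
realize (its norm distribution fixes mean/sd ≈ 2.4).

Cohorts draw diameters lognormally (mean 50, sd 25 mm, clipped to 18–110
mm, matching a surgical lung-tumor cohort), place the two foci
symmetrically about the center along the major axis, and by default cap
the true offset at 0.3 × diameter (size-dependent separation: only large
tumors can mismatch, reproducing the observed "all mismatch tumors
> 3 cm" structure). The lesion-level SUV amplitude and minimum-ADC level
are drawn from a bivariate normal with correlation `coupling` (default
−0.5, the moderate inverse relation reported for matched tumors), then
clipped to positive physiological ranges; the lesion SUV baseline scales
with the amplitude (1 + 0.9 · amplitude) so the whole lesion always
clears the adaptive threshold. Per-lesion voxel noise is seeded by
(master seed, lesion index); cohort-level draws use the master seed, so
both levels are independently reproducible.

What passing phantom tests shows: the pipeline recovers known extremum
separations to within grid quantization (RMSE ≲ 4.5 mm, under the 7.79 mm
PET voxel diagonal, over offsets 0–40 mm), derives the 12 mm threshold
from reader vectors realizing the published moments, recovers the sign of
a generating SUV_max–ADC_min coupling in the match stratum, and measures
PET/MRI volumes in near-perfect agreement on noise-free lesions. What it
does not show: robustness to respiratory motion, EPI distortion,
partial-volume effects, multimodal heterogeneity with several competing
foci, or real reader behavior — none of which the generator emulates.

## Published-data fixtures

The per-patient table of the 10-patient simultaneous PET/MRI cohort is
bundled as CSV exactly as printed; `table3_summary` recomputes its
summary row (half-up rounding to the printed precision) and the derived
counts (distances < 10 mm and > 20 mm, matched tumors > 3 cm at 12 mm).
The sequential cohort's per-patient values were never published, so only
its printed summary statistics (reader distance means/sds, mismatch
counts, registration-difference moments) are bundled as constants;
`abstract_aggregates` averages the two readers' means (14.0 mm) and
mismatch counts (9/25). Where a rule needs a *sample* realizing published
moments (the threshold derivation), a deterministic non-negative sample
with exactly those sample moments is constructed; the rule's output
depends only on the moments.

## Statistical conventions

Pearson p-values use the exact t transform with df = n − 2; Spearman uses
average ranks and the same t approximation (the original analysis
software's method is unpublished). The unpaired comparison is a Student
pooled-variance t-test by default with Welch behind a flag. Strata too
small to correlate (n < 3, or zero variance) yield NA rather than errors
so cohort runs never abort. Bland–Altman limits are bias ± 1.96 sd of the
paired differences, with a count of pairs strictly outside. Degenerate
zero-variance t-tests return (0, 1) for identical means and a large
finite statistic otherwise. No multiple-testing correction is applied,
matching the analysis being reproduced.

## Problem sizes

Default phantom grids are ~20³ (PET) to ~50×50×25 (MRI) voxels — large
enough that the lesion plus a 15 mm margin is fully contained, small
enough that a 25-lesion cohort analyzes in under a second. The Monte-Carlo
properties use 100 phantoms (distance RMSE), 100 seeded cohorts of 16
lesions (sign recovery), and 30 lesions (volume agreement).

## Known limitations

* Only positive-diagonal NIfTI affines (axis-aligned volumes); no DICOM.
* Pure-translation registration; no rotation, deformation or distortion
  correction.
* The adaptive-threshold β is a tunable stand-in for unpublished vendor
  segmentation parameters; absolute volumes depend on it, though the
  volume *agreement* between modalities does not.
* The histogram gap rule assumes outliers are separated from tumor tissue
  by ≥ 100 · 10⁻⁶ mm²/s of empty histogram; overlapping contamination
  would need the percentile fallback.
* Single-lesion scenes only; multi-focal disease is out of scope.
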