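# petmr-concordance

Spatial concordance of PET **SUV_max** and DW-MRI **ADC_min** in lung-tumor
PET/MRI: a tested pipeline for coregistration-accuracy thresholding, lesion
VOI segmentation, extremum localization, match/mismatch classification, and
stratified cohort statistics — driven either by NIfTI volumes or by a
synthetic phantom-cohort generator with known ground truth.

## The problem

The hottest FDG-PET voxel of a lung tumor (SUV_max) and its lowest apparent
diffusion coefficient voxel (ADC_min, a cellularity surrogate from DW-MRI)
are both used as aggressiveness markers, and their *numeric* correlation is
widely reported. But the two extrema need not sit in the same part of the
tumor. This package quantifies their *spatial* relationship and how it
conditions the numeric correlation:

1. **Registration accuracy.** Two readers align PET and b=800 DW-MRI with
   rigid 3D translations `t = (dx, dy, dz)`. The per-case inter-reader
   difference `‖t₁ − t₂‖` defines the accuracy distribution; its one-sided
   95% normal upper limit, `round(mean + 1.645·sd)`, is the smallest
   inter-extremum distance distinguishable from alignment error. With
   differences of 6.0 ± 3.5 mm this gives a **12 mm** threshold.
2. **Lesion measurement.** The PET VOI is grown by iterative adaptive
   thresholding, `T = bg + β·(peak − bg)` with β = 0.41; the lesion is
   delineated on the b=800 volume, copied to the ADC map, and low-ADC
   outlier voxels (aerated lung at the rim) are removed by histogram-gap
   analysis. Outputs per lesion: SUV_max, SUV_mean, V_PET, maximum 3D
   diameter, ADC_min, ADC_mean, V_MRI, and the extremum coordinates.
3. **Concordance.** The inter-extremum distance
   `D = ‖p(SUV_max) − (p(ADC_min) + t)‖` classifies each lesion as a
   spatial **match** (D ≤ 12 mm) or **mismatch** (D > 12 mm). Cross-modal
   readouts (ADC_min@SUV_max, SUV_max@ADC_min, …) are taken over a
   1 cm³ sphere (radius 6.2035 mm) clipped to the lesion VOI.
4. **Cohort statistics.** Pearson/Spearman correlations stratified by
   match status and tumor diameter (≤ / > 3 cm), unpaired t-tests, and
   Bland–Altman interobserver limits of agreement.

A published per-patient table of a 10-patient simultaneous PET/MRI cohort
is bundled so its summary row, distance counts and match counts can be
recomputed exactly.

## Worked example

```python
import petmr_concordance as pc

# a phantom lesion: 20 mm true separation between the SUV and ADC foci
spec = pc.SyntheticLesionSpec(
    semi_axes=(30, 24, 21), suv_focus=(10, 0, 0), adc_trough=(-10, 0, 0),
    noise_sd_suv=0, noise_sd_adc=0, noise_sd_dwi=0,
    rim_outlier_fraction=0, seed=7,
)
suv, adc, dwi, truth = pc.make_lesion_pair(spec)
rec = pc.analyze_lesion_pair(suv, adc, dwi, [truth.translation],
                             threshold_mm=12.0)[0]
print(f"D = {rec.distance_mm:.1f} mm (truth {truth.offset_mm:.1f}),"
      f" match={rec.match}, SUV_max={rec.suv_max:.1f},"
      f" ADC_min={rec.adc_min:.0f}")
```

prints

```
D = 16.7 mm (truth 20.0), match=False, SUV_max=10.9, ADC_min=704
```

The measured distance differs from the generating truth by a few mm — the
extrema are quantized to the PET (5.0 × 5.0 × 3.27 mm) and MRI
(2.6 × 2.6 × 5 mm) grids — and D > 12 mm correctly flags the lesion as a
spatial mismatch. The whole-cohort analyses live in `analysis/`
(`01_verify_printed_tables.py` … `04_cohort_statistics.py`), each writing
its tables under `results/`. A thin CLI wraps the same functions:

```bash
petmr-concordance verify-published
petmr-concordance simulate --seed 0 --n 10 --out scratch/demo
petmr-concordance analyze --seed 0 --out results/demo
```

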