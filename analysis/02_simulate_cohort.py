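#!/usr/bin/env python
"""Generate the reference phantom cohort: 25 paired SUV/ADC/DWI lung-lesion
phantoms with two emulated readers, the default study-like conditions
(diameters ~50 +/- 25 mm, inter-reader registration differences ~6 +/- 3.5
mm, SUV_max-ADC_min coupling -0.5).

Writes the ground-truth table to results/cohort_truth.csv and the NIfTI
volumes to scratch/cohort/ (volumes are regenerated deterministically from
the seed by the downstream scripts, so the NIfTI copies are for inspection
only).
"""

from pathlib import Path

from petmr_concordance import CohortScenario, make_cohort, write_nifti

ROOT = Path(__file__).resolve().parent.parent
SEED = 0


def main():
    scenario = CohortScenario(n_lesions=25, seed=SEED)
    pairs, truth = make_cohort(scenario)
    (ROOT / "results").mkdir(exist_ok=True)
    truth.to_csv(ROOT / "results" / "cohort_truth.csv", index=False)

    nifti_dir = ROOT / "scratch" / "cohort"
    nifti_dir.mkdir(parents=True, exist_ok=True)
    for i, (suv, adc, dwi, _) in enumerate(pairs):
        write_nifti(suv, nifti_dir / f"lesion{i:03d}_suv.nii.gz")
        write_nifti(adc, nifti_dir / f"lesion{i:03d}_adc.nii.gz")
        write_nifti(dwi, nifti_dir / f"lesion{i:03d}_dwi.nii.gz")

    print(f"generated {len(pairs)} phantom lesion pairs (seed {SEED})")
    print(f"diameters: {truth.diameter_mm.min():.0f}-{truth.diameter_mm.max():.0f} mm, "
          f"median {truth.diameter_mm.median():.0f} mm")
    print(f"true SUVmax-ADCmin offsets: {truth.true_distance_mm.min():.1f}-"
          f"{truth.true_distance_mm.max():.1f} mm")
    print(f"truth table: results/cohort_truth.csv; volumes: scratch/cohort/")


if __name__ == "__main__":
    main()
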