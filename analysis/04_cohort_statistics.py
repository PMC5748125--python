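#!/usr/bin/env python
"""Stratified correlation and group-comparison analysis of the reference
phantom cohort: SUV_max vs ADC_min by match stratum and size stratum,
PET vs MRI volume agreement, and the diameter comparison between matched
and mismatched lesions.

Reads results/lesion_records.csv (written by 03_analyze_cohort); writes
results/stratified_correlations.csv and results/group_comparisons.json.
"""

import json
from pathlib import Path

import pandas as pd

from petmr_concordance import group_compare, stratified_correlations

ROOT = Path(__file__).resolve().parent.parent


def main():
    path = ROOT / "results" / "lesion_records.csv"
    if not path.exists():
        raise SystemExit("run 03_analyze_cohort.py first")
    records = pd.read_csv(path)
    r1 = records[records.reader_id == 1]

    strat = stratified_correlations(r1)
    strat.to_csv(ROOT / "results" / "stratified_correlations.csv", index=False)

    def show(stratum, pair):
        row = strat[(strat.stratum == stratum) & (strat.pair == pair)].iloc[0]
        r = "NA" if pd.isna(row.r_pearson) else f"{row.r_pearson:+.2f} (P={row.p_pearson:.3f})"
        print(f"  {stratum:>22s}  n={row.n:>2d}  r_P={r}")

    print("SUV_max vs ADC_min by stratum (reader 1):")
    for s in ("all", "match", "mismatch", "diam<=3cm", "diam>3cm & match"):
        show(s, "suv_max/adc_min")
    vol_row = strat[(strat.stratum == "all") & (strat.pair == "v_pet_cm3/v_mri_cm3")].iloc[0]
    print(f"PET vs MRI volume: r_P={vol_row.r_pearson:.3f}")

    matched = r1[r1.match]["diameter_mm"]
    mismatched = r1[~r1.match]["diameter_mm"]
    out = {"volume_correlation_r": round(float(vol_row.r_pearson), 3)}
    if len(matched) >= 2 and len(mismatched) >= 2:
        t, p = group_compare(matched, mismatched)
        print(f"diameter, match vs mismatch: {matched.mean():.1f} vs "
              f"{mismatched.mean():.1f} mm (t={t:.2f}, P={p:.3f})")
        out["diameter_match_vs_mismatch"] = {
            "mean_match_mm": round(float(matched.mean()), 1),
            "mean_mismatch_mm": round(float(mismatched.mean()), 1),
            "t": round(t, 2),
            "p": round(p, 4),
        }
    with open(ROOT / "results" / "group_comparisons.json", "w") as fh:
        json.dump(out, fh, indent=2)


if __name__ == "__main__":
    main()
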