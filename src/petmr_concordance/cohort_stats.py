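"""Cohort aggregation and statistics: stratified Pearson/Spearman
correlations, unpaired group comparisons, Bland-Altman interobserver
agreement, and recomputation of the published simultaneous-cohort table.

The per-patient measurements of the simultaneous PET/MRI cohort (n = 10
lung tumors: SUV_max, SUV_mean, ADC_min/ADC_mean and inter-extremum
distance per reader, PET tumor diameter) are bundled as a CSV fixture so
the printed summary row and the derived counts can be recomputed exactly.
The sequential cohort's per-patient values were never published; only its
printed summary statistics (reader distance means, mismatch counts,
inter-reader registration differences) are bundled, as constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "BlandAltmanResult",
    "PUBLISHED_SEQUENTIAL",
    "load_table3",
    "correlate",
    "stratified_correlations",
    "group_compare",
    "bland_altman",
    "table3_summary",
    "abstract_aggregates",
    "STRATA",
]

#: Published summary statistics of the sequential cohort (readers 1 and 3
#: read the DW-MRI; readers 1 and 2 performed the registration).
PUBLISHED_SEQUENTIAL = {
    "n_patients": 25,
    "registration_diff_mean_mm": 6.0,
    "registration_diff_sd_mm": 3.5,
    "distance_mean_mm": {"reader1": 12.7, "reader3": 15.2},
    "distance_sd_mm": {"reader1": 8.7, "reader3": 10.5},
    "n_mismatch": {"reader1": 8, "reader3": 10},
}


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    stratum: str
    n: int
    r_pearson: float
    p_pearson: float
    r_spearman: float
    p_spearman: float


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    n: int
    n_outside: int


def load_table3() -> pd.DataFrame:
    """Per-patient measurements of the simultaneous PET/MRI cohort."""
    with resources.files("petmr_concordance.data").joinpath(
        "table3_simultaneous.csv"
    ).open() as fh:
        return pd.read_csv(fh)


class UndefinedCorrelationError(ValueError):
    """Zero variance in one of the inputs."""


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    stratum: str = "all",
    pair: str = "",
) -> CorrelationResult:
    """Pearson and Spearman correlation with two-sided p-values.

    Pearson p via the exact t transform with df = n - 2; Spearman uses
    average ranks for ties and the same t approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    rp, pp = stats.pearsonr(x, y)
    rs, ps = stats.spearmanr(x, y)
    return CorrelationResult(
        pair=pair,
        stratum=stratum,
        n=n,
        r_pearson=float(rp),
        p_pearson=float(pp),
        r_spearman=float(rs),
        p_spearman=float(ps),
    )


#: Stratum name -> row predicate on a cohort record table. Requires columns
#: ``match`` (bool) and ``diameter_mm``.
STRATA = {
    "all": lambda df: np.ones(len(df), dtype=bool),
    "match": lambda df: df["match"].to_numpy(dtype=bool),
    "mismatch": lambda df: ~df["match"].to_numpy(dtype=bool),
    "diam<=3cm": lambda df: df["diameter_mm"].to_numpy() <= 30.0,
    "diam>3cm & match": lambda df: (df["diameter_mm"].to_numpy() > 30.0)
    & df["match"].to_numpy(dtype=bool),
    "diam>3cm & mismatch": lambda df: (df["diameter_mm"].to_numpy() > 30.0)
    & ~df["match"].to_numpy(dtype=bool),
}

DEFAULT_PAIRS = [
    ("v_pet_cm3", "v_mri_cm3"),
    ("suv_max", "suv_mean"),
    ("adc_min", "adc_mean"),
    ("suv_max", "adc_min"),
    ("suv_mean", "adc_mean"),
    ("suv_max", "adc_mean_at_suvmax"),
    ("adc_min", "suv_mean_at_adcmin"),
]


def stratified_correlations(
    records: pd.DataFrame,
    strata: Sequence[str] | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """One correlation row per (stratum, variable pair).

    Strata with n < 3 (or zero variance) yield NA values rather than
    errors, so whole-cohort runs never abort on a small subgroup.
    """
    strata = list(STRATA) if strata is None else list(strata)
    pairs = DEFAULT_PAIRS if pairs is None else list(pairs)
    unknown = [s for s in strata if s not in STRATA]
    if unknown:
        raise ValueError(f"unknown strata: {unknown}")
    rows = []
    for name in strata:
        sub = records.loc[STRATA[name](records)]
        for xcol, ycol in pairs:
            pair = f"{xcol}/{ycol}"
            base = {"stratum": name, "pair": pair, "n": len(sub)}
            try:
                res = correlate(sub[xcol], sub[ycol], stratum=name, pair=pair)
                base.update(
                    r_pearson=res.r_pearson,
                    p_pearson=res.p_pearson,
                    r_spearman=res.r_spearman,
                    p_spearman=res.p_spearman,
                )
            except (ValueError, UndefinedCorrelationError):
                base.update(
                    r_pearson=np.nan, p_pearson=np.nan,
                    r_spearman=np.nan, p_spearman=np.nan,
                )
            rows.append(base)
    return pd.DataFrame(rows)


def group_compare(
    a: Sequence[float],
    b: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Unpaired two-sided t-test (Student pooled-variance by default).

    Degenerate zero-variance inputs are guarded: equal-mean groups give
    (0, 1); distinct means with zero pooled variance give a large finite t
    and a tiny p instead of an exception.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 in both groups")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * 1e12), 1e-300
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def bland_altman(reader_a: Sequence[float], reader_b: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement: bias and 1.96 sd limits of the paired
    differences a - b, plus the count of pairs strictly outside the limits."""
    a = np.asarray(reader_a, float)
    b = np.asarray(reader_b, float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    if a.size < 3:
        raise ValueError("need n >= 3 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lower, upper = bias - 1.96 * sd, bias + 1.96 * sd
    outside = int(np.sum((d < lower) | (d > upper)))
    return BlandAltmanResult(
        bias=bias, sd_diff=sd, lower_limit=lower, upper_limit=upper,
        n=int(a.size), n_outside=outside,
    )


def _round_half_up(x: float, decimals: int = 0) -> float:
    f = 10.0**decimals
    return float(np.floor(x * f + 0.5) / f)


def table3_summary(
    table: pd.DataFrame | None = None,
    match_threshold_mm: float = 12.0,
) -> dict:
    """Recompute the simultaneous-cohort summary row and derived counts.

    Means are rounded half-up to the table's displayed precision (one
    decimal for SUV and distances/diameter, integer for ADC). Counts use
    the reader-1 distances: tumors closer than 10 mm, farther than 20 mm,
    and spatially matched (distance <= threshold) tumors larger than 3 cm.
    """
    t = load_table3() if table is None else table
    if len(t) == 0:
        raise ValueError("empty cohort table")
    d1 = t["distance_mm_r1"].to_numpy(float)
    out = {
        "n": int(len(t)),
        "mean_suv_max": _round_half_up(t["suv_max"].mean(), 1),
        "mean_suv_mean": _round_half_up(t["suv_mean"].mean(), 1),
        "mean_adc_min_r1": _round_half_up(t["adc_min_r1"].mean()),
        "mean_adc_min_r3": _round_half_up(t["adc_min_r3"].mean()),
        "mean_adc_mean_r1": _round_half_up(t["adc_mean_r1"].mean()),
        "mean_adc_mean_r3": _round_half_up(t["adc_mean_r3"].mean()),
        "mean_distance_r1": _round_half_up(d1.mean(), 1),
        "mean_distance_r3": _round_half_up(t["distance_mm_r3"].mean(), 1),
        "sd_distance_r1": _round_half_up(d1.std(ddof=1), 1),
        "mean_diameter": _round_half_up(t["diameter_mm"].mean(), 1),
        "n_distance_lt_10mm": int(np.sum(d1 < 10.0)),
        "n_distance_gt_20mm": int(np.sum(d1 > 20.0)),
        "n_match_diam_gt_3cm": int(
            np.sum((d1 <= match_threshold_mm) & (t["diameter_mm"].to_numpy() > 30.0))
        ),
    }
    return out


def abstract_aggregates(published: dict | None = None) -> dict:
    """Reader-averaged headline numbers of the sequential cohort.

    The mean inter-extremum distance averaged over the two reading sessions
    and the reader-averaged mismatch count, computed from the published
    per-reader summary statistics.
    """
    pub = PUBLISHED_SEQUENTIAL if published is None else published
    means = pub["distance_mean_mm"]
    mism = pub["n_mismatch"]
    return {
        "mean_distance_mm": _round_half_up(
            (means["reader1"] + means["reader3"]) / 2.0, 1
        ),
        "n_mismatch": _round_half_up(sum(mism.values()) / len(mism)),
        "n_patients": pub["n_patients"],
    }
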