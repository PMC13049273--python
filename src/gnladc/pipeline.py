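"""End-to-end analysis: scans -> bias/ADC maps -> tidy cohort tables.

One tidy row per subject x timepoint x site with bias statistics (from the
noiseless model b-map), ADC statistics before and after correction, and
subject covariates.  Group-level (T / I / MV / EV) tables pool voxels
across member sites, mirroring combined-ROI histogram analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coil import CoilModel
from .gnc import apply_gnc, bias_percent, fit_adc, fractional_adc_bias, make_bmap
from .roi import (GROUP_OF_SITE, SITE_GROUPS, group_values, heterogeneity_cv,
                  intra_subject_nonuniformity, roi_statistics, trend_deviation)
from .simulate import CohortData, SubjectScan
from .stats import bland_altman, paired_t

log = logging.getLogger(__name__)

#: lower ADC bound (um^2/ms) excluding voxels with limited contrast-to-noise
ADC_THRESHOLD = 0.01

# b-maps depend only on (model, grid geometry, table offset): memoize across
# the many scans of a cohort that share station grids
_BMAP_CACHE: dict[tuple, object] = {}


def _cached_bmap(model: CoilModel, grid, dirs, offset):
    key = (model.cache_key, grid.origin, grid.spacing, grid.data.shape,
           float(np.atleast_1d(offset)[-1]), dirs.u.tobytes())
    if key not in _BMAP_CACHE:
        if len(_BMAP_CACHE) > 8:
            _BMAP_CACHE.clear()
        _BMAP_CACHE[key] = make_bmap(model, grid, dirs, offset)
    return _BMAP_CACHE[key]


def analyze_scan(
    scan: SubjectScan, model: CoilModel, adc_threshold: float = ADC_THRESHOLD
) -> pd.DataFrame:
    """Per-site bias and ADC statistics for one subject timepoint."""
    rows = []
    for st in scan.stations:
        grid = st.dwi.s0
        bmap = _cached_bmap(model, grid, st.dwi.directions, st.table_offset_mm)
        beta = bias_percent(bmap)
        adc = fit_adc(st.dwi)
        adcg = apply_gnc(adc, bmap)
        bias_stats = roi_statistics(beta, st.labels)
        adc_stats = roi_statistics(adc.volume, st.labels, threshold=adc_threshold,
                                   mask=adc.mask)
        adcg_stats = roi_statistics(adcg.volume, st.labels, threshold=adc_threshold,
                                    mask=adcg.mask)
        for site, bs in bias_stats.items():
            row = {
                "subject": scan.spec.subject_id,
                "timepoint": scan.timepoint,
                "site": site,
                "group": GROUP_OF_SITE.get(site),
                "station": st.station,
                "n_vox": bs.count,
                "volume_cm3": bs.volume_cm3,
                "bias_mean": bs.mean,
                "bias_median": bs.median,
                "bias_min": bs.vmin,
                "bias_max": bs.vmax,
                "mf_grade": scan.spec.mf_grade,
                "sex": scan.spec.sex,
                "age": scan.spec.age,
            }
            for prefix, stats in (("adc", adc_stats), ("adc_gnc", adcg_stats)):
                s = stats.get(site)
                row[f"{prefix}_mean"] = s.mean if s else np.nan
                row[f"{prefix}_median"] = s.median if s else np.nan
                row[f"{prefix}_sd"] = s.sd if s else np.nan
                row[f"{prefix}_n"] = s.count if s else 0
            rows.append(row)
    return pd.DataFrame(rows)


def build_cohort_table(cohort: CohortData, model: CoilModel) -> pd.DataFrame:
    """Tidy table over all subjects/timepoints/sites, joined with truths."""
    frames = []
    for series in cohort.scans:
        for scan in series:
            frames.append(analyze_scan(scan, model))
    table = pd.concat(frames, ignore_index=True)
    truth = cohort.truth[["subject", "site", "true_adc", "fat_fraction"]]
    table = table.merge(truth, on=["subject", "site"], how="left")
    dup = table.duplicated(["subject", "timepoint", "site"])
    if dup.any():
        raise ValueError("duplicate (subject, timepoint, site) keys")
    return table


def group_table(table: pd.DataFrame) -> pd.DataFrame:
    """Voxel-weighted group-level (T/I/MV/EV) means per subject x timepoint."""
    rows = []
    for (subj, tp, grp), sub in table.groupby(["subject", "timepoint", "group"]):
        w_bias = sub["n_vox"].to_numpy(float)
        w_adc = sub["adc_n"].to_numpy(float)
        row = {
            "subject": subj, "timepoint": tp, "group": grp,
            "volume_cm3": sub["volume_cm3"].sum(),
            "bias_mean": np.average(sub["bias_mean"], weights=w_bias),
            "mf_grade": sub["mf_grade"].iloc[0],
            "sex": sub["sex"].iloc[0],
            "age": sub["age"].iloc[0],
        }
        for col in ("adc_mean", "adc_gnc_mean", "true_adc"):
            vals = sub[col].to_numpy(float)
            ok = np.isfinite(vals) & (w_adc > 0)
            row[col] = np.average(vals[ok], weights=w_adc[ok]) if ok.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def subject_heterogeneity(table: pd.DataFrame, corrected: bool = True) -> pd.DataFrame:
    """Per-subject bias nonuniformity and ADC heterogeneity CV (timepoint 0)."""
    col = "adc_gnc_mean" if corrected else "adc_mean"
    rows = []
    t0 = table[table["timepoint"] == 0]
    for subj, sub in t0.groupby("subject"):
        means = sub.set_index("site")[col].dropna()
        bias = sub.set_index("site")["bias_mean"].dropna()
        row = {"subject": subj}
        row["bias_nonuniformity"] = (
            intra_subject_nonuniformity(bias.to_dict()) if len(bias) >= 2 else np.nan
        )
        row["adc_cv"] = (
            heterogeneity_cv(means.to_dict()) if len(means) >= 2 else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def trend_flags(groups: pd.DataFrame, corrected: bool = True) -> pd.DataFrame:
    """Per-subject trend-deviation flags from group means (timepoint 0)."""
    col = "adc_gnc_mean" if corrected else "adc_mean"
    rows = []
    g0 = groups[groups["timepoint"] == 0]
    for subj, sub in g0.groupby("subject"):
        means = sub.set_index("group")[col].dropna().to_dict()
        rows.append({"subject": subj, **trend_deviation(means)})
    return pd.DataFrame(rows)


def bland_altman_by_site(
    table: pd.DataFrame, value_col: str, pairs: tuple[int, int] = (0, 1)
):
    """Bland-Altman over (subject, site) test-retest pairs of ``value_col``.

    Returns the pooled result over all sites plus a per-site dict.
    """
    t0 = table[table["timepoint"] == pairs[0]].set_index(["subject", "site"])
    t1 = table[table["timepoint"] == pairs[1]].set_index(["subject", "site"])
    common = t0.index.intersection(t1.index)
    a = t0.loc[common, value_col].to_numpy(float)
    b = t1.loc[common, value_col].to_numpy(float)
    ok = np.isfinite(a) & np.isfinite(b)
    pooled = bland_altman(a[ok], b[ok])
    per_site = {}
    sites = common.get_level_values("site")
    for site in sites.unique():
        sel = ok & (sites == site)
        if sel.sum() >= 2:
            per_site[site] = bland_altman(a[sel], b[sel])
    return pooled, per_site


def summarize_groups(table: pd.DataFrame, subjects: list[str] | None = None) -> pd.DataFrame:
    """Bone-site-group summary: volume, ADC before/after GNC, paired p.

    Mirrors a per-group mean +/- SD table across subjects (timepoint 0),
    with the paired two-sided t-test of the correction effect.
    """
    g = group_table(table[table["timepoint"] == 0])
    if subjects is not None:
        g = g[g["subject"].isin(subjects)]
    rows = []
    for grp in ("T", "I", "MV", "EV"):
        sub = g[g["group"] == grp].dropna(subset=["adc_mean", "adc_gnc_mean"])
        if sub.empty:
            continue
        t, p = paired_t(sub["adc_mean"], sub["adc_gnc_mean"])
        rows.append({
            "group": grp,
            "n_subjects": len(sub),
            "volume_cm3_mean": sub["volume_cm3"].mean(),
            "volume_cm3_sd": sub["volume_cm3"].std(ddof=1),
            "adc_mean": sub["adc_mean"].mean(),
            "adc_sd": sub["adc_mean"].std(ddof=1),
            "adc_gnc_mean": sub["adc_gnc_mean"].mean(),
            "adc_gnc_sd": sub["adc_gnc_mean"].std(ddof=1),
            "p_gnc_effect": p,
        })
    return pd.DataFrame(rows)
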