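"""Cohort-level statistics: Bland-Altman repeatability, paired tests,
correlations, ANOVA, multiple-comparison thresholds, and cohort selection.

Conventions: sample SDs use the n-1 denominator; p-values come from the t
distribution (not the normal approximation) because the cohorts are small.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass
class BlandAltmanResult:
    """Test-retest agreement: mean difference and 1.96*SD limits."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_halfwidth: float        # exactly 1.96 * sd_diff
    means: np.ndarray           # per-pair (test + retest) / 2
    diffs: np.ndarray           # per-pair test - retest

    @property
    def loa(self) -> tuple[float, float]:
        return (self.mean_diff - self.loa_halfwidth,
                self.mean_diff + self.loa_halfwidth)


def bland_altman(test: Sequence[float], retest: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman analysis of paired test/retest values.

    Limits of agreement are assessed as 1.96 * SD(difference) around the
    mean difference.
    """
    a = np.asarray(test, dtype=float)
    b = np.asarray(retest, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("test and retest must be 1D arrays of equal length")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least two pairs")
    diffs = a - b
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanResult(
        n=a.size,
        mean_diff=float(diffs.mean()),
        sd_diff=sd,
        loa_halfwidth=1.96 * sd,
        means=(a + b) / 2.0,
        diffs=diffs,
    )


def paired_t(
    a: Sequence[float], b: Sequence[float], sides: int = 2,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Classical paired t-test; returns (t, p).

    ``sides=1`` (or ``alternative='greater'/'less'``) gives the one-sided
    test; 'greater' tests mean(a - b) > 0.  Zero-variance differences use
    the p = 1 convention with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D and equal length")
    if a.size < 2:
        raise ValueError("paired t-test needs n >= 2")
    if sides == 1 and alternative == "two-sided":
        alternative = "greater"
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        warnings.warn("zero-variance differences; using the p = 1 convention")
        t = 0.0 if d.mean() == 0 else float(np.sign(d.mean()) * np.inf)
        return t, 1.0
    res = sps.ttest_rel(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("Pearson correlation needs paired 1D samples, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for zero variance")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(*groups: Sequence[float]) -> tuple[float, float]:
    """Classical between/within one-way ANOVA; returns (F, p)."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in arrs):
        raise ValueError("each group needs n >= 2")
    if all(np.std(g, ddof=1) == 0 for g in arrs):
        means = [g.mean() for g in arrs]
        if np.ptp(means) == 0:
            return 0.0, 1.0
        raise ValueError("degenerate groups: zero within-group variance")
    res = sps.f_oneway(*arrs)
    return float(res.statistic), float(res.pvalue)


def multiple_comparison_threshold(alpha: float, k: int) -> float:
    """Bonferroni-adjusted significance threshold alpha / k."""
    if k < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / k


def significance_marks(p: float, alpha: float = 0.05, k: int = 6) -> str:
    """'*' at the nominal level, '**' at the Bonferroni-corrected level."""
    adj = multiple_comparison_threshold(alpha, k)
    if p < adj:
        return "**"
    if p < alpha:
        return "*"
    return ""


def select_subjects(
    cohort: pd.DataFrame, ff_limit: float = 0.40,
    ilium_sites: tuple[str, ...] = ("RI", "LI"),
) -> list[str]:
    """Subjects whose ilium fat fraction is strictly below ``ff_limit``.

    ``cohort`` is a tidy table with at least columns ``subject``, ``site``
    and ``fat_fraction``.  Subjects with no ilium FF are excluded with a
    warning; exclusions are logged with their IDs.
    """
    required = {"subject", "site", "fat_fraction"}
    if not required <= set(cohort.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    kept, excluded = [], []
    for subj, sub in cohort.groupby("subject", sort=True):
        ff = sub.loc[sub["site"].isin(ilium_sites), "fat_fraction"].dropna()
        if ff.empty:
            warnings.warn(f"subject {subj} has no ilium fat fraction; excluded")
            excluded.append(subj)
            continue
        if float(ff.mean()) < ff_limit:
            kept.append(subj)
        else:
            excluded.append(subj)
    log.info("select_subjects: kept %d, excluded %s", len(kept), excluded)
    return kept
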