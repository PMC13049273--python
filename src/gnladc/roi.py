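"""ROI statistics, histograms, site groupings, and heterogeneity indices."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .volume import ImageVolume, ROILabelMap

#: bone-site groups used throughout the analysis
SITE_GROUPS: dict[str, tuple[str, ...]] = {
    "MV": ("L2", "L3", "L4"),
    "EV": ("T11", "T12", "L1", "L5", "S1"),   # T11 when present
    "I": ("RI", "LI"),
    "T": ("RT", "LT"),
}

GROUP_OF_SITE: dict[str, str] = {
    s: g for g, members in SITE_GROUPS.items() for s in members
}


@dataclass
class Histogram:
    """Left-closed right-open bins anchored at 0."""

    edges: np.ndarray     # len(masses) + 1
    masses: np.ndarray    # normalized (sum to 1) or volume-weighted

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class ROIStats:
    """Summary statistics of one labelled region."""

    site: str
    count: int
    volume_cm3: float
    mean: float
    median: float
    sd: float
    vmin: float
    vmax: float
    histogram: Histogram | None = None

    @property
    def range(self) -> tuple[float, float]:
        return (self.vmin, self.vmax)

    @property
    def range_width(self) -> float:
        return self.vmax - self.vmin


def build_histogram(
    values: Sequence[float],
    bin_size: float,
    normalization: str = "count",
    voxel_volume: float = 1.0,
) -> Histogram:
    """Histogram with bins ``[k*bin_size, (k+1)*bin_size)`` anchored at 0.

    ``normalization='count'`` divides by the total count (masses sum to 1);
    ``'volume'`` weights each voxel by ``voxel_volume`` and divides by the
    total region volume, the convention used for bias histograms.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    if normalization not in ("count", "volume"):
        raise ValueError("normalization must be 'count' or 'volume'")
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        return Histogram(edges=np.array([]), masses=np.array([]))
    idx = np.floor(values / bin_size).astype(np.int64)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1).astype(float)
    edges = (np.arange(lo, hi + 2)) * bin_size
    # both conventions normalize to unit total mass; 'volume' is the
    # voxel-volume-weighted fraction of the ROI volume per bin
    if normalization == "volume":
        masses = counts * voxel_volume / (counts.sum() * voxel_volume)
    else:
        masses = counts / counts.sum()
    return Histogram(edges=edges, masses=masses)


def roi_statistics(
    vol: ImageVolume,
    labels: ROILabelMap,
    threshold: float | None = None,
    mask: np.ndarray | None = None,
    bin_size: float | None = None,
    histogram_normalization: str = "count",
) -> dict[str, ROIStats]:
    """Per-site statistics of ``vol`` over the labelled regions.

    Voxels are included when their label matches, they pass the optional
    validity ``mask``, and their value exceeds ``threshold`` (strict) when
    one is given.  Sites with no qualifying voxels are absent from the
    result rather than reported as zeros.
    """
    if not vol.same_geometry(labels.volume):
        raise ValueError("volume and label map geometries do not match")
    if mask is not None and mask.shape != vol.data.shape:
        raise ValueError("mask shape does not match the volume")
    vv = vol.voxel_volume_mm3
    out: dict[str, ROIStats] = {}
    for site, lab in labels.labels.items():
        sel = labels.volume.data == lab
        if mask is not None:
            sel &= mask
        vals = vol.data[sel].astype(float)
        if threshold is not None:
            vals = vals[vals > threshold]
        if vals.size == 0:
            continue
        hist = None
        if bin_size is not None:
            hist = build_histogram(vals, bin_size, histogram_normalization, vv)
        out[site] = ROIStats(
            site=site,
            count=int(vals.size),
            volume_cm3=vals.size * vv / 1000.0,
            mean=float(np.mean(vals)),
            median=float(np.median(vals)),
            sd=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
            vmin=float(np.min(vals)),
            vmax=float(np.max(vals)),
            histogram=hist,
        )
    return out


def group_values(
    vol: ImageVolume,
    labels: ROILabelMap,
    group: str,
    threshold: float | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Pooled voxel values over all member sites of a group (for combined
    histograms and group means)."""
    if group not in SITE_GROUPS:
        raise KeyError(f"unknown group {group!r}")
    sel = np.zeros(vol.data.shape, dtype=bool)
    for site in SITE_GROUPS[group]:
        if site in labels.labels:
            sel |= labels.volume.data == labels.labels[site]
    if mask is not None:
        sel &= mask
    vals = vol.data[sel].astype(float)
    if threshold is not None:
        vals = vals[vals > threshold]
    return vals


def intra_subject_nonuniformity(site_means: Mapping[str, float] | Sequence[float]) -> float:
    """Max minus min of the per-site mean biases of one subject (percent)."""
    vals = np.asarray(
        list(site_means.values()) if isinstance(site_means, Mapping) else site_means,
        dtype=float,
    )
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("nonuniformity needs at least two sites")
    return float(vals.max() - vals.min())


def heterogeneity_cv(site_means: Mapping[str, float] | Sequence[float]) -> float:
    """Coefficient of variation (percent) of site-mean ADC across bone sites."""
    vals = np.asarray(
        list(site_means.values()) if isinstance(site_means, Mapping) else site_means,
        dtype=float,
    )
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("CV needs at least two sites")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * np.std(vals, ddof=1) / mean)


def trend_deviation(group_means: Mapping[str, float]) -> dict[str, bool | None]:
    """Deviation flags from the reference heterogeneity trend.

    The reference trend has trochanter lowest, ilium highest, and
    edge-vertebrae above mid-vertebrae; a subject deviates when (strictly)
    ilium < trochanter, ilium < mid-vertebrae, or edge < mid-vertebrae.
    Exact ties set no flag; a missing group leaves its flag undefined
    (None) so it can be excluded from cohort counts.
    """
    g = {k: group_means.get(k) for k in ("T", "I", "MV", "EV")}

    def flag(a, b):
        if g[a] is None or g[b] is None:
            return None
        return bool(g[a] < g[b])

    return {
        "ilium_below_trochanter": flag("I", "T"),
        "ilium_below_mid_vertebrae": flag("I", "MV"),
        "edge_below_mid_vertebrae": flag("EV", "MV"),
    }
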