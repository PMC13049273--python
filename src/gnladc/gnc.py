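"""b-maps, bias maps, trace ADC fitting, and gradient-nonlinearity correction.

The measured trace ADC in an isotropic medium is c_bar(r) * ADC_true, where
c_bar = tr(L^T L)/3 is the trace b-value corrector of the coil model, so the
correction is a voxelwise division:  ADC_GNC = ADC / c_bar.

b-maps follow the on-scanner DICOM convention: dimensionless c_bar stored as
integers scaled to 1E4 at the isocenter.  The percent bias map is
100 * ((v / 1E4) - 1).  The b = 0 image carries no diffusion gradients and is
treated as bias-free; only the diffusion-weighted b-value is modulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .coil import CoilModel, DirectionSet, trace_corrector
from .volume import ImageVolume

log = logging.getLogger(__name__)

BMAP_SCALE = 1e4  # stored integer value at the isocenter


def _offset_vector(table_offset) -> np.ndarray:
    """Scalar offsets are S-I (z) couch translations; 3-vectors pass through."""
    off = np.atleast_1d(np.asarray(table_offset, dtype=float))
    if off.size == 1:
        return np.array([0.0, 0.0, float(off[0])])
    if off.size != 3:
        raise ValueError("table offset must be a scalar (S-I) or a 3-vector (mm)")
    return off.reshape(3)


@dataclass
class BMap:
    """Integer-scaled trace b-value ratio map (1E4 at isocenter)."""

    volume: ImageVolume          # int data, dimensionless * 1E4
    table_offset: np.ndarray     # mm, grid -> magnet translation

    @property
    def cbar(self) -> np.ndarray:
        """Dimensionless trace corrector c_bar = v / 1E4."""
        return self.volume.data / BMAP_SCALE


@dataclass
class DWISeries:
    """A b=0 / trace-DW volume pair from one imaging station."""

    s0: ImageVolume
    dw: ImageVolume
    b_nominal: float                       # s/mm^2
    directions: DirectionSet = field(default_factory=DirectionSet.axes)
    table_offset: float | Sequence[float] = 0.0

    def __post_init__(self) -> None:
        if self.b_nominal <= 0:
            raise ValueError(f"nominal b-value must be positive, got {self.b_nominal}")
        if not self.s0.same_geometry(self.dw):
            raise ValueError("b=0 and DW volumes must share one grid")


@dataclass
class ADCVolume:
    """ADC map in um^2/ms with a validity mask and corrected flag."""

    volume: ImageVolume
    mask: np.ndarray
    corrected: bool = False
    n_floored: int = 0       # voxels with S_b >= S0, floored to 0
    n_excluded: int = 0      # non-positive-signal voxels dropped from the mask


def make_bmap(
    model: CoilModel,
    grid: ImageVolume,
    dirs: DirectionSet | None = None,
    table_offset: float | Sequence[float] = 0.0,
) -> BMap:
    """Evaluate the trace b-value ratio on ``grid`` and store it 1E4-scaled.

    ``grid`` coordinates live in the patient/table frame; the magnet-frame
    position of each voxel is grid coordinate + table offset, so stations
    with different offsets produce identical values at the same anatomy.
    """
    if dirs is None:
        dirs = DirectionSet.axes()
    off = _offset_vector(table_offset)
    pts = grid.physical_points() + off
    r = np.linalg.norm(pts, axis=-1)
    if np.any(r > model.validity_radius_mm):
        lo = pts.reshape(-1, 3).min(axis=0)
        hi = pts.reshape(-1, 3).max(axis=0)
        raise ValueError(
            "grid (after table offset) extends beyond the coil validity radius "
            f"{model.validity_radius_mm:.0f} mm; magnet-frame extent "
            f"x [{lo[0]:.0f}, {hi[0]:.0f}], y [{lo[1]:.0f}, {hi[1]:.0f}], "
            f"z [{lo[2]:.0f}, {hi[2]:.0f}] mm"
        )
    cbar = trace_corrector(model.jacobian(pts), dirs)
    v = np.rint(BMAP_SCALE * cbar).astype(np.int32)
    vol = grid.copy_geometry(v, units="dimensionless")
    vol.meta["BMapScale"] = BMAP_SCALE
    vol.meta["TableOffset"] = " ".join(f"{x:g}" for x in off)
    return BMap(volume=vol, table_offset=off)


def bias_percent(bmap: BMap) -> ImageVolume:
    """Percent b-value bias map: 100 * ((v / 1E4) - 1); zero at isocenter."""
    beta = 100.0 * (bmap.volume.data / BMAP_SCALE - 1.0)
    return bmap.volume.copy_geometry(beta, units="percent")


def fit_adc(dwi: DWISeries, mask: np.ndarray | None = None) -> ADCVolume:
    """Two-point mono-exponential trace ADC in um^2/ms.

    ADC = ln(S0 / S_b) / b  (mm^2/s), converted to um^2/ms (x 1000).
    Non-positive signals inside the mask are excluded (counted and logged);
    voxels with S_b >= S0 yield a 0-floored ADC and stay flagged in the mask.
    """
    s0 = dwi.s0.data.astype(float)
    sb = dwi.dw.data.astype(float)
    positive = (s0 > 0) & (sb > 0)
    if mask is None:
        # default object mask: voxels with signal; no exclusions to report
        mask = positive
        n_excluded = 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != s0.shape:
            raise ValueError("mask shape does not match the DWI grid")
        n_excluded = int(np.sum(mask & ~positive))
        if n_excluded:
            log.warning("fit_adc: %d masked voxel(s) with non-positive signal "
                        "excluded", n_excluded)
    valid = mask & positive
    adc = np.zeros(s0.shape, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[valid] = np.log(s0[valid] / sb[valid]) / dwi.b_nominal * 1000.0
    floored = valid & (adc < 0)
    adc[floored] = 0.0
    vol = dwi.s0.copy_geometry(adc, units="um2/ms")
    return ADCVolume(volume=vol, mask=valid, corrected=False,
                     n_floored=int(floored.sum()), n_excluded=n_excluded)


def apply_gnc(adc: ADCVolume, bmap: BMap) -> ADCVolume:
    """Gradient-nonlinearity correction: ADC_GNC = ADC / (v / 1E4) voxelwise.

    Exact for isotropic media, where the measured trace ADC is c_bar * ADC_true.
    """
    if not adc.volume.same_geometry(bmap.volume):
        raise ValueError("ADC and b-map grids are not aligned")
    cbar = bmap.cbar
    if np.any(cbar <= 0):
        raise ValueError("b-map contains non-positive values")
    out = adc.volume.copy_geometry(adc.volume.data / cbar, units="um2/ms")
    return ADCVolume(volume=out, mask=adc.mask.copy(), corrected=True,
                     n_floored=adc.n_floored, n_excluded=adc.n_excluded)


def fractional_adc_bias(adc: ADCVolume, adc_gnc: ADCVolume) -> tuple[ImageVolume, np.ndarray]:
    """Fractional ADC bias in percent: 100 * (ADC - ADC_GNC) / ADC_GNC.

    Returns the percent map and its validity mask (voxels where ADC_GNC = 0
    are excluded).  On a noiseless uniform phantom this equals the model
    percent bias map voxelwise.
    """
    if not adc.volume.same_geometry(adc_gnc.volume):
        raise ValueError("ADC volumes are not aligned")
    a, g = adc.volume.data, adc_gnc.volume.data
    mask = adc.mask & adc_gnc.mask & (g != 0)
    out = np.zeros_like(a, dtype=float)
    out[mask] = 100.0 * (a[mask] - g[mask]) / g[mask]
    return adc.volume.copy_geometry(out, units="percent"), mask


def median_smooth3(vol: ImageVolume, axes: tuple[int, ...] = (1, 2)) -> ImageVolume:
    """3-point median filter applied sequentially along the given array axes.

    Default axes (1, 2) are the in-plane (y, x) directions of the [z, y, x]
    array.  Edge voxels use nearest-neighbor (replicate) padding.  This is a
    display aid only and is never applied before statistics.
    """
    data = vol.data
    for ax in axes:
        size = [1, 1, 1]
        size[ax] = 3
        data = ndimage.median_filter(data, size=tuple(size), mode="nearest")
    return vol.copy_geometry(data, units=vol.units)


def crop(vol: ImageVolume, zslice: slice, yslice: slice, xslice: slice) -> ImageVolume:
    """Axis-aligned crop that keeps the physical geometry consistent."""
    start = [s.start or 0 for s in (xslice, yslice, zslice)]
    new_origin = tuple(
        o + st * sp for o, st, sp in zip(vol.origin, start, vol.spacing)
    )
    return ImageVolume(
        data=vol.data[zslice, yslice, xslice].copy(),
        origin=new_origin, spacing=vol.spacing, units=vol.units,
        direction=vol.direction.copy(), meta=dict(vol.meta),
    )
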