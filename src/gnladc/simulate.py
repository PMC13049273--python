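"""Synthetic phantom and virtual myelofibrosis cohort generation.

The generator produces everything the downstream analysis consumes without
any external data:

* a uniform torso-size gel phantom DWI (b = 0 / b = 800 s/mm^2) whose
  diffusion-weighted signal carries the spatial b-value bias of a coil
  model, for phantom-style validation of the correction;
* a virtual cohort of subjects with ellipsoidal bone-site ROIs (bilateral
  trochanter and ilium, T11-S1 vertebral bodies) imaged in two stations
  with distinct table offsets, fat-fraction-dependent water signal,
  Rician noise, and per-timepoint repositioning jitter including
  occasional one-vertebra landmark shifts.

Signal model per diffusion direction k:  S_k = S0 exp(-b c_k(r) D_true),
with c_k the per-direction b-value corrector of the coil model; the trace
DW image is the geometric mean over the three orthogonal directions.
Rician noise is applied as the magnitude of a complex Gaussian
perturbation of each direction image before trace formation, which
reproduces the low-CNR histogram truncation seen at high fat fraction.

All randomness flows from explicit seeds: identical spec + seed give
identical volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coil import CoilModel, DirectionSet, direction_corrector
from .gnc import DWISeries, _offset_vector
from .volume import ImageVolume, ROILabelMap, SITE_LABELS

log = logging.getLogger(__name__)

UM2MS_TO_MM2S = 1e-3  # 1 um^2/ms = 1e-3 mm^2/s


def _grid(origin_mm, spacing_mm, size, units="a.u.", dtype=np.float32) -> ImageVolume:
    nx, ny, nz = size
    return ImageVolume(
        data=np.zeros((nz, ny, nx), dtype=dtype),
        origin=origin_mm, spacing=spacing_mm, units=units,
    )


def _rician(rng: np.random.Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    """Magnitude of a complex Gaussian perturbation of ``signal``."""
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def _direction_correctors(
    model: CoilModel, pts: np.ndarray, dirs: DirectionSet
) -> list[np.ndarray]:
    L = model.jacobian(pts)
    return [direction_corrector(L, u) for u in dirs.u]


# station grids and table offsets are fixed in the table frame, so the
# field evaluation is identical for every subject/timepoint: memoize it
_CK_CACHE: dict[tuple, list[np.ndarray]] = {}


def _station_correctors(
    model: CoilModel, station: int, spacing: float, table_offset: float,
    dirs: DirectionSet,
) -> list[np.ndarray]:
    key = (model.cache_key, station, spacing, table_offset,
           dirs.u.tobytes())
    if key not in _CK_CACHE:
        grid = _station_grid(station, spacing)
        pts = grid.physical_points() + _offset_vector(table_offset)
        if len(_CK_CACHE) > 8:
            _CK_CACHE.clear()
        _CK_CACHE[key] = _direction_correctors(model, pts, dirs)
    return _CK_CACHE[key]


# =========================================================================
# phantom
# =========================================================================


@dataclass(frozen=True)
class PhantomSpec:
    """Uniform torso-size gel phantom imaged as a coronal slab.

    The default preset is a sodium polyacrylate gel at room temperature
    (reference diffusivity 2.13 um^2/ms) in an oblong shell, with a
    400 (S-I) x 200 (R-L) mm^2 coronal field of view.
    """

    shell_semiaxes_mm: tuple[float, float, float] = (90.0, 60.0, 180.0)
    fov_mm: tuple[float, float] = (200.0, 400.0)    # (R-L, S-I)
    spacing_mm: float = 2.0
    n_slices: int = 3                               # A-P slab thickness
    true_adc: float = 2.13                          # um^2/ms
    s0: float = 500.0
    noise_sigma: float = 0.0
    b_value: float = 800.0                          # s/mm^2

    def __post_init__(self) -> None:
        if self.true_adc <= 0:
            raise ValueError("true diffusivity must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.spacing_mm <= 0 or min(self.fov_mm) <= 0:
            raise ValueError("FOV and spacing must be positive")

    @classmethod
    def spag_room_temperature(cls, **overrides) -> "PhantomSpec":
        return replace(cls(), **overrides)


@dataclass
class PhantomData:
    dwi: DWISeries
    truth: "ADCVolumeLike"
    mask: np.ndarray


@dataclass
class ADCVolumeLike:
    """Ground-truth ADC on the simulation grid (same fields as a fit result)."""

    volume: ImageVolume
    mask: np.ndarray


def phantom_grid(spec: PhantomSpec) -> ImageVolume:
    sp = spec.spacing_mm
    nx = int(round(spec.fov_mm[0] / sp))
    nz = int(round(spec.fov_mm[1] / sp))
    ny = spec.n_slices
    origin = (
        -spec.fov_mm[0] / 2 + sp / 2,
        -(ny * sp) / 2 + sp / 2,
        -spec.fov_mm[1] / 2 + sp / 2,
    )
    return _grid(origin, (sp, sp, sp), (nx, ny, nz))


def generate_phantom(
    spec: PhantomSpec,
    model: CoilModel,
    seed: int | None = None,
    dirs: DirectionSet | None = None,
    apply_bias: bool = True,
) -> PhantomData:
    """Simulate a b=0 / trace-DW pair of the uniform phantom.

    With ``apply_bias=False`` the diffusion weighting is spatially uniform
    (ideal linear gradients) regardless of ``model``.
    """
    if dirs is None:
        dirs = DirectionSet.axes()
    grid = phantom_grid(spec)
    pts = grid.physical_points()
    a, b_, c = spec.shell_semiaxes_mm
    mask = (
        (pts[..., 0] / a) ** 2 + (pts[..., 1] / b_) ** 2 + (pts[..., 2] / c) ** 2
    ) <= 1.0

    if apply_bias:
        cks = _direction_correctors(model, pts, dirs)
    else:
        cks = [np.ones(mask.shape)] * 3

    d_mm2s = spec.true_adc * UM2MS_TO_MM2S
    s0 = np.where(mask, spec.s0, 0.0)
    dir_imgs = [s0 * np.exp(-spec.b_value * ck * d_mm2s) for ck in cks]

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        s0 = _rician(rng, s0, spec.noise_sigma)
        dir_imgs = [_rician(rng, im, spec.noise_sigma) for im in dir_imgs]

    dw = np.cbrt(dir_imgs[0] * dir_imgs[1] * dir_imgs[2])  # geometric mean

    s0_vol = grid.copy_geometry(s0.astype(np.float32), units="a.u.")
    dw_vol = grid.copy_geometry(dw.astype(np.float32), units="a.u.")
    truth = grid.copy_geometry(
        np.where(mask, spec.true_adc, 0.0).astype(np.float32), units="um2/ms"
    )
    dwi = DWISeries(s0=s0_vol, dw=dw_vol, b_nominal=spec.b_value,
                    directions=dirs, table_offset=0.0)
    return PhantomData(dwi=dwi, truth=ADCVolumeLike(volume=truth, mask=mask), mask=mask)


# =========================================================================
# subjects
# =========================================================================

#: site -> imaging station (0 = lumbar spine, 1 = pelvis / proximal femur)
STATION_OF_SITE: dict[str, int] = {
    "T11": 0, "T12": 0, "L1": 0, "L2": 0, "L3": 0, "L4": 0, "L5": 0, "S1": 0,
    "RT": 1, "LT": 1, "RI": 1, "LI": 1,
}

#: default ellipsoid volumes (cm^3) used for the factor-3 sanity check
_DEFAULT_VOLUMES_CM3 = {"T": 88.3, "I": 72.4, "V": 21.0}

VERTEBRA_PITCH_MM = 32.0


@dataclass(frozen=True)
class SiteSpec:
    """One ellipsoidal bone-site ROI in the patient frame (L3-centered)."""

    label: str
    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]
    true_adc: float           # um^2/ms
    fat_fraction: float       # [0, 1]

    def __post_init__(self) -> None:
        if self.label not in SITE_LABELS:
            raise ValueError(f"unknown site label {self.label!r}")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError("fat fraction must be in [0, 1]")
        if self.true_adc <= 0:
            raise ValueError("true ADC must be positive")

    @property
    def volume_cm3(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.semiaxes_mm)) / 1000.0


def default_sites(
    adc: dict[str, float] | None = None,
    fat_fraction: dict[str, float] | None = None,
    include_t11: bool = False,
) -> list[SiteSpec]:
    """Anatomically plausible default site geometry.

    Trochanters sit ~102 mm lateral and 120 mm inferior of L3, ilia ~52 mm
    lateral; vertebral bodies lie on the midline at 32 mm S-I pitch with L3
    at the patient-frame origin.
    """
    adc = adc or {}
    ff = fat_fraction or {}
    geom: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
        "RT": ((-102.0, 0.0, -120.0), (38.0, 28.0, 20.0)),
        "LT": ((102.0, 0.0, -120.0), (38.0, 28.0, 20.0)),
        "RI": ((-52.0, 30.0, -95.0), (30.0, 24.0, 24.0)),
        "LI": ((52.0, 30.0, -95.0), (30.0, 24.0, 24.0)),
    }
    verts = ["T12", "L1", "L2", "L3", "L4", "L5", "S1"]
    if include_t11:
        verts = ["T11"] + verts
    z0 = {"T11": 128.0, "T12": 96.0, "L1": 64.0, "L2": 32.0, "L3": 0.0,
          "L4": -32.0, "L5": -64.0, "S1": -96.0}
    for v in verts:
        geom[v] = ((0.0, -40.0, z0[v]), (18.5, 18.5, 15.0))
    sites = []
    for label, (center, semi) in geom.items():
        sites.append(SiteSpec(
            label=label, center_mm=center, semiaxes_mm=semi,
            true_adc=adc.get(label, 0.6), fat_fraction=ff.get(label, 0.2),
        ))
    return sites


@dataclass(frozen=True)
class SubjectSpec:
    """One virtual subject: site geometry/truths plus positioning."""

    sites: tuple[SiteSpec, ...]
    station_offsets_mm: tuple[float, float] = (10.0, 130.0)  # table -> magnet S-I
    positioning_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mf_grade: int = 2
    sex: str = "F"
    age: float = 60.0
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        sep = abs(self.station_offsets_mm[1] - self.station_offsets_mm[0])
        if not 100.0 <= sep <= 240.0:
            raise ValueError(
                f"station separation {sep:.0f} mm outside the plausible "
                "100-240 mm couch-offset range"
            )
        # site volumes within factor 3 of the defaults
        for s in self.sites:
            key = "T" if s.label.endswith("T") else (
                "I" if s.label.endswith("I") and len(s.label) == 2 else "V")
            ref = _DEFAULT_VOLUMES_CM3[key]
            if not ref / 3.0 <= s.volume_cm3 <= ref * 3.0:
                raise ValueError(
                    f"{s.label} volume {s.volume_cm3:.1f} cm^3 outside factor-3 "
                    f"band of the {ref} cm^3 default"
                )
        # vertebra centers ordered superior -> inferior
        order = ["T11", "T12", "L1", "L2", "L3", "L4", "L5", "S1"]
        zs = [s.center_mm[2] for v in order for s in self.sites if s.label == v]
        if any(a <= b for a, b in zip(zs, zs[1:])):
            raise ValueError("vertebra centers must be ordered along S-I")


@dataclass
class StationScan:
    """One station of one scan: DWI pair, labels, and voxelwise truth."""

    dwi: DWISeries
    labels: ROILabelMap
    truth_adc: ImageVolume
    table_offset_mm: float
    station: int


@dataclass
class SubjectScan:
    """One timepoint of one subject (both stations)."""

    spec: SubjectSpec
    stations: list[StationScan]
    positioning_offset_mm: tuple[float, float, float]
    timepoint: int = 0


@dataclass(frozen=True)
class AcquisitionSpec:
    """Shared imaging parameters of the virtual scanner."""

    spacing_mm: float = 3.0
    s0_level: float = 500.0
    snr0: float = 150.0          # b=0 SNR before fat scaling; 0 disables noise
    b_value: float = 800.0

    @property
    def noise_sigma(self) -> float:
        return 0.0 if self.snr0 <= 0 else self.s0_level / self.snr0


def _station_grid(station: int, spacing: float) -> ImageVolume:
    if station == 0:     # lumbar spine
        ext = ((-135.0, 135.0), (-75.0, 75.0), (-160.0, 170.0))
    else:                # pelvis / proximal femur
        ext = ((-168.0, 168.0), (-75.0, 75.0), (-180.0, -40.0))
    size = tuple(int(round((hi - lo) / spacing)) for lo, hi in ext)
    origin = tuple(lo + spacing / 2 for lo, _ in ext)
    return _grid(origin, (spacing,) * 3, size)


def generate_subject(
    spec: SubjectSpec,
    model: CoilModel,
    acq: AcquisitionSpec | None = None,
    seed: int | None = None,
    dirs: DirectionSet | None = None,
    timepoint: int = 0,
) -> SubjectScan:
    """Rasterize the subject's ROIs on both station grids and simulate DWI.

    Water signal is scaled by (1 - FF) per site, so high-fat sites have low
    contrast-to-noise; the positioning offset shifts all sites within the
    (table-fixed) grids, changing their magnet-frame bias.
    """
    acq = acq or AcquisitionSpec()
    if dirs is None:
        dirs = DirectionSet.axes()
    rng = np.random.default_rng(seed)
    off = np.asarray(spec.positioning_offset_mm, dtype=float)
    stations: list[StationScan] = []
    for st in (0, 1):
        grid = _station_grid(st, acq.spacing_mm)
        pts = grid.physical_points()
        labels = np.zeros(grid.data.shape, dtype=np.int16)
        truth = np.zeros(grid.data.shape, dtype=np.float32)
        ffmap = np.zeros(grid.data.shape, dtype=np.float32)
        for s in spec.sites:
            if STATION_OF_SITE[s.label] != st:
                continue
            ctr = np.asarray(s.center_mm) + off
            rel = (pts - ctr) / np.asarray(s.semiaxes_mm)
            inside = np.einsum("...a,...a->...", rel, rel) <= 1.0
            if np.any(labels[inside] != 0):
                raise ValueError(f"ROI {s.label} overlaps another site")
            labels[inside] = SITE_LABELS[s.label]
            truth[inside] = s.true_adc
            ffmap[inside] = s.fat_fraction
        table_offset = spec.station_offsets_mm[st]
        cks = _station_correctors(model, st, acq.spacing_mm, table_offset, dirs)

        s0 = np.where(labels > 0, acq.s0_level * (1.0 - ffmap), 0.0)
        d_mm2s = truth.astype(float) * UM2MS_TO_MM2S
        dir_imgs = [s0 * np.exp(-acq.b_value * ck * d_mm2s) for ck in cks]
        if acq.noise_sigma > 0:
            s0 = _rician(rng, s0, acq.noise_sigma)
            dir_imgs = [_rician(rng, im, acq.noise_sigma) for im in dir_imgs]
        dw = np.cbrt(dir_imgs[0] * dir_imgs[1] * dir_imgs[2])

        s0_vol = grid.copy_geometry(s0.astype(np.float32), units="a.u.")
        dw_vol = grid.copy_geometry(dw.astype(np.float32), units="a.u.")
        for v in (s0_vol, dw_vol):
            v.meta["TableOffset"] = f"0 0 {table_offset:g}"
            v.meta["BNominal"] = f"{acq.b_value:g}"
        dwi = DWISeries(
            s0=s0_vol, dw=dw_vol,
            b_nominal=acq.b_value, directions=dirs, table_offset=table_offset,
        )
        lm = ROILabelMap(
            volume=grid.copy_geometry(labels, units="label"),
            labels=dict(SITE_LABELS),
        )
        stations.append(StationScan(
            dwi=dwi, labels=lm,
            truth_adc=grid.copy_geometry(truth, units="um2/ms"),
            table_offset_mm=table_offset, station=st,
        ))
    return SubjectScan(spec=spec, stations=stations,
                       positioning_offset_mm=tuple(off), timepoint=timepoint)


# =========================================================================
# cohort
# =========================================================================


@dataclass(frozen=True)
class CohortSpec:
    """Virtual cohort: size, truth model, fat fractions, and repositioning.

    Site-level true-ADC bases are the corrected group means of the study
    population this generator emulates (trochanter 0.519, ilium 0.628,
    mid-vertebrae 0.577, edge-vertebrae 0.591 um^2/ms); each subject adds a
    common offset (between-subject heterogeneity) plus per-site scatter,
    and ilium ADC carries a fibrosis-grade slope so grade correlations are
    recoverable.  Repositioning jitter defaults (sigma 8/6/12 mm R-L/A-P/S-I
    plus a 0.5-probability one-vertebra landmark shift) emulate longitudinal
    positioning variability; they are tunable, not ground truth.
    """

    n_subjects: int = 20
    n_timepoints: int = 2
    seed: int = 0
    jitter_sigma_mm: tuple[float, float, float] = (8.0, 6.0, 12.0)
    vertebra_shift_prob: float = 0.5
    vertebra_pitch_mm: float = VERTEBRA_PITCH_MM
    subject_offset_sigma_mm: tuple[float, float, float] = (10.0, 6.0, 8.0)
    adc_bases: tuple[tuple[str, float], ...] = (
        ("T", 0.519), ("I", 0.628), ("MV", 0.577), ("EV", 0.591),
    )
    subject_adc_sigma: float = 0.10
    site_adc_sigma: float = 0.03
    ilium_grade_slope: float = 0.05       # um^2/ms per grade step
    n_low_ff: int | None = None           # subjects with ilium FF < 0.40
    ff_low_range: tuple[float, float] = (0.04, 0.38)
    ff_high_range: tuple[float, float] = (0.46, 0.73)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_timepoints < 1:
            raise ValueError("cohort needs at least one subject and timepoint")
        if not 0.0 <= self.vertebra_shift_prob <= 1.0:
            raise ValueError("vertebra shift probability must be in [0, 1]")
        if any(s < 0 for s in self.jitter_sigma_mm):
            raise ValueError("jitter sigmas must be >= 0")


@dataclass
class CohortData:
    """Generated cohort: per-subject scan series plus truth tables."""

    spec: CohortSpec
    scans: list[list[SubjectScan]]        # [subject][timepoint]
    truth: pd.DataFrame                   # subject x site truths
    subjects: list[SubjectSpec]


_SITE_GROUP = {
    "RT": "T", "LT": "T", "RI": "I", "LI": "I",
    "L2": "MV", "L3": "MV", "L4": "MV",
    "T11": "EV", "T12": "EV", "L1": "EV", "L5": "EV", "S1": "EV",
}


def generate_cohort(spec: CohortSpec, model: CoilModel) -> CohortData:
    """Draw subject truths from the cohort model and simulate every scan."""
    rng = np.random.default_rng(spec.seed)
    bases = dict(spec.adc_bases)
    n_low = spec.n_low_ff
    if n_low is None:
        n_low = int(round(0.55 * spec.n_subjects))
    n_low = min(n_low, spec.n_subjects)
    low_ids = rng.permutation(spec.n_subjects)[:n_low]

    subjects: list[SubjectSpec] = []
    scans: list[list[SubjectScan]] = []
    truth_rows = []
    for i in range(spec.n_subjects):
        grade = int(rng.integers(1, 4))
        sex = "F" if rng.random() < 2.0 / 3.0 else "M"
        age = float(np.clip(rng.normal(60.0, 10.0), 30.0, 85.0))
        subj_delta = rng.normal(0.0, spec.subject_adc_sigma)
        if i in low_ids:
            ff_ilium = float(rng.uniform(*spec.ff_low_range))
        else:
            ff_ilium = float(rng.uniform(*spec.ff_high_range))
        base_off = rng.normal(0.0, spec.subject_offset_sigma_mm)

        site_adc, site_ff = {}, {}
        for label, group in _SITE_GROUP.items():
            a = bases[group] + subj_delta + rng.normal(0.0, spec.site_adc_sigma)
            if group == "I":
                a += spec.ilium_grade_slope * (grade - 2)
            site_adc[label] = float(np.clip(a, 0.10, 3.0))
            factor = {"T": 1.3, "I": 1.0}.get(group, 0.8)
            site_ff[label] = float(np.clip(ff_ilium * factor, 0.0, 0.85))

        subj = SubjectSpec(
            sites=tuple(default_sites(adc=site_adc, fat_fraction=site_ff)),
            positioning_offset_mm=tuple(base_off),
            mf_grade=grade, sex=sex, age=age, subject_id=f"S{i:02d}",
        )
        subjects.append(subj)
        for s in subj.sites:
            truth_rows.append({
                "subject": subj.subject_id, "site": s.label,
                "group": _SITE_GROUP[s.label], "true_adc": s.true_adc,
                "fat_fraction": s.fat_fraction, "mf_grade": grade,
                "sex": sex, "age": age,
            })

        series = []
        for t in range(spec.n_timepoints):
            jit = rng.normal(0.0, spec.jitter_sigma_mm)
            if rng.random() < spec.vertebra_shift_prob:
                jit[2] += spec.vertebra_pitch_mm * (1 if rng.random() < 0.5 else -1)
            tp_spec = replace(
                subj, positioning_offset_mm=tuple(np.asarray(base_off) + jit)
            )
            scan_seed = int(rng.integers(0, 2**31 - 1))
            series.append(generate_subject(
                tp_spec, model, acq=spec.acquisition, seed=scan_seed, timepoint=t
            ))
        scans.append(series)

    return CohortData(
        spec=spec, scans=scans, truth=pd.DataFrame(truth_rows), subjects=subjects
    )
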