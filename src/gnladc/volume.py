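"""3D scalar volumes, ROI label maps, and MetaImage (MHD) I/O.

Coordinate convention: right-handed magnet frame, origin at isocenter,
millimetres; +x = patient left (R-L), +y = posterior->anterior (A-P),
+z = superior (S-I).  Arrays are indexed ``[z, y, x]`` (the SimpleITK
``GetArrayFromImage`` order); ``origin`` and ``spacing`` are given in
``(x, y, z)`` order as in the MHD header.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import SimpleITK as sitk

log = logging.getLogger(__name__)

#: canonical bone-site label dictionary (0 is background)
SITE_LABELS: dict[str, int] = {
    "RT": 1, "LT": 2, "RI": 3, "LI": 4,
    "T11": 5, "T12": 6,
    "L1": 7, "L2": 8, "L3": 9, "L4": 10, "L5": 11,
    "S1": 12,
}

VALID_UNITS = ("um2/ms", "dimensionless", "percent", "a.u.", "label")


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical geometry and a mandatory units tag."""

    data: np.ndarray                       # [z, y, x]
    origin: tuple[float, float, float]     # (x0, y0, z0) mm
    spacing: tuple[float, float, float]    # (sx, sy, sz) mm, > 0
    units: str
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.origin = tuple(float(v) for v in self.origin)
        self.spacing = tuple(float(v) for v in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not self.units:
            raise ValueError("a units tag is mandatory")
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)

    # -- geometry ---------------------------------------------------------

    @property
    def size(self) -> tuple[int, int, int]:
        """Grid size in (nx, ny, nz) order."""
        nz, ny, nx = self.data.shape
        return nx, ny, nz

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) ``(ix, iy, iz)`` indices to physical mm points."""
        idx = np.asarray(idx, dtype=float)
        local = idx * np.asarray(self.spacing)
        return np.asarray(self.origin) + local @ self.direction.T

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        local = (pts - np.asarray(self.origin)) @ np.linalg.inv(self.direction).T
        return local / np.asarray(self.spacing)

    def physical_points(self) -> np.ndarray:
        """Voxel-center coordinates, shape ``data.shape + (3,)`` in (x,y,z)."""
        nz, ny, nx = self.data.shape
        iz, iy, ix = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        idx = np.stack([ix, iy, iz], axis=-1)
        return self.index_to_physical(idx)

    def same_geometry(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def copy_geometry(self, data: np.ndarray, units: str) -> "ImageVolume":
        """New volume on this grid with different voxel data/units."""
        return ImageVolume(
            data=data, origin=self.origin, spacing=self.spacing,
            units=units, direction=self.direction.copy(), meta=dict(self.meta),
        )

    # -- SimpleITK bridge -------------------------------------------------

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(self.data)
        img.SetOrigin(self.origin)
        img.SetSpacing(self.spacing)
        img.SetDirection(tuple(self.direction.flatten()))
        img.SetMetaData("Units", self.units)
        for k, v in self.meta.items():
            img.SetMetaData(str(k), str(v))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, units: str | None = None) -> "ImageVolume":
        meta = {k: img.GetMetaData(k) for k in img.GetMetaDataKeys()}
        tag = units or meta.pop("Units", None)
        meta.pop("Units", None)
        if tag is None:
            raise ValueError("image carries no Units tag; pass units= explicitly")
        return cls(
            data=sitk.GetArrayFromImage(img),
            origin=img.GetOrigin(),
            spacing=img.GetSpacing(),
            units=tag,
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
            meta=meta,
        )


def read_mhd(path: str | Path, units: str | None = None) -> ImageVolume:
    """Read a MetaImage header/raw pair into an :class:`ImageVolume`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # malformed header / size mismatch
        raise ValueError(f"cannot read MetaImage {path}: {exc}") from exc
    return ImageVolume.from_sitk(img, units=units)


def write_mhd(vol: ImageVolume, path: str | Path) -> Path:
    """Write ``vol`` losslessly as an uncompressed MHD/raw pair."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(vol.to_sitk(), str(path), useCompression=False)
    return path


# -- ROI label maps -------------------------------------------------------


@dataclass
class ROILabelMap:
    """Integer label volume plus a site-name <-> integer dictionary."""

    volume: ImageVolume
    labels: dict[str, int]

    def __post_init__(self) -> None:
        if not np.issubdtype(self.volume.data.dtype, np.integer):
            raise ValueError("label map must hold integer data")
        present = set(np.unique(self.volume.data)) - {0}
        known = set(self.labels.values())
        unknown = present - known
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in dictionary")

    def mask(self, site: str) -> np.ndarray:
        if site not in self.labels:
            raise KeyError(f"unknown site label {site!r}")
        return self.volume.data == self.labels[site]

    def present_sites(self) -> list[str]:
        present = set(np.unique(self.volume.data))
        return [s for s, v in self.labels.items() if v in present]


def write_labelmap(lm: ROILabelMap, path: str | Path) -> Path:
    path = write_mhd(lm.volume, path)
    sidecar = path.with_suffix(".labels.json")
    sidecar.write_text(json.dumps(lm.labels, indent=1))
    return path


def read_labelmap(path: str | Path) -> ROILabelMap:
    path = Path(path)
    vol = read_mhd(path, units="label")
    sidecar = path.with_suffix(".labels.json")
    labels = json.loads(sidecar.read_text()) if sidecar.exists() else dict(SITE_LABELS)
    return ROILabelMap(volume=vol, labels=labels)


# -- display-value (rescale) scaling --------------------------------------


def apply_display_scaling(
    stored: np.ndarray, slope: float, intercept: float = 0.0
) -> np.ndarray:
    """Map stored integers to physical values: ``physical = slope*stored + intercept``.

    The b-map convention is ``slope=1e-4, intercept=0`` (stored 10000 at
    isocenter -> dimensionless 1.0).
    """
    slope = float(slope)
    if not np.isfinite(slope) or slope == 0.0:
        raise ValueError(f"rescale slope must be finite and non-zero, got {slope}")
    if not np.isfinite(intercept):
        raise ValueError("rescale intercept must be finite")
    return np.asarray(stored) * slope + intercept


def invert_display_scaling(
    physical: np.ndarray, slope: float, intercept: float = 0.0,
    round_to_int: bool = False,
) -> np.ndarray:
    """Inverse of :func:`apply_display_scaling`, for writing stored values."""
    slope = float(slope)
    if not np.isfinite(slope) or slope == 0.0:
        raise ValueError(f"rescale slope must be finite and non-zero, got {slope}")
    stored = (np.asarray(physical) - intercept) / slope
    if round_to_int:
        stored = np.rint(stored).astype(np.int64)
    return stored
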