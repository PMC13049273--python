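"""Gradient-coil field model, GNL tensor, and b-value correctors.

Each physical gradient coil (x, y, z) produces a field whose spatial
dependence is expanded in real solid harmonics,

    f_a(r) = sum_terms  C_{n,m} * N_nm * r^n P_n^m(cos th) {cos,sin}(m ph) / R0^(n-1),

with Schmidt semi-normalized associated Legendre functions (no
Condon-Shortley phase) and a reference radius R0 that keeps the expansion
coefficients dimensionless.  The field is normalized by the nominal
gradient, so the first-order term of each coil reproduces the ideal linear
ramp and the gradient of f_a at the isocenter is the unit vector along
axis a.

The gradient-nonlinearity (GNL) tensor is the Jacobian

    L_ab(r) = d f_a / d x_b ,     L(0) = I,

which maps nominal to actual gradient vectors.  For a diffusion direction
u the actual b-value is scaled by c = u^T (L^T L) u, and for a trace
acquisition over an orthonormal triad the scale is the triad-independent
c_bar = tr(L^T L)/3.

Harmonic terms are assembled symbolically as Cartesian polynomials and
lambdified to numpy, so all spatial derivatives are analytic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache, cached_property
from math import factorial
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import sympy as sp
import yaml

AXES = ("x", "y", "z")

#: factor on R0 beyond which the truncated expansion is not trusted
VALIDITY_FACTOR = 1.5


class CoilTerm(NamedTuple):
    n: int          # order  >= 1
    m: int          # degree, 0 <= m <= n
    kind: str       # "cos" | "sin"
    coeff: float    # dimensionless


@lru_cache(maxsize=None)
def _solid_harmonic_expr(n: int, m: int, kind: str) -> sp.Expr:
    """Real Schmidt semi-normalized solid harmonic as an (x, y, z) polynomial.

    r^n P_n^m(cos th) cos/sin(m ph) written in Cartesian form:
    the azimuthal factor (r sin th)^m {cos,sin}(m ph) is Re/Im((x+iy)^m) and
    r^(n-m) d^m P_n/du^m (z/r) is a polynomial in z and r^2 by parity.
    """
    x, y, z = sp.symbols("x y z", real=True)
    u = sp.Symbol("u")
    g = sp.Poly(sp.diff(sp.legendre(n, u), u, m), u)
    r2 = x**2 + y**2 + z**2
    radial = sp.Integer(0)
    for (k,), c in g.terms():
        e = n - m - k
        assert e % 2 == 0, "parity of the Legendre derivative"
        radial += c * z**k * r2 ** (e // 2)
    az = sp.expand((x + sp.I * y) ** m)
    az = sp.re(az) if kind == "cos" else sp.im(az)
    norm = 1 if m == 0 else sp.sqrt(sp.Integer(2) * factorial(n - m) / factorial(n + m))
    return sp.expand(norm * az * radial)


_LINEAR_TERMS: dict[str, tuple[CoilTerm, ...]] = {
    "x": (CoilTerm(1, 1, "cos", 1.0),),
    "y": (CoilTerm(1, 1, "sin", 1.0),),
    "z": (CoilTerm(1, 0, "cos", 1.0),),
}


@dataclass(frozen=True)
class CoilModel:
    """Solid-harmonic expansion of the three gradient-coil fields.

    ``terms`` maps coil axis -> list of (n, m, cos|sin, coefficient); axes
    that are omitted default to the ideal linear term.  ``r0_mm`` is the
    reference radius of the expansion.
    """

    terms: dict[str, tuple[CoilTerm, ...]]
    r0_mm: float = 250.0
    name: str = "unnamed"

    def __post_init__(self) -> None:
        full: dict[str, tuple[CoilTerm, ...]] = {}
        for ax in AXES:
            tl = self.terms.get(ax, _LINEAR_TERMS[ax])
            tl = tuple(CoilTerm(int(n), int(m), str(kind), float(c)) for n, m, kind, c in tl)
            for t in tl:
                if t.n < 1 or not (0 <= t.m <= t.n):
                    raise ValueError(f"invalid harmonic order/degree (n={t.n}, m={t.m})")
                if t.kind not in ("cos", "sin"):
                    raise ValueError(f"term kind must be cos|sin, got {t.kind!r}")
                if not np.isfinite(t.coeff):
                    raise ValueError(f"non-finite coefficient in {ax} coil: {t}")
                if t.kind == "sin" and t.m == 0:
                    raise ValueError("sin terms require m >= 1")
            full[ax] = tl
        object.__setattr__(self, "terms", full)
        if not np.isfinite(self.r0_mm) or self.r0_mm <= 0:
            raise ValueError(f"R0 must be positive and finite, got {self.r0_mm}")
        # normalization contract: gradient of f_a at the origin is e_a
        J0 = self.jacobian(np.zeros(3))
        if not np.allclose(J0, np.eye(3), atol=1e-9):
            raise ValueError(
                "coil model violates normalization: grad f_a(0) != e_a "
                f"(got\n{J0})"
            )

    @property
    def validity_radius_mm(self) -> float:
        return VALIDITY_FACTOR * self.r0_mm

    @property
    def cache_key(self) -> tuple:
        """Hashable identity of the model (for memoizing field evaluations)."""
        return (
            self.name, self.r0_mm,
            tuple((ax, self.terms[ax]) for ax in AXES),
        )

    @cached_property
    def _callables(self):
        x, y, z = sp.symbols("x y z", real=True)
        out = {}
        for ax in AXES:
            expr = sp.Integer(0)
            for t in self.terms[ax]:
                expr += t.coeff * _solid_harmonic_expr(t.n, t.m, t.kind) / self.r0_mm ** (t.n - 1)
            expr = sp.expand(expr)
            f = sp.lambdify((x, y, z), expr, "numpy")
            df = [sp.lambdify((x, y, z), sp.diff(expr, v), "numpy") for v in (x, y, z)]
            out[ax] = (f, df)
        return out

    # -- evaluation -------------------------------------------------------

    def _split(self, points: np.ndarray):
        pts = np.asarray(points, dtype=float)
        if pts.shape[-1] != 3:
            raise ValueError("points must have trailing dimension 3 (x, y, z in mm)")
        return pts[..., 0], pts[..., 1], pts[..., 2]

    def _out_of_range(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return np.linalg.norm(pts, axis=-1) > self.validity_radius_mm

    def field(self, axis: str, points: np.ndarray, out_of_range: str = "nan") -> np.ndarray:
        """Normalized field f_a at ``points`` (mm); see :func:`evaluate_field`."""
        if axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
        px, py, pz = self._split(points)
        vals = np.asarray(self._callables[axis][0](px, py, pz), dtype=float)
        vals = np.broadcast_to(vals, px.shape).copy() if vals.shape != px.shape else vals
        bad = self._out_of_range(points)
        if np.any(bad):
            if out_of_range == "raise":
                raise ValueError(
                    f"{int(np.sum(bad))} point(s) beyond validity radius "
                    f"{self.validity_radius_mm:.0f} mm"
                )
            warnings.warn(
                "points beyond the coil-model validity radius were flagged NaN",
                stacklevel=2,
            )
            vals = np.where(bad, np.nan, vals)
        return vals

    def jacobian(self, points: np.ndarray) -> np.ndarray:
        """GNL tensor L_ab = df_a/dx_b at ``points``; shape ``points.shape[:-1] + (3, 3)``."""
        px, py, pz = self._split(points)
        rows = []
        for ax in AXES:
            _, df = self._callables[ax]
            row = [np.broadcast_to(np.asarray(d(px, py, pz), dtype=float), px.shape)
                   for d in df]
            rows.append(np.stack(row, axis=-1))
        return np.stack(rows, axis=-2)

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "R0_mm": self.r0_mm,
            "coils": {
                ax: [[t.n, t.m, t.kind, t.coeff] for t in self.terms[ax]]
                for ax in AXES
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoilModel":
        terms = {
            ax: tuple(CoilTerm(*row) for row in rows)
            for ax, rows in d.get("coils", {}).items()
        }
        return cls(terms=terms, r0_mm=float(d["R0_mm"]), name=str(d.get("name", "unnamed")))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CoilModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def linear(cls, r0_mm: float = 250.0) -> "CoilModel":
        """Ideal coil: purely linear gradients, L(r) = I everywhere."""
        return cls(terms={}, r0_mm=r0_mm, name="ideal-linear")


def default_model() -> CoilModel:
    """The shipped representative whole-body 3T coil model."""
    from importlib.resources import files

    return CoilModel.from_yaml(files("gnladc.data") / "coil_representative.yaml")


# -- diffusion directions -------------------------------------------------


@dataclass(frozen=True)
class DirectionSet:
    """Three pairwise-orthonormal diffusion-encoding directions."""

    u: np.ndarray  # (3, 3), rows are unit vectors

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float).reshape(3, 3)
        if not np.allclose(u @ u.T, np.eye(3), atol=1e-10):
            raise ValueError("direction set must be pairwise orthonormal (1e-10)")
        object.__setattr__(self, "u", u)

    @classmethod
    def axes(cls) -> "DirectionSet":
        return cls(np.eye(3))

    @classmethod
    def rotated(cls, rotation: np.ndarray) -> "DirectionSet":
        return cls(np.asarray(rotation, dtype=float))


# -- operations -----------------------------------------------------------


def evaluate_field(
    model: CoilModel, axis: str, points: np.ndarray, out_of_range: str = "nan"
) -> np.ndarray:
    """Normalized coil field f_a(r) at mm coordinates.

    A purely linear coil returns the coordinate itself; points beyond the
    validity radius (1.5 R0) are flagged NaN (or raise), never silently
    extrapolated.
    """
    return model.field(axis, points, out_of_range=out_of_range)


@dataclass
class GNLTensorField:
    """Per-voxel GNL tensor on an image grid (magnet-frame voxel centers)."""

    tensor: np.ndarray                     # shape (nz, ny, nx, 3, 3)
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensor.shape[:3]


def gnl_tensor(model: CoilModel, grid) -> GNLTensorField:
    """Evaluate L(r) at the voxel centers of ``grid`` (an :class:`ImageVolume`
    or anything with ``physical_points()``)."""
    pts = grid.physical_points()
    bad = np.linalg.norm(pts, axis=-1) > model.validity_radius_mm
    if np.any(bad):
        raise ValueError(
            f"{int(bad.sum())} voxel(s) lie beyond the validity radius "
            f"{model.validity_radius_mm:.0f} mm"
        )
    L = model.jacobian(pts)
    return GNLTensorField(tensor=L, origin=grid.origin, spacing=grid.spacing)


def direction_corrector(L: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Per-direction b-value corrector c = u^T (L^T L) u (> 0).

    ``L`` may carry leading grid dimensions; ``u`` must be a unit vector.
    """
    u = np.asarray(u, dtype=float)
    nrm = np.linalg.norm(u)
    if nrm == 0:
        raise ValueError("direction vector must be non-zero")
    if abs(nrm - 1.0) > 1e-8:
        raise ValueError(f"direction vector must be unit length, |u|={nrm}")
    L = np.asarray(L, dtype=float)
    Lu = L @ u  # actual gradient direction for nominal u
    return np.einsum("...a,...a->...", Lu, Lu)


def trace_corrector(L: np.ndarray, dirs: DirectionSet | None = None) -> np.ndarray:
    """Trace b-value corrector c_bar = mean_k u_k^T L^T L u_k = tr(L^T L)/3.

    Independent of which orthonormal triad is supplied (rotation invariance
    of the trace).
    """
    if dirs is None:
        dirs = DirectionSet.axes()
    L = np.asarray(L, dtype=float)
    cs = [direction_corrector(L, u) for u in dirs.u]
    return sum(cs) / 3.0
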