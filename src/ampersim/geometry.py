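"""Axisymmetric unit-cell geometry of a biosensor with a perforated membrane.

The sensor is modelled as one axisymmetric unit cell of radius 1 (all
lengths scaled by the cell radius ``a1*``).  From the electrode at ``z=0``
upward the cell stacks:

* ``Ω1`` selective membrane, ``0 <= z <= b1`` (product only),
* ``Ω2`` enzyme layer: a full-width slab ``b1 <= z <= b2`` plus the
  enzyme-filled lower part of the hole ``b2 <= z <= b3``,
* ``Ω3`` outer diffusion layer: the open upper part of the hole
  ``b3 <= z <= b4`` plus the full-width slab ``b4 <= z <= b5``,
* ``Ω4`` the impermeable carrier of the perforated membrane, i.e. the
  annulus ``a(z) <= r <= 1`` for ``b2 <= z <= b4``.  It carries no field
  and enters the model only through zero-flux walls.

The hole wall ``r = a(z)`` interpolates between the throat radius ``a2``
and the mouth radius ``a3`` following one of seven profiles (cylinder and
upward/downward cone, paraboloid, concave paraboloid).

Orientation convention: *upward* shapes have their narrow end (the throat
``a2``) at the hole top ``z = b4``, widening toward the enzyme side; this
is the orientation under which upward shapes carry the wider, less
resistive channels on the enzyme side.  ``GeometrySpec(flip_orientation=
True)`` swaps every upward shape with its downward partner.

Two scalar descriptors parameterize the membrane:

* perforation level ``alpha = 1 - a2`` (0 = hole as wide as the cell),
* enzyme filling level ``gamma = (b3 - b2) / (b4 - b2)`` in [0, 1].
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Shape",
    "GeometrySpec",
    "UnitCell",
    "InvalidSpecError",
    "hole_radius_profile",
    "hole_radius_slope",
    "perforation_level",
    "throat_from_alpha",
    "filling_height",
    "build_unit_cell",
    "hole_section_area",
    "wall_polyline",
    "wall_arclength",
]

_TOL = 1e-12


class InvalidSpecError(ValueError):
    """Raised for geometrically inadmissible specifications."""


class Shape(str, enum.Enum):
    CYLINDER = "cylinder"
    CONE_UP = "cone_up"
    CONE_DOWN = "cone_down"
    PARABOLOID_UP = "paraboloid_up"
    PARABOLOID_DOWN = "paraboloid_down"
    CONCAVE_PARABOLOID_UP = "concave_paraboloid_up"
    CONCAVE_PARABOLOID_DOWN = "concave_paraboloid_down"


#: shapes whose throat sits at the hole top under the default convention
_UPWARD = {Shape.CONE_UP, Shape.PARABOLOID_UP, Shape.CONCAVE_PARABOLOID_UP}
_DOWNWARD = {
    Shape.CONE_DOWN,
    Shape.PARABOLOID_DOWN,
    Shape.CONCAVE_PARABOLOID_DOWN,
}


def perforation_level(a2: float) -> float:
    """Perforation level ``alpha = 1 - a2`` of the membrane."""
    if not 0.0 < a2 <= 1.0:
        raise InvalidSpecError(f"throat radius a2 must lie in (0, 1], got {a2}")
    return 1.0 - a2


def throat_from_alpha(alpha: float) -> float:
    """Inverse of :func:`perforation_level`."""
    if not 0.0 <= alpha < 1.0:
        raise InvalidSpecError(f"perforation level must lie in [0, 1), got {alpha}")
    return 1.0 - alpha


def filling_height(gamma: float, b2: float, b4: float) -> float:
    """Height ``b3 = b2 + gamma (b4 - b2)`` of the enzyme filling."""
    if not 0.0 <= gamma <= 1.0:
        raise InvalidSpecError(f"filling level must lie in [0, 1], got {gamma}")
    if not b2 < b4:
        raise InvalidSpecError(f"need b2 < b4, got b2={b2}, b4={b4}")
    return b2 + gamma * (b4 - b2)


@dataclass(frozen=True)
class GeometrySpec:
    """Dimensionless unit-cell geometry.

    Parameters
    ----------
    shape:
        Hole-wall profile.
    a2, a3:
        Throat (narrow-end) and mouth (wide-end) radii, ``0 < a2 <= a3 <= 1``.
        The cylinder uses ``a2`` only.
    b1 .. b5:
        Heights of the selective-membrane top, enzyme-slab top (= membrane
        bottom), enzyme filling, membrane top and diffusion-layer top.
    flip_orientation:
        Swap the upward/downward interpretation of the shape.
    """

    shape: Shape
    a2: float
    a3: float
    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    flip_orientation: bool = field(default=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", Shape(self.shape))
        if not (0.0 < self.b1 < self.b2 <= self.b3 <= self.b4 < self.b5):
            raise InvalidSpecError(
                "heights must satisfy 0 < b1 < b2 <= b3 <= b4 < b5, got "
                f"b=({self.b1}, {self.b2}, {self.b3}, {self.b4}, {self.b5})"
            )
        if not self.b2 < self.b4:
            raise InvalidSpecError("perforated membrane needs b2 < b4")
        if not 0.0 < self.a2 <= 1.0:
            raise InvalidSpecError(f"a2 must lie in (0, 1], got {self.a2}")
        if self.a2 > self.a3 + _TOL:
            raise InvalidSpecError(
                f"throat must not exceed mouth: a2={self.a2} > a3={self.a3}"
            )
        if self.a3 > 1.0 + _TOL:
            raise InvalidSpecError(f"a3 must not exceed the cell radius 1, got {self.a3}")

    # -- derived descriptors -------------------------------------------------
    @property
    def alpha(self) -> float:
        return perforation_level(self.a2)

    @property
    def gamma(self) -> float:
        return (self.b3 - self.b2) / (self.b4 - self.b2)

    @classmethod
    def from_levels(
        cls,
        shape: Shape | str,
        alpha: float,
        gamma: float,
        *,
        a3: float = 0.1,
        b1: float = 2.0,
        b2: float = 4.0,
        b4: float = 14.0,
        b5: float = 16.0,
        flip_orientation: bool = False,
    ) -> "GeometrySpec":
        """Build a spec from (alpha, gamma); defaults are the study layout
        b1=2, b2=4, b4=14, b5=16, a3=0.1."""
        a2 = throat_from_alpha(alpha)
        b3 = filling_height(gamma, b2, b4)
        return cls(Shape(shape), a2, a3, b1, b2, b3, b4, b5, flip_orientation)

    def with_gamma(self, gamma: float) -> "GeometrySpec":
        return replace(self, b3=filling_height(gamma, self.b2, self.b4))


def _tau(spec: GeometrySpec, z: np.ndarray) -> np.ndarray:
    """Normalized distance from the narrow end along the hole axis."""
    zeta = (np.asarray(z, dtype=float) - spec.b2) / (spec.b4 - spec.b2)
    narrow_top = spec.shape in _UPWARD
    if spec.flip_orientation:
        narrow_top = not narrow_top
    return 1.0 - zeta if narrow_top else zeta


def hole_radius_profile(shape: Shape | str, z, spec: GeometrySpec):
    """Hole-wall radius ``a(z)`` for ``b2 <= z <= b4``.

    ``a`` is continuous, takes the value ``a2`` at the narrow end and ``a3``
    at the wide end.  Cones are linear; paraboloids are quadratic with zero
    slope at the narrow end; concave paraboloids are quadratic with zero
    slope at the wide end.
    """
    shape = Shape(shape)
    z = np.asarray(z, dtype=float)
    if np.any(z < spec.b2 - _TOL) or np.any(z > spec.b4 + _TOL):
        raise ValueError(f"z outside the hole range [{spec.b2}, {spec.b4}]")
    if shape is Shape.CYLINDER:
        a = np.full_like(z, spec.a2)
        return a if a.ndim else float(a)
    tau = np.clip(_tau(spec, z), 0.0, 1.0)
    d = spec.a3 - spec.a2
    if shape in (Shape.CONE_UP, Shape.CONE_DOWN):
        a = spec.a2 + d * tau
    elif shape in (Shape.PARABOLOID_UP, Shape.PARABOLOID_DOWN):
        a = spec.a2 + d * tau**2
    else:  # concave paraboloid: vertex at the wide end
        a = spec.a3 - d * (1.0 - tau) ** 2
    return a if a.ndim else float(a)


def hole_radius_slope(shape: Shape | str, z, spec: GeometrySpec):
    """``da/dz`` of the wall profile (analytic)."""
    shape = Shape(shape)
    z = np.asarray(z, dtype=float)
    if shape is Shape.CYLINDER:
        out = np.zeros_like(z)
        return out if out.ndim else float(out)
    L = spec.b4 - spec.b2
    tau = np.clip(_tau(spec, z), 0.0, 1.0)
    d = spec.a3 - spec.a2
    narrow_top = (shape in _UPWARD) != spec.flip_orientation
    dtau_dz = (-1.0 if narrow_top else 1.0) / L
    if shape in (Shape.CONE_UP, Shape.CONE_DOWN):
        da_dtau = d * np.ones_like(tau)
    elif shape in (Shape.PARABOLOID_UP, Shape.PARABOLOID_DOWN):
        da_dtau = 2.0 * d * tau
    else:
        da_dtau = 2.0 * d * (1.0 - tau)
    out = da_dtau * dtau_dz
    return out if out.ndim else float(out)


# 3-point Gauss-Legendre: exact for the (at most quadratic) wall profiles
_GL3_X = np.array([-math.sqrt(3.0 / 5.0), 0.0, math.sqrt(3.0 / 5.0)])
_GL3_W = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


def hole_section_area(spec: GeometrySpec, z0: float, z1: float) -> float:
    """Plane (r, z) area ``∫ a(z) dz`` of the hole between two heights."""
    if z1 <= z0 + _TOL:
        return 0.0
    zm, hh = 0.5 * (z0 + z1), 0.5 * (z1 - z0)
    zq = zm + hh * _GL3_X
    return float(hh * np.sum(_GL3_W * hole_radius_profile(spec.shape, zq, spec)))


def wall_polyline(spec: GeometrySpec, n: int) -> np.ndarray:
    """Sample the hole wall at ``n+1`` points; returns ``(n+1, 2)`` (r, z)."""
    z = np.linspace(spec.b2, spec.b4, n + 1)
    r = hole_radius_profile(spec.shape, z, spec)
    return np.column_stack([r, z])


def wall_arclength(spec: GeometrySpec) -> float:
    """Exact arc length of the wall curve (quadrature of sqrt(1 + a'^2))."""
    z0, z1 = spec.b2, spec.b4
    # composite 16-panel GL3: safely exact to round-off for these profiles
    edges = np.linspace(z0, z1, 17)
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        zm, hh = 0.5 * (a + b), 0.5 * (b - a)
        zq = zm + hh * _GL3_X
        s = hole_radius_slope(spec.shape, zq, spec)
        total += hh * np.sum(_GL3_W * np.sqrt(1.0 + np.asarray(s) ** 2))
    return float(total)


@dataclass(frozen=True)
class UnitCell:
    """Region description of the computational domain (Ω1 ∪ Ω2 ∪ Ω3).

    ``degenerate`` names the coincidence, if any, of the enzyme interface
    Γ3 with a carrier plane (``gamma=0`` -> carrier_bottom, ``gamma=1`` ->
    carrier_top) or the vanishing of the carrier (``alpha=0``).
    """

    spec: GeometrySpec
    degenerate: str | None

    @property
    def full_width(self) -> bool:
        """True when the hole spans the whole cell (carrier Ω4 vanishes)."""
        return self.spec.a2 >= 1.0 - _TOL

    def region_area(self, region: int) -> float:
        """Closed-form plane area of Ω1 / Ω2 / Ω3 in the (r, z) plane."""
        s = self.spec
        if self.full_width:
            hole = {2: s.b3 - s.b2, 3: s.b4 - s.b3}
        else:
            hole = {
                2: hole_section_area(s, s.b2, s.b3),
                3: hole_section_area(s, s.b3, s.b4),
            }
        if region == 1:
            return s.b1
        if region == 2:
            return (s.b2 - s.b1) + hole[2]
        if region == 3:
            return hole[3] + (s.b5 - s.b4)
        raise ValueError(f"unknown region {region}")

    def total_area(self) -> float:
        return sum(self.region_area(k) for k in (1, 2, 3))


def build_unit_cell(spec: GeometrySpec) -> UnitCell:
    """Validate a spec and classify degenerate configurations."""
    degenerate = None
    if spec.a2 >= 1.0 - _TOL:
        degenerate = "alpha=0: carrier vanishes; three-slab stack"
    elif spec.b3 <= spec.b2 + _TOL:
        degenerate = "gamma=0: enzyme interface coincides with carrier_bottom"
    elif spec.b3 >= spec.b4 - _TOL:
        degenerate = "gamma=1: enzyme interface coincides with carrier_top"
    return UnitCell(spec=spec, degenerate=degenerate)
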