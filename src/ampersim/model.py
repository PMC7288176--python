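"""Reaction–diffusion model of the amperometric biosensor.

Two species are tracked in the unit cell: the substrate ``S`` (present in
the enzyme region Ω2 and the outer diffusion region Ω3) and the enzymatic
product ``P`` (present everywhere, including the selective membrane Ω1).
In dimensionless form (lengths scaled by the cell radius ``a1*``,
concentrations by the Michaelis constant ``Km``, time by ``a1*^2 / D1*``):

.. math::

    \\partial_t P = D \\Delta P + \\sigma^2 S / (1 + S)  \\quad (\\Omega_2)
    \\qquad
    \\partial_t S = D \\Delta S - \\sigma^2 S / (1 + S)  \\quad (\\Omega_2)

with pure diffusion elsewhere, piecewise diffusivities ``{1, D2, D3}`` for
``P`` and ``{D2, D3}`` for ``S``, and the Damköhler number
``sigma2 = Vmax a1*^2 / (Km D1*)`` comparing the enzymatic rate to the
diffusive rate.  The product is oxidized instantly at the electrode
(``P = 0`` at ``z = 0``); the well-stirred bulk pins ``P = 0`` and
``S = S0`` at the top; every other boundary — symmetry axis, outer cell
radius, hole wall and carrier surfaces — is impermeable.  The selective
membrane passes the product only, so ``S`` obeys a zero-flux condition at
its top face Γ1, the unique mass-conserving closure.

Interface matching (field and normal-flux continuity across Γ1/Γ3) is
enforced weakly by using a single continuous field per species with
region-wise diffusivity in the conforming Galerkin discretization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometrySpec, InvalidSpecError, Shape

__all__ = [
    "KineticScheme",
    "DimensionalParams",
    "DimensionlessParams",
    "ProblemSpec",
    "FARADAY",
    "derive_vmax_km",
    "nondimensionalize",
    "redimensionalize",
    "reaction_rate",
    "build_problem",
]

FARADAY = 96485.33212  # C / mol


@dataclass(frozen=True)
class KineticScheme:
    """Rate constants of the enzymatic scheme E + S <-> ES -> E + P."""

    k1: float  # binding, conc^-1 time^-1
    k_minus1: float  # dissociation, time^-1
    k2: float  # catalytic, time^-1
    E0: float  # total enzyme concentration

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0 or self.E0 <= 0 or self.k_minus1 < 0:
            raise InvalidSpecError("rate constants must be positive (k_-1 >= 0)")


def derive_vmax_km(scheme: KineticScheme) -> tuple[float, float]:
    """Michaelis–Menten parameters ``Vmax = k2 E0``, ``Km = (k2 + k_-1)/k1``."""
    return scheme.k2 * scheme.E0, (scheme.k2 + scheme.k_minus1) / scheme.k1


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional problem parameters (consistent units assumed)."""

    D1_star: float
    D2_star: float
    D3_star: float
    a1_star: float
    a2_star: float
    a3_star: float
    b1_star: float
    b2_star: float
    b3_star: float
    b4_star: float
    b5_star: float
    S0_star: float
    Vmax: float
    Km: float
    shape: Shape = Shape.CYLINDER
    ne: int = 1
    F: float = FARADAY

    def __post_init__(self) -> None:
        for name in (
            "D1_star", "D2_star", "D3_star", "a1_star", "S0_star", "Vmax", "Km", "F",
        ):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        if self.ne < 1:
            raise InvalidSpecError("ne must be a positive integer")


@dataclass(frozen=True)
class DimensionlessParams:
    """Dimensionless transport/kinetics parameters plus the geometry."""

    sigma2: float  # Damköhler number Vmax a1*^2 / (Km D1*)
    S0: float  # bulk substrate / Km
    D2: float  # enzyme diffusivity / D1*
    D3: float  # diffusion-layer diffusivity / D1*
    geometry: GeometrySpec

    def __post_init__(self) -> None:
        for name in ("sigma2", "S0", "D2", "D3"):
            if getattr(self, name) < 0 or (name != "sigma2" and getattr(self, name) == 0):
                raise InvalidSpecError(f"{name} must be positive")


def nondimensionalize(p: DimensionalParams) -> DimensionlessParams:
    """Scale lengths by ``a1*``, concentrations by ``Km``, time by
    ``a1*^2 / D1*``; ``sigma2 = Vmax a1*^2 / (Km D1*)``."""
    a1 = p.a1_star
    geo = GeometrySpec(
        shape=p.shape,
        a2=p.a2_star / a1,
        a3=p.a3_star / a1,
        b1=p.b1_star / a1,
        b2=p.b2_star / a1,
        b3=p.b3_star / a1,
        b4=p.b4_star / a1,
        b5=p.b5_star / a1,
    )
    return DimensionlessParams(
        sigma2=p.Vmax * a1**2 / (p.Km * p.D1_star),
        S0=p.S0_star / p.Km,
        D2=p.D2_star / p.D1_star,
        D3=p.D3_star / p.D1_star,
        geometry=geo,
    )


def redimensionalize(
    dp: DimensionlessParams,
    *,
    a1_star: float,
    D1_star: float,
    Km: float,
    ne: int = 1,
    F: float = FARADAY,
) -> DimensionalParams:
    """Inverse of :func:`nondimensionalize` given the three scales."""
    g = dp.geometry
    return DimensionalParams(
        D1_star=D1_star,
        D2_star=dp.D2 * D1_star,
        D3_star=dp.D3 * D1_star,
        a1_star=a1_star,
        a2_star=g.a2 * a1_star,
        a3_star=g.a3 * a1_star,
        b1_star=g.b1 * a1_star,
        b2_star=g.b2 * a1_star,
        b3_star=g.b3 * a1_star,
        b4_star=g.b4 * a1_star,
        b5_star=g.b5 * a1_star,
        S0_star=dp.S0 * Km,
        Vmax=dp.sigma2 * Km * D1_star / a1_star**2,
        Km=Km,
        shape=g.shape,
        ne=ne,
        F=F,
    )


def reaction_rate(S, sigma2: float):
    """Michaelis–Menten source ``sigma2 * S / (1 + S)`` (scaled units).

    Applied with ``+`` sign to the product and ``-`` sign to the substrate
    in the enzyme region.  Negative concentrations signal a solver
    overshoot and are rejected here (the solver clips only inside its own
    source evaluation).
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("negative substrate concentration passed to reaction_rate")
    out = sigma2 * S / (1.0 + S)
    return out if out.ndim else float(out)


#: boundary-condition kinds by facet tag, per field
_P_DIRICHLET = {"electrode": 0.0, "bulk_top": 0.0}
_P_ZERO_FLUX = ("axis", "outer", "hole_wall", "carrier_bottom", "carrier_top")
_S_ZERO_FLUX = ("axis", "outer", "hole_wall", "carrier_bottom", "carrier_top", "gamma1")


@dataclass(frozen=True)
class ProblemSpec:
    """Complete discretization-ready problem statement.

    ``diffusivity_P`` / ``diffusivity_S`` map region tags to coefficients;
    regions absent from the ``S`` map carry no substrate equation (the
    selective membrane).  Dirichlet maps give facet-tag -> value; every
    other tagged facet of the mesh is zero-flux (natural).  Interior
    interfaces (gamma1, gamma3 for ``P``) are handled by field continuity.
    """

    params: DimensionlessParams
    diffusivity_P: dict[int, float]
    diffusivity_S: dict[int, float]
    source_region: int
    dirichlet_P: dict[str, float]
    dirichlet_S: dict[str, float]
    zero_flux_P: tuple[str, ...]
    zero_flux_S: tuple[str, ...]

    @property
    def sigma2(self) -> float:
        return self.params.sigma2

    @property
    def S0(self) -> float:
        return self.params.S0


def build_problem(params: DimensionlessParams, mesh) -> ProblemSpec:
    """Assemble the :class:`ProblemSpec` for a tagged mesh and check that
    every boundary facet is covered by exactly one condition per field."""
    geo = params.geometry
    ms = mesh.spec
    if ms is not None and (
        abs(ms.b3 - geo.b3) > 1e-9 or abs(ms.a2 - geo.a2) > 1e-9 or ms.shape != geo.shape
    ):
        raise ValueError("mesh was generated for a different geometry")

    spec = ProblemSpec(
        params=params,
        diffusivity_P={1: 1.0, 2: params.D2, 3: params.D3},
        diffusivity_S={2: params.D2, 3: params.D3},
        source_region=2,
        dirichlet_P=dict(_P_DIRICHLET),
        dirichlet_S={"bulk_top": params.S0},
        zero_flux_P=_P_ZERO_FLUX,
        zero_flux_S=_S_ZERO_FLUX,
    )

    boundary = [t for t in mesh.facets if t not in ("gamma1", "gamma3")]
    for tag in boundary:
        facets = mesh.facets[tag]
        if facets.size == 0:
            continue
        in_p = (tag in spec.dirichlet_P) + (tag in spec.zero_flux_P)
        if in_p != 1:
            raise ValueError(f"facet tag {tag!r} not covered exactly once for P")
        # the substrate field exists only above the selective membrane
        touches_s = bool(np.any(mesh.points[np.unique(facets), 1] > geo.b1 - 1e-12))
        in_s = (tag in spec.dirichlet_S) + (tag in spec.zero_flux_S)
        if touches_s and in_s != 1:
            raise ValueError(f"facet tag {tag!r} not covered exactly once for S")
    # the substrate obeys zero flux at the selective-membrane top (gamma1)
    return spec
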